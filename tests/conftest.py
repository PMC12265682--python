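import numpy as np
import pytest

from antigenforge.config import RunConfig
from antigenforge.fixtures import make_toy_genome, write_fixture_bundle
from antigenforge.pipeline import run_pipeline

SEED = 11


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(SEED)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle") / "fx"
    write_fixture_bundle(out, SEED)
    return out


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run") / "out"
    cfg = RunConfig(input_dir=str(bundle_dir), out_dir=str(out), seed=SEED)
    report = run_pipeline(cfg)
    return cfg, out, report


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
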