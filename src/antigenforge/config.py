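"""Run configuration.

Every tumor-specificity threshold defaults to its published value in the
filter functions themselves; :class:`RunConfig` carries the knobs that are
legitimately tunable (pseudocount, genus-background read threshold,
recurrence thresholds, quantile convention, window sizes, class toggles)
plus paths and mode. Overrides relative to the defaults are recorded in the
run report, and every output carries the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .events import RECURRENCE_DEFAULTS

ALL_CLASSES = [
    "self_gene", "splicing", "intron_retention", "te_chimeric", "te_self",
    "fusion", "variant", "microbiome", "nuorf",
]


@dataclass
class RunConfig:
    input_dir: str = "."
    out_dir: str = "out"
    mode: str = "cohort"  # cohort | per_sample
    classes: list[str] = field(default_factory=lambda: list(ALL_CLASSES))
    seed: int = 0
    pseudocount: float = 0.01
    genus_read_threshold: int = 10
    recurrence: dict[str, float] = field(
        default_factory=lambda: dict(RECURRENCE_DEFAULTS)
    )
    flank_nt: int = 33
    mutation_window: int = 14
    min_tail_aa: int = 8
    tie_window_nt: int = 8
    quantile: float = 75.0
    use_median_junction_counts: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("cohort", "per_sample"):
            raise ValueError(f"mode must be cohort or per_sample, got {self.mode!r}")
        unknown = set(self.classes) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        semantic = {k: v for k, v in self.to_dict().items()
                    if k not in ("input_dir", "out_dir")}
        payload = json.dumps(semantic, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def overrides(self) -> dict:
        default = RunConfig().to_dict()
        cur = self.to_dict()
        skip = {"input_dir", "out_dir", "seed"}
        return {k: v for k, v in cur.items() if k not in skip and default[k] != v}

    @classmethod
    def from_yaml(cls, path: str | Path, **cli_overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in cli_overrides.items() if v is not None})
        return cls(**data)
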