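"""Run configuration: every tunable with its default, loadable from YAML."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class RunConfig:
    """Defaults follow the method's published operating point.

    Score table: 1000 bootstrap iterations of 10,000-read draws, log2 ratio
    capped at +/-5, zero below a combined count of 20. Patient FS: one
    million sampled fragments. VFS: 8-read minimum. Variant tracking: read
    cutoff grid [1, 8] x minimum-variant grid [1, 6]. Cross-validation: 20
    repeats of 10 folds (score-table rebuilds inside CV use a reduced
    ``cv_n_boot``). Clinical simulation: 5.8% benefit, 10,000 iterations.
    """

    n_boot: int = 1000
    n_sample: int = 10_000
    cap: float = 5.0
    min_count: int = 20
    fs_n_sample: int = 1_000_000
    min_reads: int = 8
    read_cutoff_range: tuple[int, int] = (1, 8)
    min_variants_range: tuple[int, int] = (1, 6)
    n_repeats: int = 20
    n_folds: int = 10
    cv_n_boot: int = 100
    benefit_rate: float = 0.058
    sim_iters: int = 10_000
    length_cap: int = 600
    min_mapq: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(known)}")
        for key in ("read_cutoff_range", "min_variants_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["read_cutoff_range"] = list(d["read_cutoff_range"])
        d["min_variants_range"] = list(d["min_variants_range"])
        return d
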