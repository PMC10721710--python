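"""Run configuration: one serializable record of every stage parameter.

Defaults follow the published analysis where it states a value: pruning
at 16 unique values, co-occurrence on at least 16 plots, 999 permutation
steps, alpha = 0.05.  The coupling null model defaults to 199
permutations for desk-scale runs (999 for fidelity runs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # screening
    min_unique: int = 16
    min_co_occurrence: int = 16
    n_perm: int = 999
    alpha: float = 0.05
    css_quantile: float = 0.5
    use_all_plots: bool = False
    stage_split: bool = True
    # profiles
    gamma_grid: list = field(
        default_factory=lambda: [round(0.05 * i, 2) for i in range(10)])
    n_boot: int = 1000
    min_profile_points: int = 2
    # coupling
    coupling_n_perm: int = 199
    significant_only: bool = True
    deviation_test: str = "wilcoxon"
    # shared
    seed: int = 0
    # paths
    values: str = ""
    variables: str = ""
    plots: str = ""
    outdir: str = "results"

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            try:
                path = Path(source)
                text = path.read_text() if path.is_file() else str(source)
            except OSError:
                text = str(source)
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
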