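"""Run configuration: every tunable of the pipeline in one validated object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml


@dataclass
class RunConfig:
    """Defaults for the full scan pipeline.

    n_perm
        Permutations averaged into the phenotype-independent mutual
        information.
    n_trial, n_p
        Train/test trials per block and permutation-null fits per trial.
    kappa_grid, eta_grid
        SNF hyperparameter grid searched by the minimax block-size
        criterion.
    s_min, t_max
        Minimum block size and iteration cap of the hierarchical
        decomposition.
    q_statistic
        Reduction over a block's similarities in the inter-block odds:
        "max" (default) or "mean".
    """

    n_perm: int = 100
    n_trial: int = 1000
    n_p: int = 20
    kappa_grid: tuple[int, ...] = (10, 11, 12, 13, 14, 15)
    eta_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7)
    s_min: int = 2
    t_max: int = 50
    snf_iterations: int = 20
    seed: int = 0
    q_statistic: str = "max"
    max_missing_fraction: float = 0.5
    already_positive: bool = False

    def __post_init__(self) -> None:
        if min(self.n_perm, self.n_trial, self.n_p, self.s_min, self.t_max) < 1:
            raise ValueError("counts must be >= 1")
        if self.snf_iterations < 0:
            raise ValueError("snf_iterations must be >= 0")
        if not self.kappa_grid or not self.eta_grid:
            raise ValueError("parameter grids must be non-empty")
        if any(k < 2 for k in self.kappa_grid):
            raise ValueError("kappa values must be >= 2")
        if any(e <= 0 for e in self.eta_grid):
            raise ValueError("eta values must be > 0")
        if self.q_statistic not in ("max", "mean"):
            raise ValueError("q_statistic must be 'max' or 'mean'")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kappa_grid", "eta_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kappa_grid"] = list(self.kappa_grid)
        d["eta_grid"] = list(self.eta_grid)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
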