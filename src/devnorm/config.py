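"""Pipeline configuration: the analysis constants, in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .fitting import FitConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Constants of the normative-modelling pipeline.

    Defaults are the standard analysis constants: 10-fold cross-validation,
    three rounds of 3σ outlier removal, Shapiro–Wilk at α = 0.05 with the
    "normal enough" window (|skew| < 0.6, Pearson kurtosis in (2.4, 3.6)),
    a ±2 z-score deficit cutoff, and a central 95% normative band. The two
    ``scaling_*`` switches select the sensitivity-check variants of the spread
    scaling: ``scaling_root_inside`` moves the n/(n−DOF) bias factor under the
    square root, and ``scaling_dof_curve_only`` counts only the mean-curve
    coefficients as consumed degrees of freedom (excluding the residual
    line's 2).
    """

    k_folds: int = 10
    outlier_rounds: int = 3
    outlier_sd: float = 3.0
    shapiro_alpha: float = 0.05
    skew_limit: float = 0.6
    kurtosis_window: tuple = (2.4, 3.6)
    z_cutoff: float = 2.0
    coverage: float = 0.95
    seed: int = 0
    max_iterations: int = 1000
    convergence_tolerance: float = 1e-10
    scaling_root_inside: bool = False
    scaling_dof_curve_only: bool = False

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        for name in ("outlier_rounds", "outlier_sd", "shapiro_alpha",
                     "skew_limit", "z_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must be in (0, 1)")
        lo, hi = self.kurtosis_window
        if not 0 < lo < hi:
            raise ValueError("kurtosis_window must be an increasing positive pair")

    def fit_config(self) -> FitConfig:
        return FitConfig(k_folds=self.k_folds, seed=self.seed,
                         max_iterations=self.max_iterations,
                         convergence_tolerance=self.convergence_tolerance)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kurtosis_window"] = list(self.kurtosis_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "kurtosis_window" in d:
            d["kurtosis_window"] = tuple(d["kurtosis_window"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
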