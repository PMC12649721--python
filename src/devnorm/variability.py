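"""Age-varying variability: absolute-residual model, scaling, z-scores.

Residual spread in child motor performance shrinks substantially with age,
so a single standard deviation misrepresents both young and old ends of the
range. Instead, a straight line is fit to |residual| versus age (with the
same 10-fold cross-validated selection used for the mean curve), giving the
predicted mean absolute residual at any age. That prediction is converted to
an unbiased age-specific spread estimate

    s(age) = √(π/2) · n/(n − DOF) · (intercept + slope·age)

(√(π/2) is the classical factor turning the mean absolute deviation of a
normal variable into its standard deviation; n/(n − DOF) corrects the bias
from the DOF parameters consumed by the fitted models), and each residual
is standardised as z = residual / s(age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fitting import CurveModel, FitConfig, cv_folds, heldout_r2, predict
from .simulate import MAD_TO_SD

__all__ = [
    "ResidualModel",
    "compute_residuals",
    "fit_residual_model",
    "scale_factor",
    "z_scores",
]

#: relative floor applied to the predicted mean absolute residual so the
#: spread stays positive where the fitted line dips <= 0 at extreme ages
FLOOR_FRACTION = 1e-9


@dataclass
class ResidualModel:
    """Linear model of the mean absolute residual versus age.

    ``dof`` counts the residual degrees of freedom consumed before the
    spread is estimated: the mean-curve coefficients (5 with the hand term,
    4 without) plus 2 for this line. ``floor`` is the positivity floor for
    the predicted mean absolute residual, set to a tiny fraction of the
    response range. ``root_inside`` switches to the alternative reading of
    the scaling formula, √(π/2 · n/(n−DOF)), for sensitivity checks.
    """

    intercept: float
    slope: float
    n: int
    dof: int
    test_r2: float = float("nan")
    fold_r2: list = field(default_factory=list)
    best_fold: int = -1
    floor: float = 1e-9
    root_inside: bool = False
    seed: Optional[int] = None

    def predicted_abs_residual(self, age):
        m = self.intercept + self.slope * np.asarray(age, dtype=float)
        return np.maximum(m, self.floor)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept, "slope": self.slope,
            "n": self.n, "dof": self.dof, "test_r2": self.test_r2,
            "fold_r2": list(self.fold_r2), "best_fold": self.best_fold,
            "floor": self.floor, "root_inside": self.root_inside,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResidualModel":
        return cls(**d)


def compute_residuals(model: CurveModel, df: pd.DataFrame) -> np.ndarray:
    """Observed minus fitted value for every row of a cohort slice."""
    for col in ("sex", "hand"):
        codes = set(np.unique(df[col]))
        if not codes <= {0, 1}:
            raise ValueError(f"{col} codes outside {{0,1}}: {sorted(codes - {0, 1})}")
    yhat = predict(model, df["age"].to_numpy(float), df["sex"].to_numpy(float),
                   df["hand"].to_numpy(float))
    return df["value"].to_numpy(float) - np.asarray(yhat)


def fit_residual_model(ages, abs_residuals, config: FitConfig,
                       mean_model_params: int,
                       value_range: float = 1.0,
                       line_dof: int = 2,
                       root_inside: bool = False) -> ResidualModel:
    """Cross-validated straight-line fit of |residual| versus age.

    Uses the same k-fold argmax-held-out-R² contest as the mean curve, with
    ordinary least squares per fold. The fold seed is the mean-curve seed
    offset by +1, so the two contests use different but reproducible splits.
    If every residual is zero the degenerate model (0, 0) is returned with a
    warning.
    """
    ages = np.asarray(ages, dtype=float)
    r = np.asarray(abs_residuals, dtype=float)
    if (r < 0).any():
        raise ValueError("absolute residuals must be >= 0")
    n = ages.size
    dof = mean_model_params + line_dof
    floor = FLOOR_FRACTION * (value_range if value_range > 0 else 1.0)

    if np.allclose(r, 0.0):
        warnings.warn("all residuals are zero: degenerate residual model",
                      stacklevel=2)
        return ResidualModel(0.0, 0.0, n, dof, test_r2=1.0, floor=floor,
                             root_inside=root_inside, seed=config.seed + 1)

    folds = cv_folds(n, config.k_folds, config.seed + 1)
    fits, scores = [], []
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        slope, intercept = np.polyfit(ages[mask], r[mask], 1)
        pred = intercept + slope * ages[test_idx]
        fits.append((float(intercept), float(slope)))
        scores.append(heldout_r2(r[test_idx], pred))
    best = max(range(len(folds)), key=lambda i: (scores[i], -i))
    intercept, slope = fits[best]
    return ResidualModel(
        intercept, slope, n, dof,
        test_r2=float(scores[best]), fold_r2=[float(s) for s in scores],
        best_fold=int(best), floor=floor, root_inside=root_inside,
        seed=config.seed + 1,
    )


def scale_factor(resmodel: ResidualModel, age):
    """Age-specific spread estimate s(age) from the absolute-residual line.

    Default form: s = √(π/2) · n/(n−DOF) · predicted mean |residual|. With
    ``root_inside`` set on the model, the bias factor moves under the root:
    s = √(π/2 · n/(n−DOF)) · predicted mean |residual|.
    """
    if resmodel.n <= resmodel.dof:
        raise ValueError(f"n ({resmodel.n}) must exceed DOF ({resmodel.dof})")
    m = resmodel.predicted_abs_residual(age)
    bias = resmodel.n / (resmodel.n - resmodel.dof)
    if resmodel.root_inside:
        s = np.sqrt(np.pi / 2.0 * bias) * m
    else:
        s = MAD_TO_SD * bias * m
    return float(s) if np.ndim(s) == 0 else s


def z_scores(residuals, resmodel: ResidualModel, ages) -> np.ndarray:
    """Standardise residuals by the age-specific spread: z = residual / s(age)."""
    s = scale_factor(resmodel, ages)
    return np.asarray(residuals, dtype=float) / np.asarray(s, dtype=float)
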