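"""Normative performance intervals, percentage-change summaries, and
deficit scoring of new individuals.

A fitted :class:`NormativeModel` defines, at every age, a central 95% band
around the mean curve: in working (possibly transformed) space the bounds
are ``center ± z₀.₉₇₅·s(age)`` with s(age) from the absolute-residual
model, then mapped back to the original scale. A new individual's value is
standardised the same way the training data were, and |z| beyond a cutoff
(±2 by default, roughly the 2nd/98th percentiles) flags a deficit in that
parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .fitting import CurveModel, FitConfig, kfold_cv_fit, predict
from .gate import NormalityVerdict, OutlierReport, TransformSpec
from .variability import ResidualModel, compute_residuals, fit_residual_model, scale_factor

__all__ = [
    "NormativeModel",
    "DEFAULT_CODING",
    "interval_curve",
    "interval_width_change",
    "mean_curve_change",
    "fixed_vs_changing_width",
    "score_participant",
    "bootstrap_curve_ci",
    "round_half_away",
]

DEFAULT_CODING = {
    "sex": {"female": 0, "male": 1},
    "hand": {"non_dominant": 0, "dominant": 1},
}


@dataclass
class NormativeModel:
    """Everything needed to score new individuals against a cohort.

    Bundles the mean curve, the absolute-residual (spread) model, the
    transform under which both were fitted, the normality verdict and
    outlier report from model building, the covariate coding, and
    provenance (parameter name, seeds, config hash, fitted age range).
    """

    curve: CurveModel
    residual: ResidualModel
    transform: TransformSpec
    gate: NormalityVerdict
    outliers: OutlierReport
    coding: dict = field(default_factory=lambda: DEFAULT_CODING)
    provenance: dict = field(default_factory=dict)

    @property
    def age_range(self):
        return tuple(self.provenance.get("age_range", (float("-inf"), float("inf"))))

    def to_dict(self) -> dict:
        return {
            "curve": self.curve.to_dict(),
            "residual": self.residual.to_dict(),
            "transform": self.transform.to_dict(),
            "gate": self.gate.to_dict(),
            "outliers": self.outliers.to_dict(),
            "coding": self.coding,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        return cls(
            curve=CurveModel.from_dict(d["curve"]),
            residual=ResidualModel.from_dict(d["residual"]),
            transform=TransformSpec.from_dict(d["transform"]),
            gate=NormalityVerdict.from_dict(d["gate"]),
            outliers=OutlierReport.from_dict(d["outliers"]),
            coding=d["coding"],
            provenance=d["provenance"],
        )


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (report style: 58.5 → 59)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def interval_curve(nm: NormativeModel, ages, coverage: float = 0.95,
                   sex: int = 0, hand: int = 0) -> pd.DataFrame:
    """Age-resolved normative band at the given covariates.

    Returns a frame with columns ``age, center, lower, upper, width`` on the
    original measurement scale. Bounds are built in working space as
    ``center ± q·s(age)`` with q the normal quantile for the requested
    central coverage, then back-transformed; for the order-reversing
    reciprocal transform the bounds swap, and bounds outside a transform's
    domain (e.g. a negative working-space value under sqrt or inverse) are
    clipped to the domain edge with a warning.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    q = float(sstats.norm.ppf(0.5 + coverage / 2.0))
    center_w = np.asarray(predict(nm.curve, ages, sex, hand), dtype=float)
    s = np.asarray(scale_factor(nm.residual, ages), dtype=float)
    lo_w, hi_w = center_w - q * s, center_w + q * s
    if nm.transform.kind in ("sqrt", "inverse"):
        eps = 1e-12
        if (lo_w <= 0).any():
            warnings.warn("working-space lower bound clipped to the transform domain",
                          stacklevel=2)
        lo_w = np.maximum(lo_w, eps)
        hi_w = np.maximum(hi_w, eps)
    center = nm.transform.inverse(center_w)
    lower = nm.transform.inverse(lo_w)
    upper = nm.transform.inverse(hi_w)
    if nm.transform.order_reversing:
        lower, upper = upper, lower
    return pd.DataFrame({
        "age": ages, "center": center, "lower": lower, "upper": upper,
        "width": upper - lower,
    })


def interval_width_change(width_young: float, width_old: float) -> float:
    """Signed percentage change in band width from the young to the old end.

    Returns the full-precision percentage; use :func:`round_half_away` for
    report display (e.g. a width falling from 0.2680 to 0.0685 is a 74%
    decrease).
    """
    if width_young <= 0:
        raise ValueError("baseline width must be > 0")
    return 100.0 * (width_old - width_young) / width_young


def mean_curve_change(nm: NormativeModel, age_lo: float = 5.0,
                      age_hi: float = 18.0, sex: int = 0, hand: int = 0) -> float:
    """Signed percentage change in the fitted mean curve across the age range.

    Evaluated on the original measurement scale at the stated covariates.
    Undefined when the curve crosses zero at the young end (the ratio loses
    meaning); that case raises rather than reporting an arbitrary sign.
    """
    band = interval_curve(nm, [age_lo, age_hi], sex=sex, hand=hand)
    y_lo, y_hi = float(band["center"].iloc[0]), float(band["center"].iloc[1])
    if y_lo == 0:
        raise ZeroDivisionError("mean curve is 0 at the young end: percentage undefined")
    return 100.0 * (y_hi - y_lo) / y_lo


def fixed_vs_changing_width(changing_width: float, fixed_width: float) -> float:
    """Signed % difference of an age-varying band width vs a fixed-width band."""
    if fixed_width <= 0:
        raise ValueError("fixed width must be > 0")
    return 100.0 * (changing_width - fixed_width) / fixed_width


def score_participant(nm: NormativeModel, age: float, sex: int, hand: int,
                      value: float, cutoff: float = 2.0):
    """Standardise a new observation and flag a deficit when |z| > cutoff.

    The value is mapped into the model's working space with the stored
    transform shift, the residual from the mean curve is divided by the
    age-specific spread s(age), and |z| beyond the cutoff flags a deficit.
    Ages outside the fitted range are scored with an extrapolation warning —
    developmental curves change fastest at the young end, where the model is
    least constrained.
    """
    if sex not in (0, 1) or hand not in (0, 1):
        raise ValueError(f"sex/hand must be dummy-coded 0/1, got sex={sex} hand={hand}")
    lo, hi = nm.age_range
    if not lo <= age <= hi:
        warnings.warn(
            f"age {age} outside the fitted range [{lo}, {hi}]: "
            "extrapolated z-scores are unreliable", stacklevel=2)
    working = float(nm.transform.forward(value))
    resid = working - predict(nm.curve, age, sex, hand)
    z = float(resid / scale_factor(nm.residual, age))
    return z, bool(abs(z) > cutoff)


def bootstrap_curve_ci(df: pd.DataFrame, config: FitConfig, family: str,
                       ages, B: int = 200, seed: int = 0,
                       includes_hand: bool = True, coverage: float = 0.95,
                       mean_model_params: Optional[int] = None) -> pd.DataFrame:
    """Case-resampling bootstrap confidence bands for the normative curves.

    Participants are resampled with replacement (keeping both hand rows of a
    participant together), the mean curve and residual line are refit on
    each replicate, and percentile 95% CIs for the band center, lower and
    upper bounds are reported on the age grid. Replicates whose fit fails
    are dropped.
    """
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small; CIs will be noisy",
                      stacklevel=2)
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    rng = np.random.default_rng(seed)
    pids = df["participant_id"].unique()
    by_pid = {p: g for p, g in df.groupby("participant_id", sort=False)}
    q = float(sstats.norm.ppf(0.5 + coverage / 2.0))
    n_params = mean_model_params or (5 if includes_hand else 4)

    centers, lowers, uppers = [], [], []
    for b in range(B):
        take = rng.choice(pids, size=pids.size, replace=True)
        boot = pd.concat([by_pid[p] for p in take], ignore_index=True)
        cfg = FitConfig(k_folds=config.k_folds, seed=config.seed + 1000 + b,
                        max_iterations=config.max_iterations,
                        convergence_tolerance=config.convergence_tolerance)
        try:
            curve = kfold_cv_fit(boot, cfg, family, includes_hand)
            resid = np.abs(compute_residuals(curve, boot))
            rm = fit_residual_model(boot["age"].to_numpy(float), resid, cfg,
                                    n_params,
                                    float(boot["value"].max() - boot["value"].min()))
            c = np.asarray(predict(curve, ages, 0, 0), dtype=float)
            s = np.asarray(scale_factor(rm, ages), dtype=float)
        except Exception:
            continue
        centers.append(c)
        lowers.append(c - q * s)
        uppers.append(c + q * s)
    if not centers:
        raise RuntimeError("every bootstrap replicate failed to fit")
    centers, lowers, uppers = map(np.array, (centers, lowers, uppers))
    out = {"age": ages}
    for name, arr in (("center", centers), ("lower", lowers), ("upper", uppers)):
        out[f"{name}_lo"] = np.percentile(arr, 2.5, axis=0)
        out[f"{name}_hi"] = np.percentile(arr, 97.5, axis=0)
    return pd.DataFrame(out)
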