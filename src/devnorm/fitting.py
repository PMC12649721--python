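"""Growth-curve fitting with cross-validated model selection.

Each performance parameter is modelled by one of two curve families in age,
with additive dummy-coded covariates for sex (female=0, male=1) and hand
(non-dominant=0, dominant=1)::

    exponential:  y = a0·exp(a1·age) + a2·sex + a3·hand + a4
    quadratic:    y = a0·age² + a1·age + a2·sex + a3·hand + a4

The exponential family is used whenever every observed value is strictly
positive; parameters that take zero or negative values get the quadratic
family, because the log-linearised initial estimates (Foss's method) need a
positive response. Fitting uses 10-fold cross-validation: the data are split
into ten near-equal random groups, each fold's model is trained on the other
nine and scored by R² = 1 − SSE/SST on its held-out group, and the fold
model with the best held-out R² is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CurveModel",
    "FitConfig",
    "FitError",
    "select_family",
    "foss_initial_estimates",
    "fit_quadratic",
    "fit_exponential",
    "kfold_cv_fit",
    "predict",
    "cv_folds",
]


class FitError(RuntimeError):
    """Raised when a curve fit cannot be completed."""


@dataclass
class FitConfig:
    """Cross-validation and optimizer contract.

    ``k_folds`` random near-equal groups; Levenberg–Marquardt damped least
    squares for the exponential family with at most ``max_iterations``
    residual evaluations and an SSE-change tolerance of
    ``convergence_tolerance``. Held-out R² is always 1 − SSE/SST computed on
    the held-out fold.
    """

    k_folds: int = 10
    seed: int = 0
    max_iterations: int = 1000
    convergence_tolerance: float = 1e-10


@dataclass
class CurveModel:
    """A fitted mean curve.

    ``a3`` (the hand offset) is fixed at 0 when ``includes_hand`` is false —
    bimanual-task parameters have no meaningful hand covariate. ``fold_r2``
    records every fold's held-out R² (NaN for folds that failed to fit);
    ``best_fold`` is the index of the winning fold.
    """

    family: str
    a0: float
    a1: float
    a2: float
    a3: float
    a4: float
    includes_hand: bool = True
    test_r2: float = float("nan")
    fold_r2: list = field(default_factory=list)
    best_fold: int = -1
    seed: Optional[int] = None
    converged: bool = True

    @property
    def n_params(self) -> int:
        return 5 if self.includes_hand else 4

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3, self.a4])

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "a0": self.a0, "a1": self.a1, "a2": self.a2,
            "a3": self.a3, "a4": self.a4,
            "includes_hand": self.includes_hand,
            "n_params": self.n_params,
            "test_r2": self.test_r2,
            "fold_r2": list(self.fold_r2),
            "best_fold": self.best_fold,
            "seed": self.seed,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CurveModel":
        return cls(
            family=d["family"], a0=d["a0"], a1=d["a1"], a2=d["a2"],
            a3=d["a3"], a4=d["a4"], includes_hand=d["includes_hand"],
            test_r2=d["test_r2"], fold_r2=list(d["fold_r2"]),
            best_fold=d["best_fold"], seed=d["seed"],
            converged=d.get("converged", True),
        )


def select_family(values: Sequence[float]) -> str:
    """Choose the curve family from the sign of the observed values.

    Exponential iff every value is strictly positive; any zero or negative
    value forces the quadratic family (the log-linearised initial estimates
    are undefined otherwise).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot select a family from an empty value list")
    return "exponential" if (v > 0).all() else "quadratic"


def foss_initial_estimates(ages, values):
    """Log-linearised initial estimates for the exponential fit.

    Fitting a straight line b + m·age to ln(y) gives a0_init = e^b and
    a1_init = m. When the values hug zero (min < 5% of max) an offset is
    plainly present, so 0.9·min is subtracted before taking logs and
    restored as a4_init; otherwise a4_init = 0. Covariate offsets start at 0.

    Returns ``(a0_init, a1_init, a4_init)``.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if (y <= 0).any():
        raise ValueError("log-linearised initial estimates need strictly positive values")
    shift = 0.0
    if y.min() < 0.05 * y.max():
        shift = 0.9 * y.min()
    logy = np.log(y - shift)
    m, b = np.polyfit(ages, logy, 1)
    return float(np.exp(b)), float(m), float(shift)


def fit_quadratic(df: pd.DataFrame, includes_hand: bool = True,
                  seed: Optional[int] = None) -> CurveModel:
    """Ordinary least squares for the quadratic family.

    A dummy covariate without variation in the data (e.g. an all-zero hand
    column) is dropped from the design and its coefficient pinned to 0; any
    remaining rank deficiency (e.g. a single age) is an error naming the
    collinear columns.
    """
    age = df["age"].to_numpy(float)
    y = df["value"].to_numpy(float)
    named = [("age^2", age**2), ("age", age), ("sex", df["sex"].to_numpy(float))]
    if includes_hand:
        named.append(("hand", df["hand"].to_numpy(float)))
    # dummies constant across the cohort are unidentifiable: pin to 0
    named = [(n, c) for n, c in named
             if n not in ("sex", "hand") or np.ptp(c) > 0]
    named.append(("intercept", np.ones(len(df))))
    X = np.column_stack([c for _, c in named])
    if len(y) < X.shape[1]:
        raise FitError(f"need at least {X.shape[1]} observations, got {len(y)}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(f"rank-deficient design (rank {rank} of {X.shape[1]}); "
                       f"columns: {[n for n, _ in named]}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef = dict(zip((n for n, _ in named), beta))
    return CurveModel("quadratic", float(coef["age^2"]), float(coef["age"]),
                      float(coef.get("sex", 0.0)), float(coef.get("hand", 0.0)),
                      float(coef["intercept"]), includes_hand=includes_hand,
                      seed=seed)


def _exp_predict(theta: np.ndarray, age, sex, hand, free: tuple):
    a0, a1 = theta[0], theta[1]
    i = 2
    a2 = a3 = 0.0
    if "sex" in free:
        a2 = theta[i]
        i += 1
    if "hand" in free:
        a3 = theta[i]
        i += 1
    a4 = theta[i]
    with np.errstate(over="ignore"):
        growth = np.exp(np.clip(a1 * age, -700.0, 700.0))
    return a0 * growth + a2 * sex + a3 * hand + a4


def fit_exponential(df: pd.DataFrame, init=None, includes_hand: bool = True,
                    config: Optional[FitConfig] = None,
                    seed: Optional[int] = None) -> CurveModel:
    """Nonlinear least squares for the exponential family.

    ``init`` is ``(a0_init, a1_init, a4_init)``; if omitted it is computed
    from the data with :func:`foss_initial_estimates` (the exponential fit is
    sensitive to its starting point, so a good initial estimate matters).
    """
    config = config or FitConfig()
    age = df["age"].to_numpy(float)
    sex = df["sex"].to_numpy(float)
    hand = df["hand"].to_numpy(float)
    y = df["value"].to_numpy(float)
    if init is None:
        init = foss_initial_estimates(age, y)
    a0i, a1i, a4i = init
    # dummies constant across the cohort are unidentifiable: pin to 0
    free = tuple(n for n, c in (("sex", sex), ("hand", hand))
                 if (n != "hand" or includes_hand) and np.ptp(c) > 0)
    x0 = [a0i, a1i] + [0.0] * len(free) + [a4i]
    if len(y) < len(x0):
        raise FitError(f"need at least {len(x0)} observations, got {len(y)}")

    def resid(theta):
        r = y - _exp_predict(theta, age, sex, hand, free)
        return np.where(np.isfinite(r), r, 1e150)

    def jac(theta):
        a0, a1 = theta[0], theta[1]
        with np.errstate(over="ignore"):
            growth = np.exp(np.clip(a1 * age, -700.0, 700.0))
        cols = [-growth, -a0 * age * growth]
        if "sex" in free:
            cols.append(-sex)
        if "hand" in free:
            cols.append(-hand)
        cols.append(-np.ones_like(age))
        J = np.column_stack(cols)
        return np.where(np.isfinite(J), J, 0.0)

    res = least_squares(
        resid, x0, jac=jac, method="lm",
        ftol=config.convergence_tolerance, xtol=1e-12, gtol=1e-12,
        max_nfev=config.max_iterations,
    )
    if not np.all(np.isfinite(res.x)):
        raise FitError(f"exponential fit diverged: theta={res.x}")
    theta = res.x
    a0, a1 = theta[0], theta[1]
    i = 2
    a2 = a3 = 0.0
    if "sex" in free:
        a2 = theta[i]
        i += 1
    if "hand" in free:
        a3 = theta[i]
        i += 1
    a4 = theta[i]
    return CurveModel("exponential", float(a0), float(a1), float(a2), float(a3),
                      float(a4), includes_hand=includes_hand, seed=seed,
                      converged=bool(res.status > 0))


def predict(model: CurveModel, age, sex=0, hand=0):
    """Evaluate the fitted curve at the given covariates."""
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    hand = np.asarray(hand, dtype=float)
    if model.family == "exponential":
        base = model.a0 * np.exp(model.a1 * age)
    elif model.family == "quadratic":
        base = model.a0 * age**2 + model.a1 * age
    else:
        raise ValueError(f"unknown family {model.family!r}")
    out = base + model.a2 * sex + model.a3 * hand + model.a4
    return float(out) if out.ndim == 0 else out


def cv_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded permutation split into k near-equal index groups."""
    if k < 2:
        raise ValueError("k_folds must be >= 2")
    if k > n:
        raise ValueError(f"k_folds {k} exceeds n {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(g) for g in np.array_split(perm, k)]


def heldout_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R² = 1 − SSE/SST on a held-out fold (can be negative on a bad fold)."""
    sse = float(np.sum((y_true - y_pred) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if sse < 1e-12 else float("-inf")
    return 1.0 - sse / sst


def kfold_cv_fit(df: pd.DataFrame, config: FitConfig, family: str,
                 includes_hand: bool = True) -> CurveModel:
    """K-fold cross-validated fit: return the fold model with best held-out R².

    Each of the k folds is held out once; its model is trained on the
    remaining k−1 folds and scored by R² on the held-out fold. The winner is
    the fold model with maximal held-out R² (ties broken by lowest fold
    index; folds that fail to fit are excluded from the contest). The winner
    is returned as-is, not refit on the full data.
    """
    n = len(df)
    folds = cv_folds(n, config.k_folds, config.seed)
    df = df.reset_index(drop=True)

    models: list[Optional[CurveModel]] = []
    scores: list[float] = []
    for test_idx in folds:
        train = df.drop(index=test_idx)
        test = df.loc[test_idx]
        try:
            if family == "quadratic":
                m = fit_quadratic(train, includes_hand, seed=config.seed)
            elif family == "exponential":
                m = fit_exponential(train, includes_hand=includes_hand,
                                    config=config, seed=config.seed)
            else:
                raise ValueError(f"unknown family {family!r}")
            r2 = heldout_r2(test["value"].to_numpy(float),
                            np.asarray(predict(m, test["age"].to_numpy(float),
                                               test["sex"].to_numpy(float),
                                               test["hand"].to_numpy(float))))
        except (FitError, np.linalg.LinAlgError):
            m, r2 = None, float("nan")
        models.append(m)
        scores.append(r2)

    valid = [i for i, m in enumerate(models) if m is not None and np.isfinite(scores[i])]
    if not valid:
        raise FitError("every cross-validation fold failed to fit")
    best = max(valid, key=lambda i: (scores[i], -i))
    winner = models[best]
    winner.test_r2 = float(scores[best])
    winner.fold_r2 = [float(s) for s in scores]
    winner.best_fold = int(best)
    return winner
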