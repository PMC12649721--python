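"""Normality gating: sigma-clipping, Shapiro–Wilk with a moment-based
relaxation, and the shift-then-transform ladder.

The z-scores feeding a normative band must be close enough to normal for
the ±1.96·s band to mean 95%. The gate runs three rounds of 3σ clipping
(so isolated extreme points cannot dominate the normality test), then a
Shapiro–Wilk test. Distributions that fail Shapiro–Wilk but have |skew|
< 0.6 and Pearson kurtosis between 2.4 and 3.6 are accepted as "normal
enough" — at these sample sizes Shapiro–Wilk rejects deviations too small
to matter for a 95% band. If the gate still fails, the response is shifted
to a minimum of exactly 1 (subtract the minimum, add one) and the log,
square-root and reciprocal transforms are tried; each candidate reruns the
entire pipeline in its own transformed space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np
from scipy import stats

__all__ = [
    "OutlierReport",
    "NormalityVerdict",
    "TransformSpec",
    "TRANSFORM_KINDS",
    "remove_outliers",
    "normality_assess",
    "normal_enough",
    "apply_transform",
    "invert_transform",
    "choose_transform",
]

TRANSFORM_KINDS = ("none", "log", "sqrt", "inverse")

SHAPIRO_MAX_N = 5000


@dataclass
class OutlierReport:
    """Indices flagged in each of the three sigma-clipping rounds.

    ``round_flagged[i]`` holds the indices newly flagged in round i; flags
    accumulate, so the sets of cumulative flags are nested by construction.
    ``retained`` is the boolean mask of surviving observations.
    """

    round_flagged: list
    retained: np.ndarray
    rounds: int = 3

    @property
    def flagged(self) -> np.ndarray:
        if not any(len(r) for r in self.round_flagged):
            return np.array([], dtype=int)
        return np.sort(np.concatenate([np.asarray(r, dtype=int)
                                       for r in self.round_flagged]))

    def to_dict(self) -> dict:
        return {
            "round_flagged": [[int(i) for i in r] for r in self.round_flagged],
            "n": int(self.retained.size),
            "rounds": self.rounds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OutlierReport":
        retained = np.ones(d["n"], dtype=bool)
        for r in d["round_flagged"]:
            retained[np.asarray(r, dtype=int)] = False
        return cls([list(r) for r in d["round_flagged"]], retained, d["rounds"])


def remove_outliers(z, rounds: int = 3, n_sd: float = 3.0) -> OutlierReport:
    """Iterative sigma clipping of z-scores.

    Each round recomputes the mean and standard deviation over the currently
    retained points and flags any point more than ``n_sd`` standard
    deviations from that mean; exactly ``rounds`` rounds run regardless of
    whether new points are flagged. A round with zero standard deviation
    flags nothing.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 4:
        raise ValueError("need at least 4 points for outlier removal")
    retained = np.ones(z.size, dtype=bool)
    round_flagged = []
    for _ in range(rounds):
        kept = z[retained]
        sd = kept.std(ddof=1)
        if sd == 0.0:
            round_flagged.append([])
            continue
        mean = kept.mean()
        new = retained & (np.abs(z - mean) > n_sd * sd)
        round_flagged.append(np.flatnonzero(new).tolist())
        retained &= ~new
    return OutlierReport(round_flagged, retained, rounds=rounds)


@dataclass
class NormalityVerdict:
    """Outcome of the normality gate on a set of z-scores.

    Kurtosis uses the Pearson convention (normal = 3). ``final_pass`` is
    true when either the Shapiro–Wilk test passes or the moments fall in the
    "normal enough" window.
    """

    shapiro_p: float
    skew: float
    kurtosis: float
    passed_shapiro: bool
    normal_enough: bool
    n: int = 0

    @property
    def final_pass(self) -> bool:
        return self.passed_shapiro or self.normal_enough

    def to_dict(self) -> dict:
        return {
            "shapiro_p": self.shapiro_p, "skew": self.skew,
            "kurtosis": self.kurtosis, "passed_shapiro": self.passed_shapiro,
            "normal_enough": self.normal_enough, "final_pass": self.final_pass,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalityVerdict":
        return cls(d["shapiro_p"], d["skew"], d["kurtosis"],
                   d["passed_shapiro"], d["normal_enough"], d.get("n", 0))


def normal_enough(skew: float, kurtosis: float,
                  skew_limit: float = 0.6,
                  kurtosis_window: tuple = (2.4, 3.6)) -> bool:
    """Moment-based relaxation: |skew| < 0.6 and kurtosis in (2.4, 3.6)."""
    lo, hi = kurtosis_window
    return abs(skew) < skew_limit and lo < kurtosis < hi


def normality_assess(z, alpha: float = 0.05, skew_limit: float = 0.6,
                     kurtosis_window: tuple = (2.4, 3.6),
                     subsample_seed: int = 0) -> NormalityVerdict:
    """Shapiro–Wilk test plus skew/kurtosis on (outlier-cleaned) z-scores.

    Shapiro–Wilk is only calibrated up to n = 5000; larger samples are
    tested on a seeded subsample of 5000 while the moments use all points.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 3:
        raise ValueError("normality assessment needs at least 3 points")
    test_sample = z
    if z.size > SHAPIRO_MAX_N:
        rng = np.random.default_rng(subsample_seed)
        test_sample = rng.choice(z, size=SHAPIRO_MAX_N, replace=False)
    p = float(stats.shapiro(test_sample).pvalue)
    skew = float(stats.skew(z))
    kurt = float(stats.kurtosis(z, fisher=False))  # Pearson: normal = 3
    return NormalityVerdict(
        shapiro_p=p, skew=skew, kurtosis=kurt,
        passed_shapiro=p > alpha,
        normal_enough=normal_enough(skew, kurt, skew_limit, kurtosis_window),
        n=int(z.size),
    )


@dataclass(frozen=True)
class TransformSpec:
    """A variance-stabilising transform with its recorded shift.

    ``shift`` is the minimum of the original values; every transform input
    is ``value − shift + 1``, which has minimum exactly 1 so all three
    transforms are real and finite. The reciprocal transform reverses order.
    """

    kind: str = "none"
    shift: float = 0.0

    def forward(self, values):
        v = np.asarray(values, dtype=float)
        if self.kind == "none":
            return v
        shifted = v - self.shift + 1.0
        if self.kind == "log":
            return np.log(shifted)
        if self.kind == "sqrt":
            return np.sqrt(shifted)
        if self.kind == "inverse":
            return 1.0 / shifted
        raise ValueError(f"unknown transform {self.kind!r}")

    def inverse(self, transformed):
        t = np.asarray(transformed, dtype=float)
        if self.kind == "none":
            return t
        if self.kind == "log":
            shifted = np.exp(t)
        elif self.kind == "sqrt":
            shifted = t**2
        elif self.kind == "inverse":
            shifted = 1.0 / t
        else:
            raise ValueError(f"unknown transform {self.kind!r}")
        return shifted + self.shift - 1.0

    @property
    def order_reversing(self) -> bool:
        return self.kind == "inverse"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "shift": self.shift}

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        return cls(d["kind"], d["shift"])


def apply_transform(values, kind: str):
    """Shift values to a minimum of 1, then apply the named transform.

    Returns ``(transformed, TransformSpec)``; the spec records the shift so
    the transform is invertible. ``kind="none"`` records a zero shift and
    returns the values unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot transform an empty value list")
    if kind not in TRANSFORM_KINDS:
        raise ValueError(f"unknown transform {kind!r}; choose from {TRANSFORM_KINDS}")
    spec = TransformSpec(kind, float(v.min()) if kind != "none" else 0.0)
    return spec.forward(v), spec


def invert_transform(transformed, spec: TransformSpec):
    """Map transformed values back to the original scale."""
    return spec.inverse(transformed)


def choose_transform(candidates: dict) -> str:
    """Transform selection rule, applied after the untransformed pipeline
    failed the gate.

    ``candidates`` maps each transform kind in {log, sqrt, inverse} to a
    ``(final_pass, test_r2)`` pair (kinds whose pipeline failed to fit are
    simply absent). The transform with normally distributed z-scores wins;
    among several passing transforms the one with the highest held-out R²
    wins; if none pass, the untransformed models are kept for simplicity.
    """
    passing = {k: r2 for k, (ok, r2) in candidates.items() if ok}
    if not passing:
        return "none"
    # deterministic among equal R²: ladder order log, sqrt, inverse
    order = {k: i for i, k in enumerate(("log", "sqrt", "inverse"))}
    return max(passing, key=lambda k: (passing[k], -order.get(k, 99)))
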