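"""End-to-end pipeline: cohort slice → serializable normative model.

Stage order for each performance parameter:

1. choose the curve family from the sign of the values,
2. 10-fold cross-validated mean-curve fit (log-linearised initial
   estimates for the exponential family),
3. linear absolute-residual model, same cross-validation contest,
4. z-scores via the unbiased age-specific spread,
5. three rounds of 3σ outlier removal on the z-scores,
6. Shapiro–Wilk + "normal enough" gate on the retained z-scores,
7. if the gate fails: rerun 1–6 under the log, square-root and reciprocal
   transforms (values shifted to a minimum of 1) and keep the passing
   variant with the best held-out R², or the untransformed models if none
   pass.

Every random step derives from the single pipeline seed; the audit log
records each fold R², outlier round, gate verdict and transform decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .fitting import FitError, kfold_cv_fit, select_family
from .gate import (OutlierReport, TransformSpec, apply_transform,
                   choose_transform, normality_assess, remove_outliers)
from .ranges import DEFAULT_CODING, NormativeModel
from .variability import compute_residuals, fit_residual_model, z_scores

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class VariantResult:
    """One transform variant's full fitted pipeline."""
    kind: str
    transform: TransformSpec
    curve: object
    residual: object
    outliers: OutlierReport
    verdict: object
    zset: pd.DataFrame


@dataclass
class PipelineResult:
    model: NormativeModel
    zscores: pd.DataFrame
    chosen: str
    variants: dict
    log: list = field(default_factory=list)

    def gate_report(self) -> dict:
        """Per-variant gate summary (JSON-ready)."""
        rep = {}
        for kind, v in self.variants.items():
            rep[kind] = {
                "shapiro_p": v.verdict.shapiro_p,
                "skew": v.verdict.skew,
                "kurtosis": v.verdict.kurtosis,
                "final_pass": v.verdict.final_pass,
                "test_r2": v.curve.test_r2,
                "chosen": kind == self.chosen,
                "outlier_indices": [int(i) for i in v.outliers.flagged],
            }
        return rep


def _run_variant(df: pd.DataFrame, kind: str, config: PipelineConfig,
                 includes_hand: bool, log: list) -> VariantResult:
    values = df["value"].to_numpy(float)
    transformed, tspec = apply_transform(values, kind)
    work = df.copy()
    work["value"] = transformed

    family = select_family(transformed)
    log.append({"event": "family_selected", "variant": kind, "family": family})

    curve = kfold_cv_fit(work, config.fit_config(), family, includes_hand)
    log.append({"event": "curve_fit", "variant": kind, "family": family,
                "fold_r2": curve.fold_r2, "best_fold": curve.best_fold,
                "test_r2": curve.test_r2})

    resid = compute_residuals(curve, work)
    ages = work["age"].to_numpy(float)
    resmodel = fit_residual_model(
        ages, np.abs(resid), config.fit_config(), curve.n_params,
        value_range=float(transformed.max() - transformed.min()),
        line_dof=0 if config.scaling_dof_curve_only else 2,
        root_inside=config.scaling_root_inside,
    )
    log.append({"event": "residual_fit", "variant": kind,
                "intercept": resmodel.intercept, "slope": resmodel.slope,
                "fold_r2": resmodel.fold_r2, "test_r2": resmodel.test_r2})

    from .variability import scale_factor
    s = scale_factor(resmodel, ages)
    z = z_scores(resid, resmodel, ages)
    report = remove_outliers(z, rounds=config.outlier_rounds, n_sd=config.outlier_sd)
    for i, flagged in enumerate(report.round_flagged):
        log.append({"event": "outlier_round", "variant": kind, "round": i + 1,
                    "flagged": [int(j) for j in flagged]})
    verdict = normality_assess(
        z[report.retained], alpha=config.shapiro_alpha,
        skew_limit=config.skew_limit, kurtosis_window=config.kurtosis_window,
        subsample_seed=config.seed,
    )
    log.append({"event": "normality", "variant": kind,
                "shapiro_p": verdict.shapiro_p, "skew": verdict.skew,
                "kurtosis": verdict.kurtosis, "final_pass": verdict.final_pass})

    zset = pd.DataFrame({
        "participant_id": df["participant_id"].to_numpy(),
        "hand": df["hand"].to_numpy(),
        "age": ages,
        "residual": resid,
        "s": np.asarray(s, dtype=float),
        "z": z,
        "retained": report.retained,
    })
    return VariantResult(kind, tspec, curve, resmodel, report, verdict, zset)


def run_pipeline(df: pd.DataFrame, parameter: str,
                 config: Optional[PipelineConfig] = None,
                 includes_hand: bool = True) -> PipelineResult:
    """Build a normative model for one parameter of a long-format cohort."""
    config = config or PipelineConfig()
    part = df[df["parameter"] == parameter].reset_index(drop=True)
    if part.empty:
        raise ValueError(f"parameter {parameter!r} not present in the cohort")
    log: list = [{"event": "start", "parameter": parameter, "n": len(part),
                  "seed": config.seed, "config_hash": config.config_hash()}]

    variants = {"none": _run_variant(part, "none", config, includes_hand, log)}
    if variants["none"].verdict.final_pass:
        chosen = "none"
        log.append({"event": "transform_decision", "chosen": "none",
                    "reason": "untransformed z-scores passed the gate"})
    else:
        candidates = {}
        for kind in ("log", "sqrt", "inverse"):
            try:
                variants[kind] = _run_variant(part, kind, config, includes_hand, log)
                candidates[kind] = (variants[kind].verdict.final_pass,
                                    variants[kind].curve.test_r2)
            except (FitError, ValueError) as exc:
                log.append({"event": "variant_failed", "variant": kind,
                            "error": str(exc)})
        chosen = choose_transform(candidates)
        log.append({"event": "transform_decision", "chosen": chosen,
                    "candidates": {k: {"final_pass": v[0], "test_r2": v[1]}
                                   for k, v in candidates.items()}})

    win = variants[chosen]
    ages = part["age"].to_numpy(float)
    model = NormativeModel(
        curve=win.curve,
        residual=win.residual,
        transform=win.transform,
        gate=win.verdict,
        outliers=win.outliers,
        coding=DEFAULT_CODING,
        provenance={
            "parameter": parameter,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_obs": int(len(part)),
            "age_range": [float(ages.min()), float(ages.max())],
            "includes_hand": includes_hand,
            "devnorm_version": __version__,
        },
    )
    return PipelineResult(model=model, zscores=win.zset, chosen=chosen,
                          variants=variants, log=log)
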