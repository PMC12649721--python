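"""Reference synthetic scenarios emulating a developmental Kinarm cohort.

These presets define the study conditions used throughout the validation
suite: a 288-participant cohort aged 5–18 (mean ≈ 13 y, SD ≈ 3.2 y, about
two boys per girl) and ground-truth parameters whose mean trends and
age-varying noise reproduce the headline behaviour of typical robotic
task parameters:

* ``reaction_time`` (s, unimanual): decaying exponential, ≈54% faster by
  age 18, with a 95% normative band shrinking from ≈0.268 s at age 5 to
  ≈0.0685 s at 18 (≈74% decrease). Both hands observed per participant.
* ``path_length_ratio`` (unitless, unimanual): decaying exponential, ≈20%
  decrease, band shrinking ≈0.687 → ≈0.187.
* ``total_hits`` (count, bimanual): increasing exponential with a +8-ball
  male offset; band nearly constant (≈82 → ≈87 hits). One observation per
  participant, no hand covariate.
* ``movement_area_bias`` (unitless, bimanual): shallow quadratic crossing
  zero, so the quadratic family is exercised.

Noise intercept/slope values are expected absolute deviations m(age); the
corresponding 95% band width is 2·1.96·√(π/2)·m(age).
"""

from __future__ import annotations

from .simulate import Demographics, GroundTruthSpec

__all__ = ["study_demographics", "STUDY_TRUTHS", "scenario_dict"]


def study_demographics(n_participants: int = 288, seed: int = 0) -> Demographics:
    """Demographics of the emulated cohort (defaults are the study conditions)."""
    return Demographics(n_participants=n_participants, age_min=5.0, age_max=18.0,
                        age_mean=13.0, age_sd=3.2, male_fraction=0.66, seed=seed)


STUDY_TRUTHS: dict[str, GroundTruthSpec] = {
    "reaction_time": GroundTruthSpec(
        family="exponential",
        a0=0.85, a1=-0.2083, a2=0.01, a3=0.005, a4=0.22,
        noise_intercept=0.0702, noise_slope=-0.00313,
        noise_shape="normal", per_hand=True,
    ),
    "path_length_ratio": GroundTruthSpec(
        family="exponential",
        a0=0.743, a1=-0.1238, a2=0.01, a3=0.01, a4=1.2,
        noise_intercept=0.1791, noise_slope=-0.00784,
        noise_shape="normal", per_hand=True,
    ),
    "total_hits": GroundTruthSpec(
        family="exponential",
        a0=50.0, a1=0.09, a2=8.0, a3=0.0, a4=30.0,
        noise_intercept=16.3, noise_slope=0.078,
        noise_shape="normal", per_hand=False,
    ),
    "movement_area_bias": GroundTruthSpec(
        family="quadratic",
        a0=0.0008, a1=-0.025, a2=0.005, a3=0.0, a4=0.12,
        noise_intercept=0.06, noise_slope=-0.002,
        noise_shape="normal", per_hand=False,
    ),
}


def scenario_dict() -> dict:
    """YAML-ready scenario (demographics + per-parameter ground truth)."""
    demo = study_demographics()
    return {
        "demographics": {
            "n_participants": demo.n_participants,
            "age_min": demo.age_min, "age_max": demo.age_max,
            "age_mean": demo.age_mean, "age_sd": demo.age_sd,
            "male_fraction": demo.male_fraction,
        },
        "parameters": {
            name: {
                "family": t.family,
                "a0": t.a0, "a1": t.a1, "a2": t.a2, "a3": t.a3, "a4": t.a4,
                "noise_intercept": t.noise_intercept,
                "noise_slope": t.noise_slope,
                "noise_shape": t.noise_shape,
                "per_hand": t.per_hand,
            }
            for name, t in STUDY_TRUTHS.items()
        },
    }
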