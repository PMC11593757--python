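"""Canned synthetic scenarios used by the test-bench and the examples.

All scenarios cover the full study window (November 2018 to March 2024).
The calibration-bench scenarios track a single BP-like factor at a
baseline of 0.115 measurements per person-month — the order of magnitude
of monthly blood-pressure recording in English primary care — with
moderate seasonality (log-amplitude 0.10), overdispersion phi = 1.5 and
roughly 30,000 eligible persons out of 40,000 generated (the remainder
are curation contaminants, mostly under-18s).
"""

from __future__ import annotations

import math

from .synth import ContaminantProbs, Disruption, ScenarioConfig

__all__ = [
    "demo_scenario",
    "null_scenario",
    "sustained_disruption_scenario",
]


def _single_factor_base(seed: int, **overrides) -> ScenarioConfig:
    kwargs = dict(
        n_persons=40_000,
        baseline_log_rate={"bp": math.log(0.115)},
        seasonal_amplitude={"bp": 0.10},
        seasonal_phase={"bp": 10.0},
        dispersion_phi=1.5,
        dup_prob=0.05,
        valueless_prob=0.05,
        contaminants=ContaminantProbs(),
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def null_scenario(seed: int = 0) -> ScenarioConfig:
    """No-disruption scenario (depth 1) with a mild declining trend.

    Used to check that observed post-March-2020 rates stay inside the
    composite expectation band at (at least) its nominal coverage.
    """
    return _single_factor_base(
        seed,
        annual_trend=-0.02,
        disruption={"bp": Disruption(depth=1.0)},
    )


def sustained_disruption_scenario(seed: int = 0, depth: float = 0.8) -> ScenarioConfig:
    """Sustained multiplicative disruption (default -20%) from March 2020.

    The long-term trend is zero so the continued- and frozen-trend
    counterfactuals coincide in expectation and the band midpoint targets
    the undisrupted level; the injected depth is then identified by the
    period relative deviation.
    """
    return _single_factor_base(
        seed,
        annual_trend=0.0,
        disruption={
            "bp": Disruption(
                depth=depth, half_life=math.inf, post_offset=depth - 1.0
            )
        },
    )


def demo_scenario(seed: int = 0, n_persons: int = 20_000) -> ScenarioConfig:
    """All twelve factors with a realistic drop-and-recovery disruption.

    BP recovers only partially (long-run level 16% below the pre-pandemic
    projection); most other factors recover fully within roughly a year;
    alcohol overshoots slightly, mimicking post-pandemic catch-up.
    """
    disruption = {}
    for factor in ScenarioConfig().baseline_log_rate:
        disruption[factor] = Disruption(depth=0.35, half_life=6.0, post_offset=0.0)
    disruption["bp"] = Disruption(depth=0.30, half_life=10.0, post_offset=-0.16)
    disruption["fasting_glucose"] = Disruption(depth=0.30, half_life=14.0, post_offset=-0.25)
    disruption["alcohol"] = Disruption(depth=0.40, half_life=6.0, post_offset=0.08)
    disruption["hba1c"] = Disruption(depth=0.35, half_life=5.0, post_offset=0.05)
    return ScenarioConfig(
        n_persons=n_persons,
        annual_trend=-0.02,
        disruption=disruption,
        seed=seed,
    )
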