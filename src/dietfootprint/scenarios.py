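"""Counterfactual reduced-consumption scenarios by marginal standardisation.

Three "first-quintile" scenarios ask what the national mean footprint
intensity would be if every stratum purchased like the lowest quintile
of ultra-processed-food energy share (S1), of beef energy share (S2), or
of both (S3).  A joint main-effects model — both quintile indicator
sets plus the adjustment covariates, no interaction, justified when the
Wald interaction test is non-significant — is fitted by expansion-
weighted least squares.  Each scenario then overwrites the relevant
quintile indicator(s) with 1 for every stratum, keeps covariates at
their observed values, and averages the predictions with the expansion
weights (G-computation).  The baseline is the weighted mean of fitted
values on the observed data, which for WLS with an intercept equals the
weighted mean observed outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .accounting import StratumDietSummary
from .association import (
    OUTCOMES,
    QuintileAssignment,
    _fit_wls,
    _formula,
    build_analysis_frame,
)
from .reference_tables import StratumProfile

SCENARIOS = ("baseline", "S1_upf_q1", "S2_beef_q1", "S3_both_q1")


@dataclass(frozen=True)
class ScenarioResult:
    """Predicted national mean intensities for one scenario.

    Percent changes are relative to the baseline row of the same run;
    negative means a reduction.  The baseline row carries 0.
    """

    scenario: str
    carbon_per_1000kcal: float
    water_per_1000kcal: float
    pct_change_carbon: float
    pct_change_water: float


def percent_change(baseline_value: float, scenario_value: float) -> float:
    """Signed percent change of a scenario value versus baseline."""
    if baseline_value <= 0:
        raise ValueError(
            f"baseline value must be strictly positive, got {baseline_value}"
        )
    return (scenario_value - baseline_value) / baseline_value * 100.0


def _scenario_means(
    summaries: Sequence[StratumDietSummary],
    beef_assignment: Sequence[QuintileAssignment],
    upf_assignment: Sequence[QuintileAssignment],
    profiles: Sequence[StratumProfile],
    outcome: str,
    with_interaction: bool,
    log_income: bool,
) -> dict[str, float]:
    frame = build_analysis_frame(
        summaries, profiles, {"beef": beef_assignment, "upf": upf_assignment}
    )
    joiner = " * " if with_interaction else " + "
    exposure_term = joiner.join(
        ["C(beef_q, Treatment(1))", "C(upf_q, Treatment(1))"]
    )
    formula = _formula(outcome, [exposure_term], "adjusted", log_income)
    result = _fit_wls(frame, formula)
    weights = frame["expansion_weight"].to_numpy(dtype=float)
    weights = weights / weights.sum()

    def averaged(data) -> float:
        return float(np.average(np.asarray(result.predict(data)), weights=weights))

    return {
        "baseline": averaged(frame),
        "S1_upf_q1": averaged(frame.assign(upf_q=1)),
        "S2_beef_q1": averaged(frame.assign(beef_q=1)),
        "S3_both_q1": averaged(frame.assign(beef_q=1, upf_q=1)),
    }


def predict_scenarios(
    summaries: Sequence[StratumDietSummary],
    beef_assignment: Sequence[QuintileAssignment],
    upf_assignment: Sequence[QuintileAssignment],
    profiles: Sequence[StratumProfile],
    with_interaction: bool = False,
    log_income: bool = False,
) -> list[ScenarioResult]:
    """Predict the four scenario rows for both footprint intensities."""
    carbon = _scenario_means(
        summaries, beef_assignment, upf_assignment, profiles,
        OUTCOMES[0], with_interaction, log_income,
    )
    water = _scenario_means(
        summaries, beef_assignment, upf_assignment, profiles,
        OUTCOMES[1], with_interaction, log_income,
    )
    results = []
    for scenario in SCENARIOS:
        results.append(
            ScenarioResult(
                scenario=scenario,
                carbon_per_1000kcal=carbon[scenario],
                water_per_1000kcal=water[scenario],
                pct_change_carbon=(
                    0.0
                    if scenario == "baseline"
                    else percent_change(carbon["baseline"], carbon[scenario])
                ),
                pct_change_water=(
                    0.0
                    if scenario == "baseline"
                    else percent_change(water["baseline"], water[scenario])
                ),
            )
        )
    return results
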