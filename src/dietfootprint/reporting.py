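"""Emission of the paper-shaped output tables.

All internal math is full precision; percentages, ratios and percent
changes are rounded to 1 decimal place only here, at the reporting
boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import association, scenarios as scenario_mod
from .accounting import StratumDietSummary, summaries_frame
from .association import QuintileAssignment
from .reference_tables import StratumProfile

_ROUND1 = (
    "pct_energy",
    "pct_carbon",
    "pct_water",
    "ratio_carbon",
    "ratio_water",
    "pct_change_vs_baseline",
)


def round_report(frame: pd.DataFrame) -> pd.DataFrame:
    """Round the reporting columns to 1 decimal place."""
    out = frame.copy()
    for col in out.columns:
        if col in _ROUND1:
            out[col] = out[col].round(1)
    return out


def write_contributions(table: pd.DataFrame, path: str | Path) -> None:
    """Write the Nova contribution table (group/subgroup/total-beef shares)."""
    round_report(table).to_csv(path, index=False)


def write_stratum_summaries(
    summaries: Sequence[StratumDietSummary], path: str | Path
) -> None:
    summaries_frame(summaries).to_csv(path, index=False)


def quintile_means_table(
    summaries: Sequence[StratumDietSummary],
    profiles: Sequence[StratumProfile],
    weighted: bool = True,
    log_income: bool = False,
) -> pd.DataFrame:
    """Quintile means for both exposures x outcomes x adjustments.

    One row per quintile with the predictive-margin mean, its robust
    SE, the trend p-value of the block, and the weighted mean exposure
    share within the quintile (the survey's quintile description).
    """
    rows = []
    for exposure in association.EXPOSURES:
        assignment = association.assign_weighted_quintiles(
            summaries, profiles, exposure, weighted=weighted
        )
        for outcome in association.OUTCOMES:
            for adjustment in association.ADJUSTMENTS:
                fit = association.fit_quintile_model(
                    summaries, assignment, profiles, outcome, adjustment, log_income
                )
                p_trend = association.trend_test(
                    summaries, assignment, profiles, outcome, adjustment, log_income
                )
                exposure_means = _exposure_means(assignment, profiles)
                for i, level in enumerate(fit.quintile_levels):
                    rows.append(
                        {
                            "exposure": exposure,
                            "outcome": outcome,
                            "adjustment": adjustment,
                            "quintile": int(level),
                            "mean": fit.adjusted_means[i],
                            "se": fit.margin_se[i],
                            "exposure_share_pct": exposure_means[int(level)],
                            "p_trend": p_trend,
                            "n_strata": fit.n_strata,
                        }
                    )
    return pd.DataFrame(rows)


def _exposure_means(
    assignment: Sequence[QuintileAssignment], profiles: Sequence[StratumProfile]
) -> dict[int, float]:
    weight_of = {p.stratum_id: p.expansion_weight for p in profiles}
    frame = pd.DataFrame(
        {
            "quintile": [a.quintile for a in assignment],
            "value": [a.exposure_value for a in assignment],
            "w": [weight_of[a.stratum_id] for a in assignment],
        }
    )
    grouped = frame.groupby("quintile").apply(
        lambda g: (g["value"] * g["w"]).sum() / g["w"].sum(), include_groups=False
    )
    return {int(q): float(v) for q, v in grouped.items()}


def write_quintile_means(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def scenarios_table(results: Sequence[scenario_mod.ScenarioResult]) -> pd.DataFrame:
    """Long-format scenario table: one row per scenario x outcome."""
    rows = []
    for result in results:
        rows.append(
            {
                "scenario": result.scenario,
                "outcome": "carbon_per_1000kcal",
                "predicted_mean": result.carbon_per_1000kcal,
                "pct_change_vs_baseline": result.pct_change_carbon,
            }
        )
    for result in results:
        rows.append(
            {
                "scenario": result.scenario,
                "outcome": "water_per_1000kcal",
                "predicted_mean": result.water_per_1000kcal,
                "pct_change_vs_baseline": result.pct_change_water,
            }
        )
    return pd.DataFrame(rows)


def write_scenarios(table: pd.DataFrame, path: str | Path) -> None:
    round_report(table).to_csv(path, index=False)


def plot_scenarios(table: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of predicted intensities by scenario, one panel per footprint."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    labels = {
        "carbon_per_1000kcal": "gCO2eq / 1000 kcal",
        "water_per_1000kcal": "litres / 1000 kcal",
    }
    for ax, (outcome, ylabel) in zip(axes, labels.items()):
        sub = table[table["outcome"] == outcome]
        ax.bar(sub["scenario"], sub["predicted_mean"], color="#4878a8")
        ax.set_ylabel(ylabel)
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
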