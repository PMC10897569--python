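"""Quintile construction and survey-weighted regression models.

The exposures are the percentage of dietary energy from beef items and
from ultra-processed foods, cut into expansion-weight-weighted quintiles
across strata.  Footprint intensity per 1000 kcal is regressed on
quintile indicators by weighted least squares (weights = expansion
weights), crude or adjusted for income, area of residence, macro-region
and the out-of-home expenditure share.  Standard errors are
heteroskedasticity-robust (HC3 sandwich) throughout — the closest
desk-scale analogue of survey-weighted (pweight) estimation; full
design-based linearised variance is out of scope.

Adjusted quintile means are population-averaged predictive margins: set
every stratum to quintile q, keep its observed covariates, predict, and
average the predictions with the expansion weights.  The trend test
refits the model with the integer quintile score 1-5 in place of the
indicator set and reports the robust two-sided p-value of the score
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .accounting import StratumDietSummary, summaries_frame
from .reference_tables import StratumProfile

OUTCOMES = ("carbon_per_1000kcal", "water_per_1000kcal")
EXPOSURES = ("beef", "upf")
ADJUSTMENTS = ("crude", "adjusted")
N_QUINTILES = 5

_EXPOSURE_COLUMN = {"beef": "pct_energy_beef", "upf": "pct_energy_upf"}
_COVARIATE_TERMS = (
    "{income}",
    "C(area, Treatment('urban'))",
    "C(region, Treatment('Southeast'))",
    "out_of_home_share",
)


@dataclass(frozen=True)
class QuintileAssignment:
    """One stratum's quintile (1-5) of one exposure's energy share."""

    stratum_id: str
    exposure: str
    quintile: int
    exposure_value: float


@dataclass
class ModelFit:
    """A fitted quintile model with predictive margins.

    ``adjusted_means[q-1]`` is the population-averaged prediction with
    every stratum set to quintile q; for the crude model these are the
    weighted quintile means.  ``params``/``cov`` use the HC3 robust
    covariance.
    """

    outcome: str
    exposure: str
    adjustment: str
    params: pd.Series
    cov: pd.DataFrame
    adjusted_means: np.ndarray
    margin_se: np.ndarray
    quintile_levels: np.ndarray
    n_strata: int
    result: object = field(repr=False, default=None)


@dataclass(frozen=True)
class WaldResult:
    """Joint Wald test of a set of coefficients (robust covariance)."""

    statistic: float
    df: int
    pvalue: float


def weighted_quintile_cuts(
    values: Sequence[float], weights: Sequence[float] | None = None, n_groups: int = 5
) -> np.ndarray:
    """Assign each value its weighted quantile group (1..n_groups).

    Cut-points sit at weighted cumulative probability 1/n, 2/n, ...
    over the values sorted ascending; tied values share the group of
    their first occurrence in sort order.  Assignments are invariant to
    rescaling all weights by a positive constant.
    """
    v = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    if len(v) < n_groups:
        raise ValueError(
            f"need at least {n_groups} observations, got {len(v)}"
        )
    if np.unique(v).size < n_groups:
        raise ValueError(
            f"only {np.unique(v).size} distinct values; cannot form {n_groups} "
            "groups — use fewer groups"
        )
    if not (w > 0).all():
        raise ValueError("weights must be strictly positive")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / w.sum()
    groups = np.ceil(cum * n_groups - 1e-9).astype(int)
    groups = np.clip(groups, 1, n_groups)
    sorted_values = v[order]
    first = np.searchsorted(sorted_values, sorted_values, side="left")
    groups = groups[first]
    out = np.empty(len(v), dtype=int)
    out[order] = groups
    return out


def assign_weighted_quintiles(
    summaries: Sequence[StratumDietSummary],
    profiles: Sequence[StratumProfile],
    exposure: str,
    weighted: bool = True,
) -> list[QuintileAssignment]:
    """Weighted quintiles of one exposure's energy share across strata.

    ``weighted=False`` gives unweighted quintiles for sensitivity
    analysis.  Strata with undefined intensity (zero energy) are still
    assigned, so the caller decides inclusion.
    """
    if exposure not in EXPOSURES:
        raise ValueError(f"exposure must be one of {EXPOSURES}, got {exposure!r}")
    column = _EXPOSURE_COLUMN[exposure]
    weight_of = {p.stratum_id: p.expansion_weight for p in profiles}
    values = [getattr(s, column) for s in summaries]
    weights = (
        [weight_of[s.stratum_id] for s in summaries] if weighted else None
    )
    groups = weighted_quintile_cuts(values, weights, N_QUINTILES)
    return [
        QuintileAssignment(
            stratum_id=s.stratum_id,
            exposure=exposure,
            quintile=int(q),
            exposure_value=float(v),
        )
        for s, q, v in zip(summaries, groups, values)
    ]


def build_analysis_frame(
    summaries: Sequence[StratumDietSummary],
    profiles: Sequence[StratumProfile],
    assignments: Mapping[str, Sequence[QuintileAssignment]] | None = None,
) -> pd.DataFrame:
    """Merge summaries, covariates, weights and quintiles; drop zero-energy strata."""
    frame = summaries_frame(summaries)
    prof = pd.DataFrame(
        {
            "stratum_id": [p.stratum_id for p in profiles],
            "expansion_weight": [p.expansion_weight for p in profiles],
            "income": [p.income for p in profiles],
            "area": [p.area for p in profiles],
            "region": [p.region for p in profiles],
            "out_of_home_share": [p.out_of_home_share for p in profiles],
        }
    )
    frame = frame.merge(prof, on="stratum_id", how="inner")
    if assignments:
        for exposure, assigned in assignments.items():
            q = {a.stratum_id: a.quintile for a in assigned}
            frame[f"{exposure}_q"] = frame["stratum_id"].map(q)
    frame = frame[frame["energy"] > 0].reset_index(drop=True)
    return frame


def _formula(outcome: str, exposure_terms: Sequence[str], adjustment: str,
             log_income: bool) -> str:
    terms = list(exposure_terms)
    if adjustment == "adjusted":
        income = "np.log(income)" if log_income else "income"
        terms += [t.format(income=income) for t in _COVARIATE_TERMS]
    elif adjustment != "crude":
        raise ValueError(f"adjustment must be one of {ADJUSTMENTS}, got {adjustment!r}")
    return f"{outcome} ~ " + " + ".join(terms)


def _check_rank(result) -> None:
    exog = result.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        r = np.abs(np.diag(np.linalg.qr(exog, mode="r")))
        bad = [
            name
            for name, d in zip(result.model.exog_names, r)
            if d < 1e-8 * r.max()
        ]
        raise ValueError(
            f"design matrix is rank deficient; collinear terms: {bad}"
        )


def _fit_wls(frame: pd.DataFrame, formula: str):
    model = smf.wls(formula, data=frame, weights=frame["expansion_weight"])
    result = model.fit(cov_type="HC3")
    _check_rank(result)
    return result


def _margins(result, frame: pd.DataFrame, qcol: str, levels: Sequence[int]):
    """Predictive margins over quintile levels with delta-method SEs."""
    design_info = result.model.data.design_info
    weights = frame["expansion_weight"].to_numpy(dtype=float)
    weights = weights / weights.sum()
    means = np.empty(len(levels))
    ses = np.empty(len(levels))
    cov = result.cov_params().to_numpy()
    for i, level in enumerate(levels):
        counterfactual = frame.assign(**{qcol: level})
        (design,) = build_design_matrices(
            [design_info], counterfactual, return_type="matrix"
        )
        g = weights @ np.asarray(design)
        means[i] = float(g @ result.params.to_numpy())
        ses[i] = float(np.sqrt(g @ cov @ g))
    return means, ses


def fit_quintile_model(
    summaries: Sequence[StratumDietSummary],
    assignment: Sequence[QuintileAssignment],
    profiles: Sequence[StratumProfile],
    outcome: str,
    adjustment: str = "adjusted",
    log_income: bool = False,
) -> ModelFit:
    """WLS of footprint intensity on quintile indicators (reference Q1).

    The adjusted model adds income, area (urban reference), region
    (Southeast reference) and out-of-home expenditure share.  Adjusted
    means are predictive margins; for the additive model, Q1's margin
    plus each quintile coefficient reproduces that quintile's margin.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    exposure = assignment[0].exposure
    qcol = f"{exposure}_q"
    frame = build_analysis_frame(summaries, profiles, {exposure: assignment})
    if frame[qcol].isna().any():
        missing = sorted(frame.loc[frame[qcol].isna(), "stratum_id"])
        raise ValueError(f"strata without quintile assignment: {missing}")
    levels = np.sort(frame[qcol].unique())
    formula = _formula(outcome, [f"C({qcol}, Treatment(1))"], adjustment, log_income)
    result = _fit_wls(frame, formula)
    means, ses = _margins(result, frame, qcol, levels)
    return ModelFit(
        outcome=outcome,
        exposure=exposure,
        adjustment=adjustment,
        params=result.params,
        cov=result.cov_params(),
        adjusted_means=means,
        margin_se=ses,
        quintile_levels=levels,
        n_strata=len(frame),
        result=result,
    )


def trend_test(
    summaries: Sequence[StratumDietSummary],
    assignment: Sequence[QuintileAssignment],
    profiles: Sequence[StratumProfile],
    outcome: str,
    adjustment: str = "adjusted",
    log_income: bool = False,
) -> float:
    """P for trend: integer quintile score 1-5 replaces the indicators.

    Returns the two-sided p-value of the score coefficient under the
    HC3 robust covariance.
    """
    exposure = assignment[0].exposure
    qcol = f"{exposure}_q"
    frame = build_analysis_frame(summaries, profiles, {exposure: assignment})
    formula = _formula(outcome, [qcol], adjustment, log_income)
    result = _fit_wls(frame, formula)
    return float(result.pvalues[qcol])


def trend_slope(
    summaries: Sequence[StratumDietSummary],
    assignment: Sequence[QuintileAssignment],
    profiles: Sequence[StratumProfile],
    outcome: str,
    adjustment: str = "adjusted",
) -> tuple[float, float]:
    """(slope per quintile, robust SE) from the integer-scored trend model."""
    exposure = assignment[0].exposure
    qcol = f"{exposure}_q"
    frame = build_analysis_frame(summaries, profiles, {exposure: assignment})
    formula = _formula(outcome, [qcol], adjustment, log_income=False)
    result = _fit_wls(frame, formula)
    return float(result.params[qcol]), float(result.bse[qcol])


def fit_exposure_model(
    summaries: Sequence[StratumDietSummary],
    profiles: Sequence[StratumProfile],
    outcome: str,
    adjustment: str = "crude",
) -> pd.DataFrame:
    """WLS of intensity on the two continuous energy shares (% points).

    Returns a frame indexed by term with ``coef``, ``se`` and the 95 %
    confidence bounds; used for parameter-recovery checks against the
    synthetic generator's closed-form slopes.
    """
    frame = build_analysis_frame(summaries, profiles)
    formula = _formula(
        outcome, ["pct_energy_beef", "pct_energy_upf"], adjustment, log_income=False
    )
    result = _fit_wls(frame, formula)
    conf = result.conf_int()
    return pd.DataFrame(
        {
            "coef": result.params,
            "se": result.bse,
            "ci_low": conf[0],
            "ci_high": conf[1],
        }
    )


def interaction_wald(
    summaries: Sequence[StratumDietSummary],
    beef_assignment: Sequence[QuintileAssignment],
    upf_assignment: Sequence[QuintileAssignment],
    profiles: Sequence[StratumProfile],
    outcome: str,
    log_income: bool = False,
) -> WaldResult:
    """Wald test that all beef x UPF quintile product terms are zero.

    Fits the joint adjusted model with both indicator sets and their 16
    products, then jointly tests the products under the robust
    covariance (F reference, the convention of survey regression
    software).
    """
    frame = build_analysis_frame(
        summaries, profiles, {"beef": beef_assignment, "upf": upf_assignment}
    )
    formula = _formula(
        outcome,
        ["C(beef_q, Treatment(1)) * C(upf_q, Treatment(1))"],
        "adjusted",
        log_income,
    )
    result = _fit_wls(frame, formula)
    product_terms = [
        name
        for name in result.params.index
        if "beef_q" in name and "upf_q" in name
    ]
    if not product_terms:
        raise ValueError("no interaction terms present in the fitted model")
    constraints = np.zeros((len(product_terms), len(result.params)))
    for i, name in enumerate(product_terms):
        constraints[i, list(result.params.index).index(name)] = 1.0
    test = result.wald_test(constraints, use_f=True, scalar=True)
    return WaldResult(
        statistic=float(test.statistic),
        df=len(product_terms),
        pvalue=float(test.pvalue),
    )
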