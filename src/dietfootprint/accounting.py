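"""Per-capita footprint accounting and Nova-group attribution.

The accounting convention follows household-budget-survey practice:

* energy is computed on the *edible* mass — the purchased quantity times
  the item's edible fraction, converted through its energy density —
  because seeds, husks and bones feed nobody;
* carbon and water footprints are computed on the *full as-purchased*
  mass, because the inedible parts are inherent to producing the edible
  fraction and their life-cycle impact is inseparable;
* 7-day household totals are divided by 7 and by the stratum's resident
  count to give per-capita daily quantities.

Per-1000-kcal intensities (footprint / energy x 1000) standardise the
footprint for diet size and are the outcome fed to the association
models.  The contribution table attributes energy and footprints across
the four Nova groups, their subgroups and total beef, and reports the
footprint/energy ratio — a group's share of a footprint divided by its
share of energy; 1 means the group's footprint is proportional to its
calories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference_tables import (
    FoodItem,
    PurchaseRecord,
    StratumProfile,
    index_items,
)

logger = logging.getLogger(__name__)

DAYS_IN_DIARY = 7.0

SUMMARY_COLUMNS = [
    "stratum_id",
    "energy",
    "carbon",
    "water",
    "pct_energy_upf",
    "pct_energy_beef",
    "carbon_per_1000kcal",
    "water_per_1000kcal",
]


@dataclass(frozen=True)
class StratumDietSummary:
    """Per-capita daily diet summary for one stratum.

    ``energy`` kcal/person-day; ``carbon`` gCO2eq/person-day; ``water``
    l/person-day; the two shares are % of energy from ultra-processed
    foods (Nova group 4) and from beef items (across groups 1, 3, 4).
    Per-1000-kcal intensities are ``None`` when the stratum has zero
    energy.
    """

    stratum_id: str
    energy: float
    carbon: float
    water: float
    pct_energy_upf: float
    pct_energy_beef: float
    carbon_per_1000kcal: float | None
    water_per_1000kcal: float | None


def item_energy(quantity_as_purchased: float, item: FoodItem) -> float:
    """Energy (kcal) of a purchased quantity: edible mass x energy density.

    quantity [kg] x edible_fraction x 1000 [g/kg] / 100 [g per density
    unit] x energy_density [kcal/100 g edible].
    """
    if quantity_as_purchased < 0:
        raise ValueError(f"quantity must be >= 0, got {quantity_as_purchased}")
    return quantity_as_purchased * item.edible_fraction * 10.0 * item.energy_density


def item_footprints(quantity_as_purchased: float, item: FoodItem) -> tuple[float, float]:
    """(gCO2eq, litres) of a purchased quantity.

    Uses the full as-purchased mass — the edible fraction is *not*
    applied, since the impact of inedible parts is inseparable from
    producing the edible ones.
    """
    if quantity_as_purchased < 0:
        raise ValueError(f"quantity must be >= 0, got {quantity_as_purchased}")
    return (
        quantity_as_purchased * item.carbon_intensity,
        quantity_as_purchased * item.water_intensity,
    )


def per_capita_daily(total_7day: float, n_residents: int) -> float:
    """Convert a 7-day stratum total into a per-person-day quantity."""
    if n_residents < 1:
        raise ValueError(f"n_residents must be >= 1, got {n_residents}")
    return total_7day / DAYS_IN_DIARY / n_residents


def summarise_stratum(
    purchases: Sequence[PurchaseRecord],
    items: Iterable[FoodItem] | Mapping[str, FoodItem],
    profile: StratumProfile,
) -> StratumDietSummary:
    """Summarise one stratum's purchases record by record.

    Energy, carbon and water are per-capita daily sums over all records;
    the exposure shares are % of energy from Nova group 4 and from beef
    items.  Zero-energy strata get ``None`` per-1000-kcal fields.
    """
    index = index_items(items)
    energy = carbon = water = 0.0
    energy_upf = energy_beef = 0.0
    for record in purchases:
        if record.stratum_id != profile.stratum_id:
            raise ValueError(
                f"purchase for stratum {record.stratum_id!r} passed to "
                f"summarise_stratum for {profile.stratum_id!r}"
            )
        item = index[record.item_code]
        e = item_energy(record.quantity, item)
        c, w = item_footprints(record.quantity, item)
        energy += e
        carbon += c
        water += w
        if item.nova_group == 4:
            energy_upf += e
        if item.is_beef:
            energy_beef += e
    energy_pc = per_capita_daily(energy, profile.n_residents)
    carbon_pc = per_capita_daily(carbon, profile.n_residents)
    water_pc = per_capita_daily(water, profile.n_residents)
    if energy > 0:
        pct_upf = energy_upf / energy * 100.0
        pct_beef = energy_beef / energy * 100.0
        carbon_1000 = carbon_pc / energy_pc * 1000.0
        water_1000 = water_pc / energy_pc * 1000.0
    else:
        pct_upf = pct_beef = 0.0
        carbon_1000 = water_1000 = None
        logger.warning(
            "stratum %s has zero total energy; per-1000-kcal intensities undefined",
            profile.stratum_id,
        )
    return StratumDietSummary(
        stratum_id=profile.stratum_id,
        energy=energy_pc,
        carbon=carbon_pc,
        water=water_pc,
        pct_energy_upf=pct_upf,
        pct_energy_beef=pct_beef,
        carbon_per_1000kcal=carbon_1000,
        water_per_1000kcal=water_1000,
    )


def _merged_frame(
    purchases: Sequence[PurchaseRecord],
    items: Iterable[FoodItem] | Mapping[str, FoodItem],
) -> pd.DataFrame:
    index = index_items(items)
    frame = pd.DataFrame(
        {
            "stratum_id": [r.stratum_id for r in purchases],
            "item_code": [r.item_code for r in purchases],
            "quantity": [r.quantity for r in purchases],
        }
    )
    attrs = pd.DataFrame(
        {
            "item_code": list(index),
            "nova_group": [i.nova_group for i in index.values()],
            "subgroup": [i.subgroup for i in index.values()],
            "is_beef": [i.is_beef for i in index.values()],
            "kcal_per_kg": [
                i.edible_fraction * 10.0 * i.energy_density for i in index.values()
            ],
            "carbon_intensity": [i.carbon_intensity for i in index.values()],
            "water_intensity": [i.water_intensity for i in index.values()],
        }
    )
    unknown = set(frame["item_code"]) - set(attrs["item_code"])
    if unknown:
        raise KeyError(f"unknown item codes in purchases: {sorted(unknown)}")
    merged = frame.merge(attrs, on="item_code", how="left")
    merged["energy"] = merged["quantity"] * merged["kcal_per_kg"]
    merged["carbon"] = merged["quantity"] * merged["carbon_intensity"]
    merged["water"] = merged["quantity"] * merged["water_intensity"]
    return merged


def summarise_strata(
    purchases: Sequence[PurchaseRecord],
    items: Iterable[FoodItem] | Mapping[str, FoodItem],
    profiles: Sequence[StratumProfile],
) -> list[StratumDietSummary]:
    """Vectorised stratum summaries for the whole survey.

    Equivalent to calling :func:`summarise_stratum` per stratum (a
    property the test suite checks); strata with no purchases yield
    all-zero summaries with undefined intensities.
    """
    merged = _merged_frame(purchases, items)
    grouped = merged.groupby("stratum_id")[["energy", "carbon", "water"]].sum()
    upf = (
        merged[merged["nova_group"] == 4].groupby("stratum_id")["energy"].sum()
    )
    beef = merged[merged["is_beef"]].groupby("stratum_id")["energy"].sum()
    summaries: list[StratumDietSummary] = []
    n_zero = 0
    for profile in profiles:
        sid = profile.stratum_id
        if sid in grouped.index:
            energy, carbon, water = grouped.loc[sid]
        else:
            energy = carbon = water = 0.0
        e_upf = float(upf.get(sid, 0.0))
        e_beef = float(beef.get(sid, 0.0))
        energy_pc = per_capita_daily(float(energy), profile.n_residents)
        carbon_pc = per_capita_daily(float(carbon), profile.n_residents)
        water_pc = per_capita_daily(float(water), profile.n_residents)
        if energy > 0:
            summaries.append(
                StratumDietSummary(
                    stratum_id=sid,
                    energy=energy_pc,
                    carbon=carbon_pc,
                    water=water_pc,
                    pct_energy_upf=e_upf / energy * 100.0,
                    pct_energy_beef=e_beef / energy * 100.0,
                    carbon_per_1000kcal=carbon_pc / energy_pc * 1000.0,
                    water_per_1000kcal=water_pc / energy_pc * 1000.0,
                )
            )
        else:
            n_zero += 1
            summaries.append(
                StratumDietSummary(
                    stratum_id=sid,
                    energy=0.0,
                    carbon=carbon_pc,
                    water=water_pc,
                    pct_energy_upf=0.0,
                    pct_energy_beef=0.0,
                    carbon_per_1000kcal=None,
                    water_per_1000kcal=None,
                )
            )
    if n_zero:
        logger.warning(
            "%d strata have zero total energy and are excluded from "
            "per-1000-kcal analyses",
            n_zero,
        )
    return summaries


def summaries_frame(summaries: Sequence[StratumDietSummary]) -> pd.DataFrame:
    """Tabulate summaries, one row per stratum (undefined intensities -> NaN)."""
    return pd.DataFrame(
        {
            "stratum_id": [s.stratum_id for s in summaries],
            "energy": [s.energy for s in summaries],
            "carbon": [s.carbon for s in summaries],
            "water": [s.water for s in summaries],
            "pct_energy_upf": [s.pct_energy_upf for s in summaries],
            "pct_energy_beef": [s.pct_energy_beef for s in summaries],
            "carbon_per_1000kcal": [
                math.nan if s.carbon_per_1000kcal is None else s.carbon_per_1000kcal
                for s in summaries
            ],
            "water_per_1000kcal": [
                math.nan if s.water_per_1000kcal is None else s.water_per_1000kcal
                for s in summaries
            ],
        }
    )


def footprint_energy_ratio(pct_footprint: float, pct_energy: float) -> float:
    """Share of a footprint over share of energy; NaN when the energy share is 0.

    Ratios above (below) one mark groups whose footprint per calorie is
    higher (lower) than the diet overall.  Reported rounded to 1 decimal
    at the reporting layer; full precision here.
    """
    if pct_energy <= 0:
        return math.nan
    return pct_footprint / pct_energy


def contribution_table(
    purchases: Sequence[PurchaseRecord],
    items: Iterable[FoodItem] | Mapping[str, FoodItem],
    profiles: Sequence[StratumProfile],
) -> pd.DataFrame:
    """Attribute energy, carbon and water across Nova groups and subgroups.

    Pools expansion-weight-weighted per-capita stratum quantities into
    national totals, then expresses each Nova group, each subgroup and
    total beef as a percentage of the grand totals, with
    footprint/energy ratios.  Returns columns ``label, level,
    pct_energy, pct_carbon, pct_water, ratio_carbon, ratio_water``;
    within the group level each pct column sums to 100.
    """
    merged = _merged_frame(purchases, items)
    meta = pd.DataFrame(
        {
            "stratum_id": [p.stratum_id for p in profiles],
            "n_residents": [p.n_residents for p in profiles],
            "expansion_weight": [p.expansion_weight for p in profiles],
        }
    )
    merged = merged.merge(meta, on="stratum_id", how="left")
    if merged["expansion_weight"].isna().any():
        missing = sorted(
            merged.loc[merged["expansion_weight"].isna(), "stratum_id"].unique()
        )
        raise KeyError(f"purchases reference strata without profiles: {missing}")
    # expansion-weighted per-capita daily quantities
    scale = merged["expansion_weight"] / (DAYS_IN_DIARY * merged["n_residents"])
    for col in ("energy", "carbon", "water"):
        merged[col] = merged[col] * scale

    totals = merged[["energy", "carbon", "water"]].sum()
    if not (totals > 0).all():
        raise ValueError(
            f"grand totals must be strictly positive, got {totals.to_dict()}"
        )

    def rows(group: pd.DataFrame, label: str, level: str) -> dict:
        e = group["energy"].sum() / totals["energy"] * 100.0
        c = group["carbon"].sum() / totals["carbon"] * 100.0
        w = group["water"].sum() / totals["water"] * 100.0
        return {
            "label": label,
            "level": level,
            "pct_energy": e,
            "pct_carbon": c,
            "pct_water": w,
            "ratio_carbon": footprint_energy_ratio(c, e),
            "ratio_water": footprint_energy_ratio(w, e),
        }

    out = []
    for nova in (1, 2, 3, 4):
        sub = merged[merged["nova_group"] == nova]
        out.append(rows(sub, f"nova_group_{nova}", "group"))
        for subgroup in sorted(sub["subgroup"].unique()):
            out.append(rows(sub[sub["subgroup"] == subgroup], subgroup, "subgroup"))
    out.append(rows(merged[merged["is_beef"]], "total beef", "total_beef"))
    return pd.DataFrame(out)


def national_means(
    summaries: Sequence[StratumDietSummary],
    profiles: Sequence[StratumProfile],
) -> dict[str, float]:
    """Expansion-weighted national means of the per-capita summary fields.

    Per-1000-kcal intensities average stratum-level intensities over the
    strata where they are defined (mean of ratios, the regression
    outcome), not the ratio of national means.
    """
    weights = {p.stratum_id: p.expansion_weight for p in profiles}
    frame = summaries_frame(summaries)
    frame["w"] = frame["stratum_id"].map(weights)
    if frame["w"].isna().any():
        missing = sorted(frame.loc[frame["w"].isna(), "stratum_id"])
        raise KeyError(f"summaries reference strata without profiles: {missing}")
    out: dict[str, float] = {}
    for col in ("energy", "carbon", "water", "pct_energy_upf", "pct_energy_beef"):
        out[col] = float(np.average(frame[col], weights=frame["w"]))
    for col in ("carbon_per_1000kcal", "water_per_1000kcal"):
        ok = frame[col].notna()
        out[col] = float(np.average(frame.loc[ok, col], weights=frame.loc[ok, "w"]))
    return out
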