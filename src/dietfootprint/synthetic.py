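"""Synthetic household-budget-survey microdata with known ground truth.

Real survey microdata (purchase diaries, food-composition and footprint
coefficient tables) cannot be redistributed, so this module generates a
reduced-scale survey with the statistical structure the analysis
assumes: strata of aggregated households with expansion weights, a
7-day purchase diary, and across-strata gradients in the beef and
ultra-processed-food (UPF) energy shares that induce known
footprint-intensity slopes.

Generation is *energy-share-first*: each stratum draws target beef and
UPF energy shares, allocates the remaining energy across the other
items by a symmetric Dirichlet composition, and then inverts the energy
targets back to as-purchased masses through each item's energy density
and edible fraction.  Ground truth is therefore exact in share space,
where the exposures are defined.  Multiplicative log-normal noise on
quantities (sigma ``noise_sd``, mean-one) perturbs realised shares and
intensities jointly.

Because beef items carry intensities ``beef_carbon_multiplier`` times
the non-beef mean, the expected footprint intensity is linear in the
two share targets, with closed-form slopes (per percentage point of
energy share) stored in :class:`GroundTruth`:

    slope_beef = 10 * (kbar_beef - w4 * kbar_upf - (1 - w4) * kbar_other)
    slope_upf  = 10 * (kbar_upf - kbar_other)

where ``k_i = intensity_i / (kcal per kg)_i`` is an item's footprint per
kcal, ``kbar`` are within-category means (equal Dirichlet expectation),
and ``w4`` is the expected fraction of beef energy falling in Nova
group 4 (those items count toward both exposures, so raising the beef
share drags the UPF composition with it).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .reference_tables import (
    AREAS,
    REGIONS,
    FoodItem,
    PurchaseRecord,
    StratumProfile,
    write_food_reference,
    write_purchases,
    write_strata,
)

_REGION_PROBS = (0.08, 0.25, 0.42, 0.15, 0.10)
_ENERGY_DENSITY_MEAN = {1: 150.0, 2: 600.0, 3: 250.0, 4: 380.0}
_CARBON_MEAN = {1: 1000.0, 3: 1800.0, 4: 2800.0}
_WATER_MEAN = {1: 800.0, 3: 1200.0, 4: 1800.0}
# culinary ingredients (sugar, salt, oils): near-zero footprint per kg
_CARBON_MEAN_GROUP2 = 150.0
_WATER_MEAN_GROUP2 = 100.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Defaults echo the survey being emulated at reduced scale: 120
    strata (vs 575) with 16-120 households each, a 40-item reference
    with beef items in Nova groups 1, 3 and 4, exposure ranges spanning
    the observed quintile spreads (beef 3.0-8.2 %, UPF 10.1-28.1 % of
    energy), mean energy availability 1221.5 kcal/person-day, and beef
    intensities 13x the non-beef mean so beef's footprint/energy ratio
    lands near its observed order of magnitude (~9).  ``noise_sd`` is
    the sigma of the mean-one log-normal quantity noise (10 % default).
    """

    seed: int = 0
    n_strata: int = 120
    households_per_stratum: tuple[int, int] = (16, 120)
    residents_per_household: tuple[float, float] = (2.5, 3.5)
    n_items: int = 40
    beef_share_range: tuple[float, float] = (3.0, 8.2)
    upf_share_range: tuple[float, float] = (10.1, 28.1)
    beef_carbon_multiplier: float = 13.0
    mean_energy: float = 1221.5
    energy_sd: float = 150.0
    noise_sd: float = 0.1
    covariate_effects: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_strata < 5 or self.n_items < 8:
            raise ValueError("need at least 5 strata and 8 items")
        for name in ("beef_share_range", "upf_share_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"{name} must lie within [0, 100], got {(lo, hi)}")
        if not self.beef_carbon_multiplier > 0:
            raise ValueError("beef_carbon_multiplier must be positive")
        if self.beef_share_range[1] + self.upf_share_range[1] > 100:
            raise ValueError("beef and UPF share ranges sum beyond 100 % of energy")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        for key in (
            "households_per_stratum",
            "residents_per_household",
            "beef_share_range",
            "upf_share_range",
        ):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        for key, value in raw.items():
            if isinstance(value, tuple):
                raw[key] = list(value)
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(raw, handle, sort_keys=False)


@dataclass
class GroundTruth:
    """What the generator actually put into the data.

    ``strata`` has one row per stratum with the *target* (pre-noise)
    energy, beef/UPF shares and the exact expected per-1000-kcal
    intensities implied by its item composition; the slopes are the
    closed-form derivatives of expected intensity with respect to each
    share in percentage points.
    """

    strata: pd.DataFrame
    slope_beef_carbon: float
    slope_upf_carbon: float
    slope_beef_water: float
    slope_upf_water: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slopes": {
                "beef_carbon": self.slope_beef_carbon,
                "upf_carbon": self.slope_upf_carbon,
                "beef_water": self.slope_beef_water,
                "upf_water": self.slope_upf_water,
            },
            "strata": self.strata.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _item_counts(n_items: int) -> dict[int, int]:
    counts = {
        1: max(2, round(0.35 * n_items)),
        2: max(2, round(0.15 * n_items)),
        3: max(2, round(0.20 * n_items)),
    }
    counts[4] = n_items - sum(counts.values())
    if counts[4] < 2:
        raise ValueError(f"n_items={n_items} leaves fewer than 2 ultra-processed items")
    return counts


def generate_reference(config: SimulationConfig) -> list[FoodItem]:
    """Draw the synthetic food reference table (deterministic in the seed).

    Beef items (two in group 1, one each in groups 3 and 4) receive
    exactly ``beef_carbon_multiplier`` times the non-beef mean carbon
    and water intensity; group 2 items get near-zero intensities.
    """
    rng = _rng(config, 101)
    counts = _item_counts(config.n_items)
    beef_per_group = {1: 2 if counts[1] >= 4 else 1, 3: 1, 4: 1}
    if counts[4] - beef_per_group[4] < 1:
        raise ValueError("group 4 needs at least one non-beef item")

    rows: list[dict] = []
    code = 0
    for nova, n_in_group in sorted(counts.items()):
        n_beef = beef_per_group.get(nova, 0)
        for j in range(n_in_group):
            code += 1
            is_beef = j < n_beef
            if is_beef:
                energy_density = 200.0 * float(rng.lognormal(0.0, 0.1))
                edible_fraction = float(rng.uniform(0.70, 0.85))
                subgroup = {
                    1: "beef",
                    3: "salted, cured, smoked beef",
                    4: "reconstituted beef products",
                }[nova]
            else:
                energy_density = _ENERGY_DENSITY_MEAN[nova] * float(
                    rng.lognormal(0.0, 0.3)
                )
                edible_fraction = (
                    float(rng.uniform(0.60, 1.0))
                    if nova == 1
                    else float(rng.uniform(0.85, 1.0))
                )
                subgroup = f"group{nova}_subgroup_{j % 3}"
            if nova == 2:
                carbon = _CARBON_MEAN_GROUP2 * float(rng.lognormal(0.0, 0.3))
                water = _WATER_MEAN_GROUP2 * float(rng.lognormal(0.0, 0.3))
            elif is_beef:
                carbon = water = np.nan  # filled below from the non-beef mean
            else:
                carbon = _CARBON_MEAN[nova] * float(rng.lognormal(0.0, 0.4))
                water = _WATER_MEAN[nova] * float(rng.lognormal(0.0, 0.4))
            rows.append(
                {
                    "item_code": f"F{code:03d}",
                    "name": f"synthetic item {code}",
                    "nova_group": nova,
                    "subgroup": subgroup,
                    "is_beef": is_beef,
                    "energy_density": energy_density,
                    "edible_fraction": edible_fraction,
                    "carbon_intensity": carbon,
                    "water_intensity": water,
                }
            )
    frame = pd.DataFrame(rows)
    non_beef = ~frame["is_beef"]
    beef_carbon = config.beef_carbon_multiplier * frame.loc[non_beef, "carbon_intensity"].mean()
    beef_water = config.beef_carbon_multiplier * frame.loc[non_beef, "water_intensity"].mean()
    frame.loc[frame["is_beef"], "carbon_intensity"] = beef_carbon
    frame.loc[frame["is_beef"], "water_intensity"] = beef_water
    return [FoodItem(**row) for row in frame.to_dict(orient="records")]


def _confounding_index(
    config: SimulationConfig,
    income: np.ndarray,
    area: np.ndarray,
    region: np.ndarray,
    out_of_home: np.ndarray,
) -> tuple[np.ndarray, float]:
    """A [0, 1] covariate index and the mixing strength for exposure tilting."""
    effects = dict(config.covariate_effects or {})
    if not effects:
        return np.zeros(config.n_strata), 0.0
    n = config.n_strata

    def rank01(x: np.ndarray) -> np.ndarray:
        return (np.argsort(np.argsort(x)) + 0.5) / len(x)

    parts = {
        "income": rank01(income),
        "area": (area == "rural").astype(float),
        "region": np.array([REGIONS.index(r) / (len(REGIONS) - 1) for r in region]),
        "out_of_home": rank01(out_of_home),
    }
    index = np.zeros(n)
    total = 0.0
    for name, coef in effects.items():
        if name not in parts:
            raise ValueError(f"unknown covariate effect {name!r}")
        index += coef * parts[name]
        total += abs(coef)
    return index / total, min(1.0, total)


def generate_population(
    config: SimulationConfig, reference: Sequence[FoodItem]
) -> tuple[list[PurchaseRecord], list[StratumProfile], GroundTruth]:
    """Draw strata, covariates, exposure targets and the purchase diary.

    Raises if the drawn share targets are infeasible (beef + UPF beyond
    100 % of energy, or a UPF target below the beef energy already
    falling in Nova group 4).
    """
    rng = _rng(config, 202)
    n = config.n_strata
    items = list(reference)
    kcal_per_kg = np.array(
        [i.edible_fraction * 10.0 * i.energy_density for i in items]
    )
    if not (kcal_per_kg > 0).all():
        raise ValueError("every reference item needs positive energy density")
    k_carbon = np.array([i.carbon_intensity for i in items]) / kcal_per_kg
    k_water = np.array([i.water_intensity for i in items]) / kcal_per_kg
    beef_mask = np.array([i.is_beef for i in items])
    beef4_mask = beef_mask & np.array([i.nova_group == 4 for i in items])
    upf_nb_mask = ~beef_mask & np.array([i.nova_group == 4 for i in items])
    other_mask = ~beef_mask & np.array([i.nova_group != 4 for i in items])

    # strata and covariates
    hh_lo, hh_hi = config.households_per_stratum
    n_households = rng.integers(hh_lo, hh_hi + 1, size=n)
    n_residents = np.round(
        n_households * rng.uniform(*config.residents_per_household, size=n)
    ).astype(int)
    n_residents = np.maximum(n_residents, n_households)
    expansion_weight = rng.lognormal(np.log(5.0e4), 0.5, size=n)
    income = rng.lognormal(np.log(1500.0), 0.5, size=n)
    area = np.where(rng.uniform(size=n) < 0.85, AREAS[0], AREAS[1])
    region = rng.choice(REGIONS, size=n, p=_REGION_PROBS)
    out_of_home = rng.uniform(10.0, 40.0, size=n)

    # exposure targets, optionally tilted toward a covariate index
    index, strength = _confounding_index(config, income, area, region, out_of_home)
    u_beef = (1 - strength) * rng.uniform(size=n) + strength * index
    u_upf = (1 - strength) * rng.uniform(size=n) + strength * index
    b_lo, b_hi = config.beef_share_range
    p_lo, p_hi = config.upf_share_range
    beef_share = b_lo + u_beef * (b_hi - b_lo)
    upf_share = p_lo + u_upf * (p_hi - p_lo)
    if np.any(beef_share + upf_share > 100):
        raise ValueError("infeasible share targets: beef + UPF exceed 100 % of energy")

    energy = np.maximum(config.mean_energy + config.energy_sd * rng.standard_normal(n), 300.0)

    # within-category compositions (symmetric Dirichlet)
    w_beef = rng.dirichlet(np.ones(beef_mask.sum()), size=n)
    w_upf = rng.dirichlet(np.ones(upf_nb_mask.sum()), size=n)
    w_other = rng.dirichlet(np.ones(other_mask.sum()), size=n)
    beef4_within = w_beef[:, beef4_mask[beef_mask]].sum(axis=1)
    beef4_share = beef_share * beef4_within
    upf_nonbeef = upf_share - beef4_share
    if np.any(upf_nonbeef < 0):
        raise ValueError(
            "infeasible share targets: UPF share below its Nova-group-4 beef component"
        )
    other_total = 100.0 - beef_share - upf_nonbeef
    if np.any(other_total <= 0):
        raise ValueError("infeasible share targets: nothing left for other foods")

    shares = np.zeros((n, len(items)))
    shares[:, beef_mask] = beef_share[:, None] * w_beef
    shares[:, upf_nb_mask] = upf_nonbeef[:, None] * w_upf
    shares[:, other_mask] = other_total[:, None] * w_other

    # invert energy targets to 7-day as-purchased stratum masses
    item_energy_pc = shares / 100.0 * energy[:, None]
    quantities = item_energy_pc * 7.0 * n_residents[:, None] / kcal_per_kg[None, :]
    if config.noise_sd > 0:
        sigma = config.noise_sd
        quantities = quantities * np.exp(
            rng.normal(-0.5 * sigma**2, sigma, size=quantities.shape)
        )

    profiles = [
        StratumProfile(
            stratum_id=f"S{s:04d}",
            n_households=int(n_households[s]),
            n_residents=int(n_residents[s]),
            expansion_weight=float(expansion_weight[s]),
            income=float(income[s]),
            area=str(area[s]),
            region=str(region[s]),
            out_of_home_share=float(out_of_home[s]),
        )
        for s in range(n)
    ]
    household_of = rng.integers(0, n_households[:, None], size=quantities.shape)
    purchases = [
        PurchaseRecord(
            household_id=f"S{s:04d}_h{household_of[s, i]:03d}",
            stratum_id=f"S{s:04d}",
            item_code=items[i].item_code,
            quantity=float(quantities[s, i]),
        )
        for s in range(n)
        for i in range(len(items))
    ]

    truth = pd.DataFrame(
        {
            "stratum_id": [p.stratum_id for p in profiles],
            "energy": energy,
            "beef_share": beef_share,
            "upf_share": upf_share,
            "carbon_per_1000kcal": 10.0 * shares @ k_carbon,
            "water_per_1000kcal": 10.0 * shares @ k_water,
        }
    )
    w4 = beef4_mask.sum() / beef_mask.sum()
    kbar = {
        "beef_c": k_carbon[beef_mask].mean(),
        "upf_c": k_carbon[upf_nb_mask].mean(),
        "other_c": k_carbon[other_mask].mean(),
        "beef_w": k_water[beef_mask].mean(),
        "upf_w": k_water[upf_nb_mask].mean(),
        "other_w": k_water[other_mask].mean(),
    }
    ground_truth = GroundTruth(
        strata=truth,
        slope_beef_carbon=10.0
        * (kbar["beef_c"] - w4 * kbar["upf_c"] - (1 - w4) * kbar["other_c"]),
        slope_upf_carbon=10.0 * (kbar["upf_c"] - kbar["other_c"]),
        slope_beef_water=10.0
        * (kbar["beef_w"] - w4 * kbar["upf_w"] - (1 - w4) * kbar["other_w"]),
        slope_upf_water=10.0 * (kbar["upf_w"] - kbar["other_w"]),
    )
    return purchases, profiles, ground_truth


def expected_results(config: SimulationConfig) -> GroundTruth:
    """Recompute the ground truth deterministically from the config alone."""
    reference = generate_reference(config)
    _, _, truth = generate_population(config, reference)
    return truth


def simulate(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the three input CSVs plus ``ground_truth.json`` to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    purchases, profiles, truth = generate_population(config, reference)
    paths = {
        "reference": outdir / "food_reference.csv",
        "purchases": outdir / "purchases.csv",
        "strata": outdir / "strata.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_food_reference(reference, paths["reference"])
    write_purchases(purchases, paths["purchases"])
    write_strata(profiles, paths["strata"])
    truth.to_json(paths["ground_truth"])
    return paths
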