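"""Shared fixtures: a tiny hand-built food universe, the default synthetic
survey world, and a factory for constructed regression worlds where the
outcome-exposure relation is set directly."""

from __future__ import annotations

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

import dietfootprint as dfp
from dietfootprint.accounting import StratumDietSummary
from dietfootprint.reference_tables import REGIONS, FoodItem, StratumProfile
from dietfootprint.synthetic import generate_population, generate_reference


@pytest.fixture
def simple_items() -> list[FoodItem]:
    """Four foods spanning the Nova groups, one of them beef."""
    return [
        FoodItem("R1", "rice", 1, "cereals", False, 360.0, 1.0, 2500.0, 1500.0),
        FoodItem("B1", "beef cuts", 1, "beef", True, 190.0, 0.75, 26000.0, 15000.0),
        FoodItem("O1", "soybean oil", 2, "oils", False, 880.0, 1.0, 200.0, 100.0),
        FoodItem("U1", "soft drink", 4, "sweetened beverages", False, 40.0, 1.0, 400.0, 300.0),
    ]


def make_profile(sid: str, **overrides) -> StratumProfile:
    base = dict(
        stratum_id=sid,
        n_households=20,
        n_residents=60,
        expansion_weight=1.0,
        income=1500.0,
        area="urban",
        region="Southeast",
        out_of_home_share=25.0,
    )
    base.update(overrides)
    return StratumProfile(**base)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture(scope="session")
def default_world() -> SimpleNamespace:
    """The default 120-stratum synthetic survey at seed 1, fully summarised."""
    config = dfp.SimulationConfig(seed=1)
    reference = generate_reference(config)
    purchases, profiles, truth = generate_population(config, reference)
    summaries = dfp.summarise_strata(purchases, reference, profiles)
    return SimpleNamespace(
        config=config,
        reference=reference,
        purchases=purchases,
        profiles=profiles,
        truth=truth,
        summaries=summaries,
    )


def build_regression_world(
    seed: int,
    n: int = 250,
    slope_beef: float = 120.0,
    slope_upf: float = 5.0,
    product: float = 0.0,
    noise: float = 100.0,
    weight_sd: float = 0.1,
    constant_outcome: float | None = None,
):
    """Stratum summaries with a directly controlled outcome-exposure relation.

    The carbon intensity outcome is ``1000 + slope_beef*b + slope_upf*u
    + product*b*u + noise``; water gets different slopes.  Covariates
    and weights are drawn independently of everything else.
    """
    rng = np.random.default_rng(seed)
    b = rng.uniform(3.0, 8.2, n)
    u = rng.uniform(10.1, 28.1, n)
    eps = rng.normal(0.0, noise, n)
    eps_w = rng.normal(0.0, noise, n)
    if constant_outcome is not None:
        carbon = np.full(n, constant_outcome)
        water = np.full(n, constant_outcome / 2)
    else:
        carbon = 1000.0 + slope_beef * b + slope_upf * u + product * b * u + eps
        water = 800.0 + 0.6 * slope_beef * b + 1.5 * slope_upf * u + eps_w
    weights = rng.lognormal(0.0, weight_sd, n)
    summaries = [
        StratumDietSummary(
            stratum_id=f"S{i:04d}",
            energy=1500.0,
            carbon=1500.0 * carbon[i] / 1000.0,
            water=1500.0 * water[i] / 1000.0,
            pct_energy_upf=float(u[i]),
            pct_energy_beef=float(b[i]),
            carbon_per_1000kcal=float(carbon[i]),
            water_per_1000kcal=float(water[i]),
        )
        for i in range(n)
    ]
    profiles = [
        make_profile(
            f"S{i:04d}",
            expansion_weight=float(weights[i]),
            income=float(rng.lognormal(7.3, 0.5)),
            area="urban" if rng.uniform() < 0.85 else "rural",
            region=str(rng.choice(REGIONS)),
            out_of_home_share=float(rng.uniform(10, 40)),
        )
        for i in range(n)
    ]
    return summaries, profiles


@pytest.fixture
def regression_world():
    return build_regression_world


@pytest.fixture
def noise_free_world() -> SimpleNamespace:
    """Noise-free synthetic survey: realised shares equal the targets."""
    config = dfp.SimulationConfig(seed=2, noise_sd=0.0)
    reference = generate_reference(config)
    purchases, profiles, truth = generate_population(config, reference)
    summaries = dfp.summarise_strata(purchases, reference, profiles)
    return SimpleNamespace(
        config=config,
        reference=reference,
        purchases=purchases,
        profiles=profiles,
        truth=truth,
        summaries=summaries,
    )


def scale_weights(profiles, factor: float):
    return [replace(p, expansion_weight=p.expansion_weight * factor) for p in profiles]
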