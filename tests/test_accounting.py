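"""Footprint accounting arithmetic, stratum summaries and the Nova
contribution table."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietfootprint as dfp
from dietfootprint.accounting import (
    contribution_table,
    footprint_energy_ratio,
    item_energy,
    item_footprints,
    per_capita_daily,
    summaries_frame,
    summarise_strata,
    summarise_stratum,
)
from dietfootprint.reference_tables import FoodItem, PurchaseRecord

from conftest import make_profile


def _item(**overrides) -> FoodItem:
    base = dict(
        item_code="X1", name="x", nova_group=1, subgroup="s", is_beef=False,
        energy_density=100.0, edible_fraction=1.0,
        carbon_intensity=1000.0, water_intensity=200.0,
    )
    base.update(overrides)
    return FoodItem(**base)


@pytest.mark.parametrize(
    "quantity, edible_fraction, density, expected",
    [
        (1.0, 1.0, 100.0, 1000.0),
        (0.0, 0.7, 450.0, 0.0),
        (2.0, 0.5, 250.0, 2500.0),
    ],
)
def test_item_energy_unit_arithmetic(quantity, edible_fraction, density, expected):
    item = _item(edible_fraction=edible_fraction, energy_density=density)
    assert item_energy(quantity, item) == pytest.approx(expected)


@pytest.mark.parametrize(
    "quantity, carbon, water, expected",
    [
        (1.0, 2000.0, 500.0, (2000.0, 500.0)),
        (0.25, 26000.0, 0.0, (6500.0, 0.0)),
    ],
)
def test_item_footprints_use_as_purchased_mass(quantity, carbon, water, expected):
    item = _item(carbon_intensity=carbon, water_intensity=water)
    assert item_footprints(quantity, item) == pytest.approx(expected)


def test_halving_edible_fraction_halves_energy_not_footprints():
    full = _item(edible_fraction=1.0, carbon_intensity=2000.0)
    half = replace(full, edible_fraction=0.5)
    assert item_energy(1.0, half) == item_energy(1.0, full) / 2
    assert item_footprints(1.0, half) == item_footprints(1.0, full)


@given(
    alpha=st.floats(0.01, 1.0),
    quantity=st.floats(0.0, 50.0),
    density=st.floats(0.0, 900.0),
    intensity=st.floats(0.0, 30000.0),
)
@settings(max_examples=50, deadline=None)
def test_edible_fraction_scales_energy_only(alpha, quantity, density, intensity):
    """Scaling the edible fraction by alpha scales energy by alpha exactly
    and leaves both footprints untouched."""
    item = _item(
        edible_fraction=1.0, energy_density=density,
        carbon_intensity=intensity, water_intensity=intensity / 2,
    )
    scaled = replace(item, edible_fraction=alpha)
    assert item_energy(quantity, scaled) == pytest.approx(
        alpha * item_energy(quantity, item), rel=1e-12, abs=0.0
    )
    assert item_footprints(quantity, scaled) == item_footprints(quantity, item)


@pytest.mark.parametrize(
    "total, residents, expected",
    [(7000.0, 1, 1000.0), (0.0, 3, 0.0), (4900.0, 7, 100.0)],
)
def test_per_capita_daily(total, residents, expected):
    assert per_capita_daily(total, residents) == pytest.approx(expected)


def test_per_capita_daily_rejects_empty_stratum():
    with pytest.raises(ValueError):
        per_capita_daily(100.0, 0)


class TestSummariseStratum:
    def test_single_item_hand_example(self):
        item = _item()
        profile = make_profile("s1", n_households=1, n_residents=1)
        summary = summarise_stratum(
            [PurchaseRecord("h1", "s1", "X1", 7.0)], [item], profile
        )
        assert summary.energy == pytest.approx(1000.0)
        assert summary.carbon == pytest.approx(1000.0)
        assert summary.water == pytest.approx(200.0)
        assert summary.carbon_per_1000kcal == pytest.approx(1000.0)
        assert summary.water_per_1000kcal == pytest.approx(200.0)

    def test_beef_share_from_energy_fractions(self):
        # beef supplies 52 of 1000 kcal -> 5.2 % of energy
        beef = _item(item_code="B1", is_beef=True, energy_density=52.0)
        other = _item(item_code="X1", energy_density=948.0)
        profile = make_profile("s1", n_households=1, n_residents=1)
        summary = summarise_stratum(
            [
                PurchaseRecord("h1", "s1", "B1", 0.7),
                PurchaseRecord("h1", "s1", "X1", 0.7),
            ],
            [beef, other],
            profile,
        )
        assert summary.energy == pytest.approx(1000.0)
        assert summary.pct_energy_beef == pytest.approx(5.2)

    def test_no_ultraprocessed_items_gives_zero_share(self, simple_items):
        profile = make_profile("s1")
        records = [PurchaseRecord("h1", "s1", "R1", 3.0)]
        summary = summarise_stratum(records, simple_items, profile)
        assert summary.pct_energy_upf == 0.0

    def test_zero_energy_stratum_has_undefined_intensities(self):
        item = _item(energy_density=0.0)
        profile = make_profile("s1")
        summary = summarise_stratum(
            [PurchaseRecord("h1", "s1", "X1", 2.0)], [item], profile
        )
        assert summary.carbon_per_1000kcal is None
        assert summary.water_per_1000kcal is None
        frame = dfp.association.build_analysis_frame([summary], [profile])
        assert frame.empty  # excluded from regression


def test_summaries_match_bruteforce_record_loop(simple_items):
    """Vectorised stratum accounting equals an independent per-record loop
    on randomised small surveys."""
    rng = np.random.default_rng(42)
    codes = [i.item_code for i in simple_items]
    index = {i.item_code: i for i in simple_items}
    for _ in range(100):
        n_strata = rng.integers(1, 4)
        profiles = [
            make_profile(f"s{k}", n_residents=int(rng.integers(20, 80)))
            for k in range(n_strata)
        ]
        records = [
            PurchaseRecord(
                f"h{rng.integers(5)}",
                f"s{rng.integers(n_strata)}",
                str(rng.choice(codes)),
                float(rng.uniform(0, 10)),
            )
            for _ in range(rng.integers(0, 25))
        ]
        summaries = summarise_strata(records, simple_items, profiles)
        for profile, summary in zip(profiles, summaries):
            # brute force: plain python accumulation over records
            energy = carbon = water = e_beef = e_upf = 0.0
            for r in records:
                if r.stratum_id != profile.stratum_id:
                    continue
                it = index[r.item_code]
                e = r.quantity * it.edible_fraction * 1000 / 100 * it.energy_density
                energy += e
                carbon += r.quantity * it.carbon_intensity
                water += r.quantity * it.water_intensity
                if it.is_beef:
                    e_beef += e
                if it.nova_group == 4:
                    e_upf += e
            residents = profile.n_residents
            assert summary.energy == pytest.approx(energy / 7 / residents, abs=1e-9)
            assert summary.carbon == pytest.approx(carbon / 7 / residents, abs=1e-9)
            assert summary.water == pytest.approx(water / 7 / residents, abs=1e-9)
            if energy > 0:
                assert summary.pct_energy_beef == pytest.approx(e_beef / energy * 100)
                assert summary.pct_energy_upf == pytest.approx(e_upf / energy * 100)
                assert summary.carbon_per_1000kcal == pytest.approx(
                    carbon / energy * 1000
                )
            # single-stratum path agrees with the vectorised one
            mine = [r for r in records if r.stratum_id == profile.stratum_id]
            loop = summarise_stratum(mine, simple_items, profile)
            assert loop.energy == pytest.approx(summary.energy, abs=1e-9)
            assert loop.carbon == pytest.approx(summary.carbon, abs=1e-9)
            assert loop.water == pytest.approx(summary.water, abs=1e-9)
            if loop.carbon_per_1000kcal is None:
                assert summary.carbon_per_1000kcal is None
            else:
                assert loop.carbon_per_1000kcal == pytest.approx(
                    summary.carbon_per_1000kcal, abs=1e-9
                )


def test_increasing_quantity_never_decreases_footprints(simple_items):
    profile = make_profile("s1")
    base = [PurchaseRecord("h1", "s1", "B1", 1.0), PurchaseRecord("h1", "s1", "R1", 2.0)]
    s0 = summarise_stratum(base, simple_items, profile)
    bigger = [PurchaseRecord("h1", "s1", "B1", 1.5), base[1]]
    s1 = summarise_stratum(bigger, simple_items, profile)
    assert s1.carbon >= s0.carbon and s1.water >= s0.water


class TestContributionTable:
    def test_single_group_universe_is_100_percent(self):
        item = _item()
        profiles = [make_profile("s1")]
        table = contribution_table(
            [PurchaseRecord("h1", "s1", "X1", 5.0)], [item], profiles
        )
        row = table[table["label"] == "nova_group_1"].iloc[0]
        assert row["pct_energy"] == pytest.approx(100.0)
        assert row["pct_carbon"] == pytest.approx(100.0)
        assert row["pct_water"] == pytest.approx(100.0)

    def test_group_percentages_sum_to_100(self, default_world):
        table = contribution_table(
            default_world.purchases, default_world.reference, default_world.profiles
        )
        groups = table[table["level"] == "group"]
        for col in ("pct_energy", "pct_carbon", "pct_water"):
            assert groups[col].sum() == pytest.approx(100.0, abs=1e-9)

    def test_equal_weight_two_stratum_carbon_split(self):
        # strata contribute 100 (group 1) and 300 (group 4) gCO2eq -> 75 %
        g1 = _item(item_code="G1", nova_group=1, carbon_intensity=100.0)
        g4 = _item(item_code="G4", nova_group=4, carbon_intensity=300.0)
        profiles = [make_profile("s1"), make_profile("s2")]
        records = [
            PurchaseRecord("h1", "s1", "G1", 1.0),
            PurchaseRecord("h2", "s2", "G4", 1.0),
        ]
        table = contribution_table(records, [g1, g4], profiles)
        row = table[table["label"] == "nova_group_4"].iloc[0]
        assert row["pct_carbon"] == pytest.approx(75.0)

    def test_total_beef_row_pools_across_groups(self, default_world):
        table = contribution_table(
            default_world.purchases, default_world.reference, default_world.profiles
        )
        beef = table[table["level"] == "total_beef"]
        assert len(beef) == 1
        subgroup_beef = table[
            table["label"].isin(
                ["beef", "salted, cured, smoked beef", "reconstituted beef products"]
            )
        ]
        assert beef.iloc[0]["pct_carbon"] == pytest.approx(
            subgroup_beef["pct_carbon"].sum()
        )

    def test_zero_grand_total_errors(self):
        item = _item(energy_density=0.0, carbon_intensity=0.0, water_intensity=0.0)
        with pytest.raises(ValueError, match="positive"):
            contribution_table(
                [PurchaseRecord("h1", "s1", "X1", 1.0)], [item], [make_profile("s1")]
            )


class TestFootprintEnergyRatio:
    @pytest.mark.parametrize(
        "pct_footprint, pct_energy, expected",
        [(46.3, 5.2, 8.9), (34.5, 5.2, 6.6), (73.9, 48.7, 1.5), (16.6, 19.4, 0.9)],
    )
    def test_reported_one_decimal_values(self, pct_footprint, pct_energy, expected):
        assert round(footprint_energy_ratio(pct_footprint, pct_energy), 1) == expected

    @pytest.mark.parametrize("x", [0.1, 5.2, 48.7, 100.0])
    def test_identity_when_shares_equal(self, x):
        assert footprint_energy_ratio(x, x) == pytest.approx(1.0)

    def test_zero_energy_share_is_undefined(self):
        assert math.isnan(footprint_energy_ratio(5.0, 0.0))

    @given(
        pct_footprint=st.floats(0.01, 100.0), pct_energy=st.floats(0.01, 100.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_above_one_iff_footprint_share_larger(self, pct_footprint, pct_energy):
        ratio = footprint_energy_ratio(pct_footprint, pct_energy)
        assert (ratio > 1) == (pct_footprint > pct_energy)


def test_national_means_are_weighted(default_world):
    means = dfp.national_means(default_world.summaries, default_world.profiles)
    frame = summaries_frame(default_world.summaries)
    weights = np.array([p.expansion_weight for p in default_world.profiles])
    assert means["energy"] == pytest.approx(
        float(np.average(frame["energy"], weights=weights))
    )
    assert means["carbon_per_1000kcal"] > 0
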