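"""Data model and CSV I/O for the three survey input tables.

A footprint analysis of a household budget survey needs three tables:

* a **food reference** table: one row per food item, carrying its Nova
  group (1 unprocessed/minimally processed, 2 processed culinary
  ingredient, 3 processed, 4 ultra-processed), subgroup label, a beef
  flag, energy density of the edible portion, the edible fraction of the
  purchased mass, and cradle-to-retail carbon and water intensities per
  kg (or litre) as purchased;
* a **purchase diary**: as-purchased quantity of each item bought by each
  household over the 7-day recording window;
* a **stratum table**: the survey's unit of analysis (clusters of
  geographically and socioeconomically homogeneous households) with
  resident counts, expansion weights and the adjustment covariates.

Validation is total: every row is either accepted or rejected with an
error naming the row and the offending field.  Unknown purchase item
codes are a hard error by default because a silently dropped item biases
footprint totals downward; ``allow_missing`` drops them with a logged
count instead.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("North", "Northeast", "Southeast", "South", "Midwest")
AREAS = ("urban", "rural")
NOVA_GROUPS = (1, 2, 3, 4)

REFERENCE_COLUMNS = [
    "item_code",
    "name",
    "nova_group",
    "subgroup",
    "is_beef",
    "energy_density_kcal_per_100g_edible",
    "edible_fraction",
    "carbon_intensity_gco2eq_per_kg",
    "water_intensity_l_per_kg",
]
PURCHASE_COLUMNS = ["household_id", "stratum_id", "item_code", "quantity_kg_7day"]
STRATA_COLUMNS = [
    "stratum_id",
    "n_households",
    "n_residents",
    "expansion_weight",
    "income",
    "area",
    "region",
    "out_of_home_share_pct",
]


class ValidationError(ValueError):
    """A table row violated the schema or a domain invariant."""


@dataclass(frozen=True)
class FoodItem:
    """One food with its classification, composition and footprint intensities.

    ``energy_density`` is kcal per 100 g of *edible* portion (food
    composition table convention); the two intensities are per kg (or
    litre) *as purchased*, so inedible parts are included in the
    footprint but excluded from the energy.
    """

    item_code: str
    name: str
    nova_group: int
    subgroup: str
    is_beef: bool
    energy_density: float
    edible_fraction: float
    carbon_intensity: float
    water_intensity: float

    def __post_init__(self) -> None:
        if self.nova_group not in NOVA_GROUPS:
            raise ValidationError(
                f"item {self.item_code!r}: nova_group must be one of {NOVA_GROUPS}, "
                f"got {self.nova_group!r}"
            )
        if self.is_beef and self.nova_group == 2:
            raise ValidationError(
                f"item {self.item_code!r}: is_beef items must belong to Nova group 1, 3 "
                "or 4, never 2 (culinary ingredients contain no beef items)"
            )
        if not self.energy_density >= 0:
            raise ValidationError(
                f"item {self.item_code!r}: energy_density must be >= 0, "
                f"got {self.energy_density}"
            )
        if not 0 < self.edible_fraction <= 1:
            raise ValidationError(
                f"item {self.item_code!r}: edible_fraction must lie in (0, 1], "
                f"got {self.edible_fraction}"
            )
        for field in ("carbon_intensity", "water_intensity"):
            if not getattr(self, field) >= 0:
                raise ValidationError(
                    f"item {self.item_code!r}: {field} must be >= 0, "
                    f"got {getattr(self, field)}"
                )


@dataclass(frozen=True)
class PurchaseRecord:
    """As-purchased quantity (kg or l) of one item by one household, 7-day total."""

    household_id: str
    stratum_id: str
    item_code: str
    quantity: float

    def __post_init__(self) -> None:
        if not self.quantity >= 0:
            raise ValidationError(
                f"household {self.household_id!r}, item {self.item_code!r}: "
                f"quantity must be >= 0, got {self.quantity}"
            )


@dataclass(frozen=True)
class StratumProfile:
    """Sampling stratum: resident count, expansion weight and covariates."""

    stratum_id: str
    n_households: int
    n_residents: int
    expansion_weight: float
    income: float
    area: str
    region: str
    out_of_home_share: float

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ValidationError(
                f"stratum {self.stratum_id!r}: n_households must be positive, "
                f"got {self.n_households}"
            )
        if self.n_residents < self.n_households:
            raise ValidationError(
                f"stratum {self.stratum_id!r}: n_residents ({self.n_residents}) must be "
                f">= n_households ({self.n_households})"
            )
        if not self.expansion_weight > 0:
            raise ValidationError(
                f"stratum {self.stratum_id!r}: expansion_weight must be > 0, "
                f"got {self.expansion_weight}"
            )
        if self.area not in AREAS:
            raise ValidationError(
                f"stratum {self.stratum_id!r}: area must be one of {AREAS}, "
                f"got {self.area!r}"
            )
        if self.region not in REGIONS:
            raise ValidationError(
                f"stratum {self.stratum_id!r}: region must be one of {REGIONS}, "
                f"got {self.region!r}"
            )
        if not 0 <= self.out_of_home_share <= 100:
            raise ValidationError(
                f"stratum {self.stratum_id!r}: out_of_home_share must lie in [0, 100], "
                f"got {self.out_of_home_share}"
            )


def edible_fraction_from_correction(correction_factor: float) -> float:
    """Convert a multiplicative correction factor (>= 1) to an edible fraction."""
    if not correction_factor >= 1:
        raise ValidationError(
            f"correction factor must be >= 1, got {correction_factor}"
        )
    return 1.0 / correction_factor


def correction_from_edible_fraction(edible_fraction: float) -> float:
    """Convert an edible fraction in (0, 1] to a correction factor (>= 1)."""
    if not 0 < edible_fraction <= 1:
        raise ValidationError(
            f"edible fraction must lie in (0, 1], got {edible_fraction}"
        )
    return 1.0 / edible_fraction


def _read_table(path: str | Path, expected_columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if list(frame.columns) != list(expected_columns):
        raise ValidationError(
            f"{path.name}: header {list(frame.columns)} does not match the expected "
            f"schema {list(expected_columns)}"
        )
    return frame


def _parse(row_label: str, field: str, raw: str, kind: type):
    if kind is bool:
        token = raw.strip().lower()
        if token in {"true", "1", "yes"}:
            return True
        if token in {"false", "0", "no"}:
            return False
        raise ValidationError(f"{row_label}: field {field!r} is not a boolean: {raw!r}")
    try:
        return kind(raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"{row_label}: field {field!r} is not a valid {kind.__name__}: {raw!r}"
        ) from exc


def read_food_reference(path: str | Path) -> list[FoodItem]:
    """Read and validate the food reference table.

    Raises :class:`ValidationError` naming the row and field on any
    invariant violation, and on duplicate item codes.
    """
    frame = _read_table(path, REFERENCE_COLUMNS)
    items: list[FoodItem] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        label = f"{Path(path).name} row {i}"
        code = row.item_code
        if code in seen:
            raise ValidationError(f"{label}: duplicate item_code {code!r}")
        seen.add(code)
        try:
            item = FoodItem(
                item_code=code,
                name=row.name,
                nova_group=_parse(label, "nova_group", row.nova_group, int),
                subgroup=row.subgroup,
                is_beef=_parse(label, "is_beef", row.is_beef, bool),
                energy_density=_parse(
                    label,
                    "energy_density_kcal_per_100g_edible",
                    row.energy_density_kcal_per_100g_edible,
                    float,
                ),
                edible_fraction=_parse(
                    label, "edible_fraction", row.edible_fraction, float
                ),
                carbon_intensity=_parse(
                    label,
                    "carbon_intensity_gco2eq_per_kg",
                    row.carbon_intensity_gco2eq_per_kg,
                    float,
                ),
                water_intensity=_parse(
                    label,
                    "water_intensity_l_per_kg",
                    row.water_intensity_l_per_kg,
                    float,
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"{label}: {exc}") from None
        items.append(item)
    return items


def read_purchases(
    path: str | Path,
    items: Iterable[FoodItem] | Mapping[str, FoodItem],
    allow_missing: bool = False,
) -> list[PurchaseRecord]:
    """Read the 7-day purchase diary, resolving item codes against the reference.

    Unknown item codes are a hard error unless ``allow_missing`` is set,
    in which case the offending records are dropped and their count
    logged (a missing footprint coefficient silently biases totals).
    """
    index = index_items(items)
    frame = _read_table(path, PURCHASE_COLUMNS)
    records: list[PurchaseRecord] = []
    dropped = 0
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        label = f"{Path(path).name} row {i}"
        if row.item_code not in index:
            if allow_missing:
                dropped += 1
                continue
            raise ValidationError(
                f"{label}: unknown item_code {row.item_code!r} "
                "(not in the food reference table)"
            )
        try:
            record = PurchaseRecord(
                household_id=row.household_id,
                stratum_id=row.stratum_id,
                item_code=row.item_code,
                quantity=_parse(label, "quantity_kg_7day", row.quantity_kg_7day, float),
            )
        except ValidationError as exc:
            raise ValidationError(f"{label}: {exc}") from None
        records.append(record)
    if dropped:
        logger.warning("dropped %d purchase records with unknown item codes", dropped)
    return records


def read_strata(path: str | Path) -> list[StratumProfile]:
    """Read and validate the stratum attribute table."""
    frame = _read_table(path, STRATA_COLUMNS)
    profiles: list[StratumProfile] = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        label = f"{Path(path).name} row {i}"
        if row.stratum_id in seen:
            raise ValidationError(f"{label}: duplicate stratum_id {row.stratum_id!r}")
        seen.add(row.stratum_id)
        try:
            profile = StratumProfile(
                stratum_id=row.stratum_id,
                n_households=_parse(label, "n_households", row.n_households, int),
                n_residents=_parse(label, "n_residents", row.n_residents, int),
                expansion_weight=_parse(
                    label, "expansion_weight", row.expansion_weight, float
                ),
                income=_parse(label, "income", row.income, float),
                area=row.area,
                region=row.region,
                out_of_home_share=_parse(
                    label, "out_of_home_share_pct", row.out_of_home_share_pct, float
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"{label}: {exc}") from None
        profiles.append(profile)
    return profiles


def index_items(
    items: Iterable[FoodItem] | Mapping[str, FoodItem],
) -> dict[str, FoodItem]:
    """Map item_code -> FoodItem; duplicate codes are a hard error."""
    if isinstance(items, Mapping):
        return dict(items)
    index: dict[str, FoodItem] = {}
    for item in items:
        if item.item_code in index:
            raise ValidationError(f"duplicate item_code {item.item_code!r}")
        index[item.item_code] = item
    return index


def write_food_reference(items: Sequence[FoodItem], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "item_code": [i.item_code for i in items],
            "name": [i.name for i in items],
            "nova_group": [i.nova_group for i in items],
            "subgroup": [i.subgroup for i in items],
            "is_beef": [i.is_beef for i in items],
            "energy_density_kcal_per_100g_edible": [i.energy_density for i in items],
            "edible_fraction": [i.edible_fraction for i in items],
            "carbon_intensity_gco2eq_per_kg": [i.carbon_intensity for i in items],
            "water_intensity_l_per_kg": [i.water_intensity for i in items],
        }
    )
    frame.to_csv(path, index=False)


def write_purchases(records: Sequence[PurchaseRecord], path: str | Path) -> None:
    frame = pd.DataFrame([asdict(r) for r in records]) if records else pd.DataFrame(
        columns=PURCHASE_COLUMNS
    )
    if records:
        frame = frame.rename(columns={"quantity": "quantity_kg_7day"})
    frame.to_csv(path, index=False, columns=PURCHASE_COLUMNS)


def write_strata(profiles: Sequence[StratumProfile], path: str | Path) -> None:
    frame = pd.DataFrame([asdict(p) for p in profiles]) if profiles else pd.DataFrame(
        columns=STRATA_COLUMNS
    )
    if profiles:
        frame = frame.rename(columns={"out_of_home_share": "out_of_home_share_pct"})
    frame.to_csv(path, index=False, columns=STRATA_COLUMNS)
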