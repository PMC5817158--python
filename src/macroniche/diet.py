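"""Scat-based diet estimation: %Vol -> %DDM -> macronutrient energy fractions.

Fecal (scat) content analyses report food items as percent of fecal volume
(%Vol). Differential digestibility distorts these shares, so each item's
%Vol is multiplied by a fecal correction factor (CF) and the products are
renormalized, yielding the item's share of digestible dry matter ingested
(%DDM). Food macronutrient masses (grams of protein, carbohydrate and lipid
per unit digestible dry matter) are converted to metabolizable energy with
17 kJ/g for protein and carbohydrate and 37 kJ/g for lipid, and each food's
energy fractions are weighted by its %DDM to give the population diet as a
3-part composition on the protein/carbohydrate/lipid simplex.

Seasonal diets are aggregated to annual diets by an unweighted mean of the
seasonal %DDM profiles — each season counts equally, rather than weighting
by scat sample size, to avoid biasing annual diets toward heavily sampled
seasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .compositional import PCL, Composition, closure

__all__ = [
    "KJ_PER_G",
    "SEASONS",
    "FecalRecord",
    "CorrectionFactorTable",
    "FoodEnergyEntry",
    "FoodEnergyTable",
    "DietEstimate",
    "apply_correction_factors",
    "food_energy_composition",
    "diet_composition",
    "aggregate_annual",
    "classify_season",
    "estimate_diets",
]

#: Metabolizable-energy conversion factors, kJ per gram.
KJ_PER_G = {"P": 17.0, "C": 17.0, "L": 37.0}

SEASONS = ("spring", "summer", "autumn", "winter")

#: Default season synonym map; configurable per study.
SEASON_SYNONYMS = {
    "spring": "spring",
    "summer": "summer",
    "autumn": "autumn",
    "fall": "autumn",
    "winter": "winter",
}

_SEASON_BY_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def _norm(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class FecalRecord:
    """One food item's share of fecal volume for a population-season."""

    population_id: str
    season: str
    food_item: str
    pct_vol: float

    def __post_init__(self):
        if self.pct_vol < 0:
            raise ValueError("pct_vol must be non-negative")


class CorrectionFactorTable:
    """Food item (or category) -> fecal correction factor.

    Item-specific CFs override category CFs; lookup fails loudly rather
    than guessing, since a silently dropped food biases the diet estimate.
    """

    def __init__(
        self,
        item_cf: Mapping[str, float] | None = None,
        category_cf: Mapping[str, float] | None = None,
        item_category: Mapping[str, str] | None = None,
    ):
        self.item_cf = {_norm(k): float(v) for k, v in (item_cf or {}).items()}
        self.category_cf = {
            _norm(k): float(v) for k, v in (category_cf or {}).items()
        }
        self.item_category = {
            _norm(k): _norm(v) for k, v in (item_category or {}).items()
        }
        for name, cf in {**self.item_cf, **self.category_cf}.items():
            if cf <= 0:
                raise ValueError(f"CF for {name!r} must be positive, got {cf}")

    def lookup(self, food_item: str) -> float:
        key = _norm(food_item)
        if key in self.item_cf:
            return self.item_cf[key]
        cat = self.item_category.get(key)
        if cat is not None and cat in self.category_cf:
            return self.category_cf[cat]
        if key in self.category_cf:
            return self.category_cf[key]
        raise KeyError(f"no correction factor for food item {food_item!r}")


@dataclass(frozen=True)
class FoodEnergyEntry:
    """Macronutrient masses of one food per unit digestible dry matter."""

    food_item: str
    protein_g: float
    carbohydrate_g: float
    lipid_g: float

    def __post_init__(self):
        m = (self.protein_g, self.carbohydrate_g, self.lipid_g)
        if any(x < 0 for x in m):
            raise ValueError(f"negative macronutrient mass for {self.food_item!r}")
        if sum(m) == 0:
            raise ValueError(f"all-zero macronutrient masses for {self.food_item!r}")

    @property
    def energy_kj(self) -> float:
        """Metabolizable energy per unit digestible dry matter, kJ."""
        return (
            KJ_PER_G["P"] * self.protein_g
            + KJ_PER_G["C"] * self.carbohydrate_g
            + KJ_PER_G["L"] * self.lipid_g
        )

    @property
    def energy_fractions(self) -> Composition:
        return food_energy_composition(self)


class FoodEnergyTable:
    """Lookup of FoodEnergyEntry by normalized food name."""

    def __init__(self, entries: Iterable[FoodEnergyEntry]):
        self.entries = {_norm(e.food_item): e for e in entries}

    def __getitem__(self, food_item: str) -> FoodEnergyEntry:
        key = _norm(food_item)
        if key not in self.entries:
            raise KeyError(f"food item {food_item!r} missing from food table")
        return self.entries[key]

    def __contains__(self, food_item: str) -> bool:
        return _norm(food_item) in self.entries

    def items(self):
        return self.entries.items()


@dataclass
class DietEstimate:
    """Estimated diet of one population for a season or the whole year."""

    population_id: str
    scope: str  # a season token or "annual"
    ddm_profile: dict[str, float]
    macronutrients: Composition
    subsidy: str = "natural"

    def __post_init__(self):
        total = sum(self.ddm_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("ddm_profile must sum to 1")


def apply_correction_factors(
    records: Sequence[FecalRecord], cf: CorrectionFactorTable
) -> dict[str, float]:
    """%Vol * CF per item, renormalized to the %DDM profile (fractions).

    ddm_i = vol_i * cf_i / sum_j vol_j * cf_j. Order-independent, and
    invariant to rescaling all CFs by one positive constant.
    """
    if not records:
        raise ValueError("no fecal records given")
    pops = {(r.population_id, r.season) for r in records}
    if len(pops) > 1:
        raise ValueError(f"records span several population-seasons: {sorted(pops)}")
    weighted: dict[str, float] = {}
    for r in records:
        weighted[r.food_item] = weighted.get(r.food_item, 0.0) + r.pct_vol * cf.lookup(
            r.food_item
        )
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("all fecal volumes are zero")
    return {item: w / total for item, w in weighted.items()}


def food_energy_composition(entry: FoodEnergyEntry) -> Composition:
    """(17*P_g, 17*C_g, 37*L_g) closed to unit sum, parts (P, C, L)."""
    raw = (
        KJ_PER_G["P"] * entry.protein_g,
        KJ_PER_G["C"] * entry.carbohydrate_g,
        KJ_PER_G["L"] * entry.lipid_g,
    )
    return closure(raw, PCL)


def diet_composition(
    ddm_profile: Mapping[str, float],
    food_table: FoodEnergyTable,
    mode: str = "as-stated",
) -> Composition:
    """Weight food energy fractions by %DDM to get the diet composition.

    mode "as-stated": arithmetic mean of the foods' energy-fraction vectors
    weighted by ddm share, then closure. mode "energy-weighted": weights are
    ddm share times the food's energy density (kJ per unit DDM), i.e. strict
    energy bookkeeping; the two agree when all foods have equal energy
    density.
    """
    if mode not in ("as-stated", "energy-weighted"):
        raise ValueError(f"unknown weighting mode {mode!r}")
    acc = np.zeros(3)
    for item, share in ddm_profile.items():
        entry = food_table[item]
        w = share if mode == "as-stated" else share * entry.energy_kj
        acc += w * entry.energy_fractions.values
    return closure(acc, PCL)


def aggregate_annual(
    seasonal: Sequence[DietEstimate],
    food_table: FoodEnergyTable,
    mode: str = "as-stated",
    average: str = "ddm",
) -> DietEstimate:
    """Annual diet as the unweighted mean of seasonal %DDM profiles.

    Each season is treated as representative of its period regardless of
    scat sample size. Foods absent in a season contribute zero there. The
    annual macronutrient composition is recomputed from the pooled annual
    ddm profile (``average="ddm"``, default); ``average="composition"``
    instead averages the seasonal compositions in Aitchison-free arithmetic
    — exposed only for sensitivity checks.
    """
    if not seasonal:
        raise ValueError("no seasonal estimates")
    pops = {e.population_id for e in seasonal}
    if len(pops) > 1:
        raise ValueError(f"mixed populations: {sorted(pops)}")
    if not 1 <= len(seasonal) <= 4:
        raise ValueError("expect 1-4 seasonal estimates")
    foods = sorted({f for e in seasonal for f in e.ddm_profile})
    profile = {
        f: sum(e.ddm_profile.get(f, 0.0) for e in seasonal) / len(seasonal)
        for f in foods
    }
    total = sum(profile.values())
    profile = {f: v / total for f, v in profile.items()}
    if average == "ddm":
        macro = diet_composition(profile, food_table, mode)
    elif average == "composition":
        macro = closure(
            np.mean([e.macronutrients.values for e in seasonal], axis=0), PCL
        )
    else:
        raise ValueError(f"unknown average {average!r}")
    return DietEstimate(
        population_id=seasonal[0].population_id,
        scope="annual",
        ddm_profile=profile,
        macronutrients=macro,
        subsidy=seasonal[0].subsidy,
    )


def classify_season(
    label: str,
    month_range: tuple[int, int] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> str:
    """Map a free-text season label to spring|summer|autumn|winter.

    Unknown labels with a month range are classified by the midpoint month
    (ranges may wrap the year end); otherwise an error lists the accepted
    synonyms — no silent guessing.
    """
    if not str(label).strip():
        raise ValueError("empty season label")
    table = dict(SEASON_SYNONYMS if synonyms is None else synonyms)
    key = _norm(label)
    if key in table:
        return table[key]
    if month_range is not None:
        a, b = month_range
        if not (1 <= a <= 12 and 1 <= b <= 12):
            raise ValueError("months must be 1-12")
        if b < a:  # wraps the year end
            b += 12
        mid = ((a + b) // 2 - 1) % 12 + 1
        return _SEASON_BY_MONTH[mid]
    raise ValueError(
        f"cannot classify season label {label!r}; accepted synonyms: "
        f"{sorted(table)} (or supply month_range)"
    )


def estimate_diets(
    records: Sequence[FecalRecord],
    cf: CorrectionFactorTable,
    food_table: FoodEnergyTable,
    subsidy: Mapping[str, str] | None = None,
    mode: str = "as-stated",
) -> tuple[list[DietEstimate], list[DietEstimate]]:
    """Full pipeline: records -> seasonal estimates -> annual estimates.

    Returns (seasonal, annual) lists sorted by population id.
    """
    subsidy = subsidy or {}
    grouped: dict[tuple[str, str], list[FecalRecord]] = {}
    for r in records:
        grouped.setdefault((r.population_id, r.season), []).append(r)
    seasonal: list[DietEstimate] = []
    for (pop, season), recs in sorted(grouped.items()):
        profile = apply_correction_factors(recs, cf)
        seasonal.append(
            DietEstimate(
                population_id=pop,
                scope=season,
                ddm_profile=profile,
                macronutrients=diet_composition(profile, food_table, mode),
                subsidy=subsidy.get(pop, "natural"),
            )
        )
    annual = [
        aggregate_annual(
            [e for e in seasonal if e.population_id == pop], food_table, mode
        )
        for pop in sorted({e.population_id for e in seasonal})
    ]
    return seasonal, annual
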