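"""Delimited-text readers/writers, schema validation and run configuration.

All tables are plain CSV with required headers; fractions are written with
six decimals (a three-decimal presentation rounding is available for
printed summaries). Compositions are stored as decimal fractions
throughout; percentages appear only at the presentation layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .compositional import (
    PCL,
    Composition,
    CompositionSet,
    CompositionSummary,
    closure,
)
from .diet import (
    CorrectionFactorTable,
    DietEstimate,
    FecalRecord,
    FoodEnergyEntry,
    FoodEnergyTable,
)

__all__ = [
    "ValidationReport",
    "RunConfig",
    "read_fecal_records",
    "read_cf_table",
    "read_food_table",
    "read_subsidy_table",
    "read_composition_set",
    "write_composition_set",
    "write_estimates",
    "write_summary",
    "write_study",
]

log = logging.getLogger("macroniche")

FECAL_HEADERS = ["population_id", "season", "food_item", "pct_vol"]
FOOD_HEADERS = ["food_item", "protein_g", "carbohydrate_g", "lipid_g"]

#: tolerated deviation of a population-season's total %Vol from 100
VOL_SUM_TOL = 2.0


@dataclass
class ValidationReport:
    accepted: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        log.warning(msg)


def _require_headers(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [h for h in required if h not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )


def read_fecal_records(path) -> tuple[list[FecalRecord], ValidationReport]:
    """Read and validate scat records.

    Duplicated (population, season, food) rows are an error. A
    population-season whose %Vol total deviates from 100 by more than
    ``VOL_SUM_TOL`` is renormalized to 100 with a logged warning (the
    renormalization is harmless downstream — the CF step renormalizes
    anyway — but the warning flags suspect data entry).
    """
    df = pd.read_csv(path)
    _require_headers(df, FECAL_HEADERS, path)
    report = ValidationReport()
    dup = df.duplicated(subset=["population_id", "season", "food_item"])
    if dup.any():
        rows = df.loc[dup, ["population_id", "season", "food_item"]]
        raise ValueError(f"{path}: duplicate rows:\n{rows.to_string(index=False)}")
    records: list[FecalRecord] = []
    for (pop, season), grp in df.groupby(["population_id", "season"], sort=True):
        total = grp["pct_vol"].sum()
        vols = grp["pct_vol"].to_numpy(dtype=float)
        if abs(total - 100.0) > VOL_SUM_TOL:
            report.warn(
                f"{pop}/{season}: total %Vol {total:.2f} deviates from 100; "
                "renormalized"
            )
            vols = vols * 100.0 / total
        for item, vol in zip(grp["food_item"], vols):
            records.append(FecalRecord(str(pop), str(season), str(item), float(vol)))
    report.accepted = len(records)
    return records, report


def read_cf_table(path) -> CorrectionFactorTable:
    df = pd.read_csv(path)
    has_item = "food_item" in df.columns
    has_cat = "category" in df.columns
    if "cf" not in df.columns or not (has_item or has_cat):
        raise ValueError(
            f"{path}: need columns (food_item|category, cf); found {list(df.columns)}"
        )
    item_cf, cat_cf, item_cat = {}, {}, {}
    for _, row in df.iterrows():
        item = row.get("food_item") if has_item else None
        cat = row.get("category") if has_cat else None
        item_ok = isinstance(item, str) or (item is not None and not pd.isna(item))
        cat_ok = isinstance(cat, str) or (cat is not None and not pd.isna(cat))
        if item_ok:
            item_cf[str(item)] = float(row["cf"])
            if cat_ok:
                item_cat[str(item)] = str(cat)
        elif cat_ok:
            cat_cf[str(cat)] = float(row["cf"])
    return CorrectionFactorTable(item_cf, cat_cf, item_cat)


def read_food_table(path) -> FoodEnergyTable:
    df = pd.read_csv(path)
    _require_headers(df, FOOD_HEADERS, path)
    return FoodEnergyTable(
        FoodEnergyEntry(
            str(r.food_item),
            float(r.protein_g),
            float(r.carbohydrate_g),
            float(r.lipid_g),
        )
        for r in df.itertuples()
    )


def read_subsidy_table(path) -> dict[str, str]:
    df = pd.read_csv(path)
    _require_headers(df, ["population_id", "subsidy"], path)
    bad = set(df["subsidy"]) - {"natural", "anthropogenic"}
    if bad:
        raise ValueError(f"{path}: unknown subsidy values {sorted(bad)}")
    return dict(zip(df["population_id"].astype(str), df["subsidy"]))


# ---------------------------------------------------------------------------
# composition sets / estimates / summaries


def write_composition_set(s: CompositionSet, path, decimals: int = 6) -> None:
    df = pd.DataFrame(np.round(s.values, decimals), columns=list(s.parts))
    for key, col in s.metadata.items():
        df.insert(0, key, col)
    df.to_csv(path, index=False)


def read_composition_set(path, parts: Sequence[str] = PCL) -> CompositionSet:
    df = pd.read_csv(path)
    _require_headers(df, parts, path)
    vals = df[list(parts)].to_numpy(dtype=float)
    meta = {
        c: df[c].astype(str).tolist() for c in df.columns if c not in parts
    }
    vals = vals / vals.sum(axis=1, keepdims=True)  # absorb rounding
    return CompositionSet(tuple(parts), vals, meta)


def write_estimates(
    estimates: Sequence[DietEstimate], path, decimals: int = 6
) -> None:
    rows = [
        {
            "population_id": e.population_id,
            "season": e.scope,
            "subsidy": e.subsidy,
            **{
                p: round(float(v), decimals)
                for p, v in e.macronutrients.asdict().items()
            },
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def estimates_to_set(estimates: Sequence[DietEstimate]) -> CompositionSet:
    return CompositionSet(
        PCL,
        np.vstack([e.macronutrients.values for e in estimates]),
        {
            "population_id": [e.population_id for e in estimates],
            "season": [e.scope for e in estimates],
            "subsidy": [e.subsidy for e in estimates],
        },
    )


def write_summary(
    summary: CompositionSummary, path, decimals: int = 6
) -> None:
    """Three-block layout: geometric mean, mean-ratio matrix, variance matrix."""
    parts = list(summary.geometric_mean.parts)
    r = lambda x: np.round(np.asarray(x, dtype=float), decimals)
    with open(path, "w") as fh:
        fh.write(f"# n={summary.n} metric_variance={summary.metric_variance:.{decimals}f}\n")
        fh.write("block,part," + ",".join(parts) + "\n")
        fh.write(
            "geometric_mean,,"
            + ",".join(f"{v:.{decimals}f}" for v in r(summary.geometric_mean.values))
            + "\n"
        )
        for name, mat in (
            ("mean_ratio", summary.mean_ratio_matrix),
            ("variance", summary.variation_matrix),
        ):
            for p, row in zip(parts, r(mat)):
                fh.write(
                    f"{name},{p}," + ",".join(f"{v:.{decimals}f}" for v in row) + "\n"
                )


def write_study(study, outdir) -> dict[str, Path]:
    """Write a simulated study's four tables (records, CFs, foods, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "fecal_records.csv",
        "cf": outdir / "correction_factors.csv",
        "foods": outdir / "food_energy.csv",
        "truth": outdir / "truth.csv",
        "subsidy": outdir / "subsidy.csv",
    }
    pd.DataFrame(
        [
            {
                "population_id": r.population_id,
                "season": r.season,
                "food_item": r.food_item,
                "pct_vol": round(r.pct_vol, 6),
            }
            for r in study.records
        ]
    ).to_csv(paths["records"], index=False)
    pd.DataFrame(
        [{"food_item": k, "cf": v} for k, v in sorted(study.cf_table.item_cf.items())]
    ).to_csv(paths["cf"], index=False)
    pd.DataFrame(
        [
            {
                "food_item": e.food_item,
                "protein_g": round(e.protein_g, 6),
                "carbohydrate_g": round(e.carbohydrate_g, 6),
                "lipid_g": round(e.lipid_g, 6),
            }
            for _, e in sorted(study.food_table.items())
        ]
    ).to_csv(paths["foods"], index=False)
    pd.DataFrame(
        [
            {
                "population_id": pop,
                "season": season,
                **{p: round(v, 9) for p, v in comp.asdict().items()},
            }
            for (pop, season), comp in sorted(study.truth.items())
        ]
    ).to_csv(paths["truth"], index=False)
    pd.DataFrame(
        [
            {"population_id": pop, "subsidy": grp}
            for pop, grp in sorted(study.subsidy.items())
        ]
    ).to_csv(paths["subsidy"], index=False)
    return paths


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Paths, modes and numeric settings for one pipeline run."""

    fecal_records: str = ""
    cf_table: str = ""
    food_table: str = ""
    subsidy_table: str = ""
    weighting_mode: str = "as-stated"
    zero_delta: float = 1e-3
    seasons: tuple[str, ...] = ("spring", "summer", "autumn")
    ilr_basis: str = "helmert-PCL"
    region_levels: tuple[float, ...] = (0.90, 0.99)
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.weighting_mode not in ("as-stated", "energy-weighted"):
            raise ValueError(f"unknown weighting mode {self.weighting_mode!r}")
        if self.zero_delta <= 0:
            raise ValueError("zero_delta must be positive")
        self.seasons = tuple(self.seasons)
        self.region_levels = tuple(self.region_levels)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"{path}: unknown config keys {sorted(bad)}")
        cfg = cls(**data)
        for key in ("fecal_records", "cf_table", "food_table", "subsidy_table"):
            p = getattr(cfg, key)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{path}: {key} file {p!r} does not exist")
        return cfg

    def save(self, path) -> None:
        data = dataclasses.asdict(self)
        data["seasons"] = list(self.seasons)
        data["region_levels"] = list(self.region_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
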