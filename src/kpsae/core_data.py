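"""Shared domain vocabulary, CSV ingestion, and validation.

All pipeline stages exchange pandas DataFrames with the fixed column
schemas documented in :data:`SCHEMAS`.  A :class:`Dataset` bundles the five
record collections (regions, population denominators, direct size
estimates, program records, auxiliary covariates); loading enforces
referential integrity against the region table, while softer data-quality
issues (a point estimate outside its own confidence interval, missing CI
bounds, missing estimation methods) surface as warnings from
:func:`validate_dataset` rather than errors, because published rows exhibit
them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "POPULATIONS",
    "METHOD_RANKING",
    "SOURCES",
    "SEXES",
    "COVARIATE_VARIABLES",
    "SCHEMAS",
    "SchemaError",
    "Dataset",
    "parse_quarter",
    "quarter_sort_key",
    "parse_age_band",
    "load_table",
    "load_dataset",
    "write_dataset",
    "validate_dataset",
]

POPULATIONS = ("FSW", "MSM")

#: Size-estimation methods ordered from highest to lowest confidence:
#: model-based SS-PSE first, respondent guesses (wisdom of the crowds) last.
METHOD_RANKING = (
    "ss_pse",
    "unique_object_multiplier",
    "mapping",
    "stakeholder_consensus",
    "literature_review",
    "key_informant",
    "wisdom_of_crowds",
)

SOURCES = ("DATIM", "KP_STAR")
SEXES = ("female", "male")
COVARIATE_VARIABLES = (
    "hiv_prevalence",
    "population_density",
    "literacy",
    "employment",
    "pop_growth",
)
SEX_STRATA = ("female", "male", "all")

# column -> (dtype kind, nullable); order defines the canonical column order
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "regions": {"region_id": ("str", False), "name": ("str", False)},
    "denominators": {
        "region_id": ("str", False),
        "sex": ("str", False),
        "age_band": ("str", False),
        "year": ("int", False),
        "count": ("int", False),
    },
    "direct_estimates": {
        "region_id": ("str", False),
        "population": ("str", False),
        "method": ("str", False),
        "point": ("float", False),
        "ci_lower": ("float", True),
        "ci_upper": ("float", True),
        "year": ("int", False),
    },
    "program_records": {
        "source": ("str", False),
        "population": ("str", False),
        "region_id": ("str", True),
        "fiscal_quarter": ("str", False),
        "count": ("int", False),
    },
    "covariates": {
        "region_id": ("str", False),
        "variable": ("str", False),
        "sex_stratum": ("str", False),
        "value": ("float", False),
    },
}

_SORT_KEYS = {
    "regions": ["region_id"],
    "denominators": ["region_id", "sex", "age_band", "year"],
    "direct_estimates": ["region_id", "population", "method"],
    "program_records": ["source", "population", "region_id", "fiscal_quarter"],
    "covariates": ["region_id", "variable", "sex_stratum"],
}

_QUARTER_RE = re.compile(r"^FY(\d{4})Q([1-4])$")
_AGE_BAND_RE = re.compile(r"^(\d+)-(\d+)$")


class SchemaError(ValueError):
    """Raised when an input table violates its documented schema."""


def parse_quarter(label: str) -> tuple[int, int]:
    """Parse a fiscal-quarter label like ``FY2020Q3`` into ``(2020, 3)``."""
    m = _QUARTER_RE.match(str(label))
    if not m:
        raise SchemaError(f"unparseable fiscal quarter label {label!r} (expected FYyyyyQq)")
    return int(m.group(1)), int(m.group(2))


def quarter_sort_key(label: str) -> int:
    """Integer sort key (year*4 + quarter) for fiscal-quarter labels."""
    y, q = parse_quarter(label)
    return y * 4 + q


def parse_age_band(band: str) -> tuple[int, int]:
    """Parse an age band ``"18-49"`` into integer endpoints; lower < upper."""
    m = _AGE_BAND_RE.match(str(band))
    if not m:
        raise SchemaError(f"unparseable age band {band!r} (expected 'A-B')")
    lo, hi = int(m.group(1)), int(m.group(2))
    if lo >= hi:
        raise SchemaError(f"age band {band!r} must have lower < upper")
    return lo, hi


@dataclass
class Dataset:
    """Bundle of the five validated record collections.

    ``truth`` is populated only for synthetic datasets and carries the
    region-level ground truth used for recovery scoring.
    """

    regions: pd.DataFrame
    denominators: pd.DataFrame = field(default_factory=pd.DataFrame)
    direct_estimates: pd.DataFrame = field(default_factory=pd.DataFrame)
    program_records: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "regions": self.regions,
            "denominators": self.denominators,
            "direct_estimates": self.direct_estimates,
            "program_records": self.program_records,
            "covariates": self.covariates,
        }

    def denominator_series(self, sex: str, age_band: str, year: int) -> pd.Series:
        """Region-indexed counts for one (sex, age band, year) cell."""
        d = self.denominators
        sel = d[(d["sex"] == sex) & (d["age_band"] == age_band) & (d["year"] == int(year))]
        if sel.empty:
            raise KeyError(f"no denominators for sex={sex}, age_band={age_band}, year={year}")
        return sel.set_index("region_id")["count"].astype(float)

    def covariate_series(self, variable: str, sex_stratum: str = "all") -> pd.Series:
        c = self.covariates
        sel = c[(c["variable"] == variable) & (c["sex_stratum"] == sex_stratum)]
        if sel.empty:
            raise KeyError(f"no covariate values for {variable!r} (stratum {sex_stratum!r})")
        return sel.set_index("region_id")["value"].astype(float)


def _coerce_column(df: pd.DataFrame, table: str, col: str, kind: str, nullable: bool) -> pd.Series:
    raw = df[col]
    if kind == "str":
        out = raw.astype("string")
        bad = out.isna() | (out.str.strip() == "")
        if bad.any() and not nullable:
            row = int(bad[bad].index[0])
            raise SchemaError(f"table {table!r}, row {row}, column {col!r}: missing value")
        if nullable:
            out = out.where(~bad, other=pd.NA)
        return out.astype(object).where(out.notna(), None)
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad[bad].index[0])
        raise SchemaError(
            f"table {table!r}, row {row}, column {col!r}: non-numeric value {raw[bad].iloc[0]!r}"
        )
    missing = num.isna()
    if missing.any() and not nullable:
        row = int(missing[missing].index[0])
        raise SchemaError(f"table {table!r}, row {row}, column {col!r}: missing value")
    if kind == "int":
        if ((num.dropna() % 1) != 0).any():
            frac = num.dropna()[(num.dropna() % 1) != 0]
            row = int(frac.index[0])
            raise SchemaError(f"table {table!r}, row {row}, column {col!r}: non-integer value")
        return num.astype("int64") if not missing.any() else num.astype("Int64")
    return num.astype(float)


def load_table(path: str | Path, table: str) -> pd.DataFrame:
    """Read one CSV table, enforce its schema, and return canonical columns.

    Columns beyond the schema are dropped with a warning; a missing schema
    column, or a value of the wrong kind, raises :class:`SchemaError`
    naming the row and column.
    """
    if table not in SCHEMAS:
        raise KeyError(f"unknown table {table!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file for table {table!r} not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    return conform_table(df, table)


def conform_table(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Validate/coerce an in-memory frame against a table schema."""
    schema = SCHEMAS[table]
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"table {table!r}: ignoring unknown columns {extra}", stacklevel=2)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r}: missing required columns {missing}")
    out = pd.DataFrame(index=df.index)
    for col, (kind, nullable) in schema.items():
        out[col] = _coerce_column(df, table, col, kind, nullable)
    out = _check_domains(out, table)
    out = out.sort_values(_SORT_KEYS[table], kind="mergesort").reset_index(drop=True)
    return out


def _check_domains(df: pd.DataFrame, table: str) -> pd.DataFrame:
    def _enum(col: str, allowed: tuple[str, ...], allow_none: bool = False) -> None:
        vals = df[col]
        for row, v in vals.items():
            if v is None and allow_none:
                continue
            if v not in allowed:
                raise SchemaError(
                    f"table {table!r}, row {row}, column {col!r}: "
                    f"value {v!r} not in {sorted(allowed)}"
                )

    if table == "denominators":
        _enum("sex", SEXES)
        for row, band in df["age_band"].items():
            parse_age_band(band)
        if (df["count"] < 0).any():
            row = int(df.index[df["count"] < 0][0])
            raise SchemaError(f"table {table!r}, row {row}, column 'count': negative count")
    elif table == "direct_estimates":
        _enum("population", POPULATIONS)
        _enum("method", METHOD_RANKING)
        if (df["point"] <= 0).any():
            row = int(df.index[df["point"] <= 0][0])
            raise SchemaError(f"table {table!r}, row {row}, column 'point': must be > 0")
        dup = df.duplicated(["region_id", "population", "method"])
        if dup.any():
            row = int(df.index[dup][0])
            raise SchemaError(
                f"table {table!r}, row {row}: duplicate (region, population, method)"
            )
    elif table == "program_records":
        _enum("source", SOURCES)
        _enum("population", POPULATIONS)
        for row, q in df["fiscal_quarter"].items():
            parse_quarter(q)
        if (df["count"] < 0).any():
            row = int(df.index[df["count"] < 0][0])
            raise SchemaError(f"table {table!r}, row {row}, column 'count': negative count")
    elif table == "covariates":
        _enum("variable", COVARIATE_VARIABLES)
        _enum("sex_stratum", SEX_STRATA)
        rates = df["variable"].isin(("hiv_prevalence", "literacy", "employment"))
        bad = rates & (~df["value"].between(0, 100))
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"table {table!r}, row {row}, column 'value': rate outside [0, 100]"
            )
        bad = (df["variable"] == "population_density") & (df["value"] < 0)
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(f"table {table!r}, row {row}, column 'value': negative density")
    elif table == "regions":
        dup = df.duplicated("region_id")
        if dup.any():
            row = int(df.index[dup][0])
            raise SchemaError(f"table {table!r}, row {row}: duplicate region_id")
    return df


def load_dataset(paths: Mapping[str, str | Path]) -> Dataset:
    """Load a full dataset bundle from per-table CSV paths.

    ``paths`` maps table names (see :data:`SCHEMAS`) to file locations; the
    region table is required, others default to empty.  Every ``region_id``
    referenced by any record must exist in the region table.
    """
    if "regions" not in paths:
        raise SchemaError("a 'regions' table path is required")
    tables: dict[str, pd.DataFrame] = {}
    for name in SCHEMAS:
        if name in paths:
            tables[name] = load_table(paths[name], name)
        else:
            tables[name] = pd.DataFrame(columns=list(SCHEMAS[name]))
    known = set(tables["regions"]["region_id"])
    for name, df in tables.items():
        if name == "regions" or "region_id" not in df.columns or df.empty:
            continue
        refs = df["region_id"]
        for row, rid in refs.items():
            if rid is None:
                continue
            if rid not in known:
                raise SchemaError(
                    f"table {name!r}, row {row}: unknown region_id {rid!r}"
                )
    return Dataset(**tables)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write each collection back to ``<out_dir>/<table>.csv``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in dataset.tables().items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    if dataset.truth is not None:
        p = out_dir / "truth.csv"
        dataset.truth.to_csv(p, index=False)
        written["truth"] = p
    return written


def validate_dataset(dataset: Dataset) -> list[str]:
    """Data-quality warnings for a loaded bundle (never errors).

    Checks each direct estimate for missing CI bounds and for a point
    estimate outside its own interval, and each surveyed
    (region, population) pair for absent estimation methods.  The returned
    list is deterministically ordered (region, population, method).
    """
    out: list[str] = []
    est = dataset.direct_estimates
    if est.empty:
        return out
    est = est.sort_values(["region_id", "population", "method"], kind="mergesort")
    for _, r in est.iterrows():
        where = f"{r.region_id}/{r.population}/{r.method}"
        lo, hi = r.ci_lower, r.ci_upper
        if pd.isna(lo) or pd.isna(hi):
            out.append(f"missing CI bounds for {where} (point {r.point:g})")
        elif not (lo <= r.point <= hi):
            out.append(
                f"point outside its CI for {where}: {r.point:g} not in [{lo:g}, {hi:g}]"
            )
    for (rid, pop), grp in est.groupby(["region_id", "population"], sort=True):
        absent = [m for m in METHOD_RANKING if m not in set(grp["method"])]
        for m in absent:
            out.append(f"missing method {m} for {rid}/{pop}")
    return out
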