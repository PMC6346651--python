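"""Age-class system and run reconstruction for a sockeye salmon population.

Sockeye in this system rear 1-3 years in the nursery lake (after the gravel
year, which is not counted in "freshwater age") and spend 1-3 years at sea,
giving nine freshwater x ocean age combinations.  Jacks are the ocean age-1
males (age classes 1-3); all older fish (ocean ages 2-3, classes 4-9) are
"nonjacks".  Abundances are tracked in two frames: by brood year (the year a
cohort was spawned) and by return year (the calendar year mature fish come
back).  A fish of age class ``a`` spawned in brood year ``y`` returns in year
``y + T_a`` where ``T_a`` is its total age (gravel year + freshwater years +
ocean years); lagging between the two frames is the core of run
reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgeClass",
    "AgeStructure",
    "BroodTable",
    "ReturnTable",
    "ObservedCounts",
    "ScaleSamples",
    "SchemaError",
    "AGE_COLUMNS",
    "total_age",
    "brood_to_return",
    "return_to_brood",
    "apply_exploitation",
    "brood_summaries",
    "read_brood_table",
    "read_observed_counts",
    "read_scale_samples",
    "read_covariate_table",
]

#: Canonical column order: ocean-major, freshwater-minor.
AGE_COLUMNS = [
    "o1_f1", "o1_f2", "o1_f3",
    "o2_f1", "o2_f2", "o2_f3",
    "o3_f1", "o3_f2", "o3_f3",
]


class SchemaError(ValueError):
    """Raised when a tabular input violates its declared schema."""


def total_age(fw_age: int, ocean_age: int) -> int:
    """Total age of an age class: gravel year + freshwater + ocean years."""
    if fw_age not in (1, 2, 3) or ocean_age not in (1, 2, 3):
        raise ValueError(
            f"invalid age combination fw={fw_age}, ocean={ocean_age}: "
            "freshwater and ocean ages must each be 1, 2 or 3"
        )
    return 1 + fw_age + ocean_age


@dataclass(frozen=True)
class AgeClass:
    """One freshwater x ocean age combination."""

    fw_age: int
    ocean_age: int

    def __post_init__(self) -> None:
        total_age(self.fw_age, self.ocean_age)  # validates

    @property
    def index_a(self) -> int:
        """1-based index in the fixed ocean-major ordering."""
        return 3 * (self.ocean_age - 1) + self.fw_age

    @property
    def total_age_Ta(self) -> int:
        return total_age(self.fw_age, self.ocean_age)

    @property
    def column(self) -> str:
        return f"o{self.ocean_age}_f{self.fw_age}"


@dataclass(frozen=True)
class AgeStructure:
    """The nine-class age system with jack / nonjack / ocean-age index sets.

    Index sets are 0-based positions into :data:`AGE_COLUMNS`.
    """

    classes: tuple[AgeClass, ...] = field(
        default_factory=lambda: tuple(
            AgeClass(fw_age=f, ocean_age=o) for o in (1, 2, 3) for f in (1, 2, 3)
        )
    )

    def __post_init__(self) -> None:
        if [c.index_a for c in self.classes] != list(range(1, len(self.classes) + 1)):
            raise ValueError("age classes must be in canonical ocean-major order")

    @property
    def n_ages(self) -> int:
        return len(self.classes)

    @property
    def total_ages(self) -> np.ndarray:
        return np.array([c.total_age_Ta for c in self.classes])

    @property
    def jack_set(self) -> np.ndarray:
        """Ocean age-1 classes (jacks)."""
        return np.array([i for i, c in enumerate(self.classes) if c.ocean_age == 1])

    @property
    def nonjack_set(self) -> np.ndarray:
        """Ocean age-2 and age-3 classes (hooknose males and all females)."""
        return np.array([i for i, c in enumerate(self.classes) if c.ocean_age > 1])

    def ocean_set(self, ocean_age: int) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.classes) if c.ocean_age == ocean_age]
        )

    @property
    def ocean_sets(self) -> dict[int, np.ndarray]:
        return {o: self.ocean_set(o) for o in (1, 2, 3)}


DEFAULT_AGES = AgeStructure()


def _validate_year_age(years: np.ndarray, values: np.ndarray, what: str) -> None:
    years = np.asarray(years)
    values = np.asarray(values)
    if years.ndim != 1 or len(years) == 0:
        raise ValueError(f"{what}: need at least one year")
    if np.any(np.diff(years) != 1):
        raise ValueError(f"{what}: years must be consecutive with no gaps")
    if values.shape != (len(years), len(AGE_COLUMNS)):
        raise ValueError(
            f"{what}: values shape {values.shape} != ({len(years)}, {len(AGE_COLUMNS)})"
        )
    with np.errstate(invalid="ignore"):
        if np.any(values < 0):
            raise ValueError(f"{what}: negative numbers-at-age")


@dataclass
class _YearAgeTable:
    """Numbers-at-age indexed by (year, age class).  NaN marks missing cells."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        _validate_year_age(self.years, self.values, type(self).__name__)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=AGE_COLUMNS)
        df.insert(0, self.year_column, self.years)
        return df

    def to_csv(self, path) -> None:
        # %.17g round-trips doubles exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def year_index(self, year: int) -> int:
        return int(year - self.years[0])

    def __eq__(self, other) -> bool:  # NaN-aware equality
        return (
            type(self) is type(other)
            and np.array_equal(self.years, other.years)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass(eq=False)
class BroodTable(_YearAgeTable):
    """Numbers-at-age produced by each brood year (cohort frame)."""

    year_column = "brood_year"


@dataclass(eq=False)
class ReturnTable(_YearAgeTable):
    """Numbers-at-age arriving in each return year (calendar frame)."""

    year_column = "return_year"


def brood_to_return(
    brood: BroodTable, ages: AgeStructure = DEFAULT_AGES
) -> ReturnTable:
    """Lag brood-year numbers-at-age into the return-year frame.

    ``R[t, a] = B[t - T_a, a]``.  Return years span ``min(brood)+3`` through
    ``max(brood)+7``; cells whose source brood year falls outside the table
    are missing (NaN), not zero.
    """
    ta = ages.total_ages
    t0, t1 = brood.years[0] + ta.min(), brood.years[-1] + ta.max()
    ret_years = np.arange(t0, t1 + 1)
    out = np.full((len(ret_years), ages.n_ages), np.nan)
    for a in range(ages.n_ages):
        src = ret_years - ta[a]
        ok = (src >= brood.years[0]) & (src <= brood.years[-1])
        out[ok, a] = brood.values[src[ok] - brood.years[0], a]
    return ReturnTable(years=ret_years, values=out)


def return_to_brood(
    ret: ReturnTable, ages: AgeStructure = DEFAULT_AGES
) -> BroodTable:
    """Run reconstruction: lag return-year numbers-at-age back to brood years.

    Exact inverse of :func:`brood_to_return` on the cells present in both
    frames.
    """
    ta = ages.total_ages
    y0, y1 = ret.years[0] - ta.max(), ret.years[-1] - ta.min()
    brood_years = np.arange(y0, y1 + 1)
    out = np.full((len(brood_years), ages.n_ages), np.nan)
    for a in range(ages.n_ages):
        src = brood_years + ta[a]
        ok = (src >= ret.years[0]) & (src <= ret.years[-1])
        out[ok, a] = ret.values[src[ok] - ret.years[0], a]
    return BroodTable(years=brood_years, values=out)


def apply_exploitation(
    ret: ReturnTable, u: np.ndarray
) -> tuple[ReturnTable, ReturnTable]:
    """Split a return-year table into catch and escapement.

    ``u`` holds year x age exploitation rates in [0, 1] (broadcastable to the
    table's shape).  Catch is ``R * u``; escapement is the exact remainder,
    so catch + escapement == R cell by cell.
    """
    u = np.broadcast_to(np.asarray(u, dtype=float), ret.values.shape)
    with np.errstate(invalid="ignore"):
        if np.any((u < 0) | (u > 1)):
            raise ValueError("exploitation rates must lie in [0, 1]")
    catch = ret.values * u
    esc = ret.values - catch
    return (
        ReturnTable(years=ret.years.copy(), values=catch),
        ReturnTable(years=ret.years.copy(), values=esc),
    )


def brood_summaries(
    brood: BroodTable, ages: AgeStructure = DEFAULT_AGES
) -> pd.DataFrame:
    """Per-brood-year jack / nonjack abundance and jack proportion.

    Rows with any missing contributing cell, or a zero cohort, have an
    undefined proportion (NaN, flagged in the ``undefined`` column).
    """
    jack = brood.values[:, ages.jack_set].sum(axis=1)
    nonjack = brood.values[:, ages.nonjack_set].sum(axis=1)
    total = jack + nonjack
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(total > 0, jack / total, np.nan)
    undefined = ~(total > 0)  # NaN or zero
    return pd.DataFrame(
        {
            "brood_year": brood.years,
            "jack_abundance": jack,
            "nonjack_abundance": nonjack,
            "jack_proportion": prop,
            "undefined": undefined,
        }
    )


# ---------------------------------------------------------------------------
# Observation containers and tabular I/O
# ---------------------------------------------------------------------------

OBSERVATION_COLUMNS = [
    "return_year",
    "catch_total",
    "escapement_total",
    "male_jacks",
    "males_total",
    "females_total",
]


@dataclass
class ObservedCounts:
    """Return-year totals and weir census columns.

    One row per return year: total catch and escapement counts, the number of
    jacks among counted males, total males, and total females at the weir.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = set(OBSERVATION_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"observations missing columns: {sorted(missing)}")
        if df["return_year"].duplicated().any():
            dup = df.loc[df["return_year"].duplicated(), "return_year"].iloc[0]
            raise SchemaError(f"duplicated return year {dup}")
        for col in OBSERVATION_COLUMNS[1:]:
            bad = df.index[df[col].fillna(0) < 0]
            if len(bad):
                raise SchemaError(f"negative count in column {col}, row {bad[0]}")
        if (df["male_jacks"] > df["males_total"]).any():
            raise SchemaError("male_jacks exceeds males_total")
        self.table = df.sort_values("return_year").reset_index(drop=True)

    @property
    def years(self) -> np.ndarray:
        return self.table["return_year"].to_numpy()


@dataclass
class ScaleSamples:
    """Age counts from scale samples for one source (catch or escapement).

    Only the years present carry likelihood information; years in which no
    scales were collected are simply absent from the table.
    """

    source: str
    years: np.ndarray
    n_sample: np.ndarray
    counts: np.ndarray  # (n_years, 9) integers

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.n_sample = np.asarray(self.n_sample, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.source not in ("catch", "escapement"):
            raise SchemaError(f"unknown scale-sample source {self.source!r}")
        if len(np.unique(self.years)) != len(self.years):
            raise SchemaError("duplicated years in scale samples")
        if np.any(self.counts < 0):
            raise SchemaError("negative scale-sample count")
        row_sums = self.counts.sum(axis=1)
        if not np.array_equal(row_sums, self.n_sample):
            bad = int(self.years[np.nonzero(row_sums != self.n_sample)[0][0]])
            raise SchemaError(
                f"scale counts do not sum to recorded sample size in year {bad}"
            )


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise SchemaError(f"cannot parse {path}: {exc}") from exc


def _check_rare_age_columns(df: pd.DataFrame, path) -> pd.DataFrame:
    """Drop rare age-class columns (ocean/freshwater age 4) with a warning."""
    rare = [c for c in df.columns if c.startswith("o4_") or c.endswith("_f4")
            or (c.startswith("z_o4") or (c.startswith("z_") and c.endswith("_f4")))]
    if rare:
        dropped = df[rare].to_numpy(dtype=float)
        mass = np.nansum(dropped)
        warnings.warn(
            f"{path}: dropping rare age-class columns {rare} "
            f"(total mass {mass:g}); only ocean/freshwater ages 1-3 are modeled"
        )
        df = df.drop(columns=rare)
    return df


def read_brood_table(path) -> BroodTable:
    """Read a brood-table CSV (``brood_year`` + the nine age columns)."""
    df = _check_rare_age_columns(_read_csv(path), path)
    missing = {"brood_year", *AGE_COLUMNS} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df["brood_year"].duplicated().any():
        dup = df.loc[df["brood_year"].duplicated(), "brood_year"].iloc[0]
        raise SchemaError(f"{path}: duplicated brood year {int(dup)}")
    df = df.sort_values("brood_year")
    vals = df[AGE_COLUMNS].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(vals < 0):
            y = int(df["brood_year"].to_numpy()[np.nonzero((vals < 0).any(axis=1))[0][0]])
            raise SchemaError(f"{path}: negative numbers-at-age in brood year {y}")
    return BroodTable(years=df["brood_year"].to_numpy(dtype=int), values=vals)


def read_observed_counts(path) -> ObservedCounts:
    """Read the return-year observation CSV."""
    return ObservedCounts(table=_read_csv(path))


def read_scale_samples(path, source: str) -> ScaleSamples:
    """Read one source's scale-sample CSV (years without samples are absent)."""
    df = _check_rare_age_columns(_read_csv(path), path)
    zcols = [f"z_{c}" for c in AGE_COLUMNS]
    missing = {"return_year", "n_sample", *zcols} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("return_year")
    return ScaleSamples(
        source=source,
        years=df["return_year"].to_numpy(dtype=int),
        n_sample=df["n_sample"].to_numpy(dtype=int),
        counts=df[zcols].to_numpy(dtype=int),
    )


def read_covariate_table(path) -> pd.DataFrame:
    """Read the annual environmental covariate CSV."""
    df = _read_csv(path)
    missing = {"year", "npgo", "kodiak_temp", "zoop_log_biomass"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df["year"].duplicated().any():
        dup = int(df.loc[df["year"].duplicated(), "year"].iloc[0])
        raise SchemaError(f"{path}: duplicated year {dup}")
    return df.sort_values("year").reset_index(drop=True)
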