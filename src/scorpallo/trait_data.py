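"""Species-level reproductive-trait tables and descriptive statistics.

The central container is :class:`TraitTable`, a thin validated wrapper around a
pandas DataFrame holding one row per species: mean body mass (g), mean testes
mass (mg), spermatophore trunk volume (mm^3), mean sperm-package length (um)
and the polyandry level (mean number of males a female accepts per reproductive
season, a proxy for sperm-competition risk).

A bundled fixture (``"vrech2014"``) carries the published eight-species
bothriurid scorpion dataset. Analysis columns (``lbm``, ``ltm``, ``lsv``,
``lsl``) are base-10 logarithms of the traits; polyandry (``pol``) enters the
models untransformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError, TraitDataError

#: CSV columns that must be present and strictly positive.
REQUIRED_COLUMNS = (
    "species",
    "body_mass_g",
    "testes_mass_mg",
    "spermatophore_volume_mm3",
    "sperm_length_um",
    "polyandry",
)

#: Optional dispersion / sample-size columns (non-negative where present).
OPTIONAL_COLUMNS = (
    "body_mass_sd",
    "n_males",
    "testes_mass_sd",
    "sperm_length_sd",
)

#: Analysis column -> (source column, multiplicative unit factor before log10).
#: Testes mass is converted mg -> g before the log so that intercepts of
#: testes-mass regressions are on the gram scale.
LOG_COLUMNS = {
    "lbm": ("body_mass_g", 1.0),
    "ltm": ("testes_mass_mg", 1e-3),
    "lsv": ("spermatophore_volume_mm3", 1.0),
    "lsl": ("sperm_length_um", 1.0),
}

ANALYSIS_COLUMNS = ("lbm", "ltm", "lsv", "lsl", "pol")

_FIXTURES = {"vrech2014": "vrech2014_traits.csv"}


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample (n-1) SD, range and size of a positive sample."""

    mean: float
    sd: float
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk statistic W in (0, 1], its p-value and the sample size."""

    W: float
    p: float
    n: int


@dataclass(frozen=True)
class AllometricFit:
    """Power-law relation y = a * x**b recovered from a log10-log10 line.

    ``a = 10**intercept`` (units of y at x = 1) and ``b = slope``
    (dimensionless scaling exponent).
    """

    a: float
    b: float
    intercept: float
    slope: float


def _normalize_name(name: str) -> str:
    return " ".join(str(name).replace("_", " ").split())


class TraitTable:
    """Validated species x trait table.

    Parameters
    ----------
    df:
        DataFrame with :data:`REQUIRED_COLUMNS`; extra columns are kept.

    Raises
    ------
    TraitDataError
        On missing columns, non-numeric or non-positive trait values,
        polyandry < 1, or duplicated species names.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TraitDataError(f"missing required column(s): {', '.join(missing)}")
        df["species"] = df["species"].map(_normalize_name)
        numeric = [c for c in df.columns if c != "species"]
        for col in numeric:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise TraitDataError(f"column {col!r} is not numeric: {exc}") from exc
        for col in REQUIRED_COLUMNS[1:]:
            if df[col].isna().any() or (df[col] <= 0).any():
                bad = df.loc[df[col].isna() | (df[col] <= 0), "species"].tolist()
                raise TraitDataError(
                    f"column {col!r} must be strictly positive; offending species: {bad}"
                )
        if (df["polyandry"] < 1).any():
            bad = df.loc[df["polyandry"] < 1, "species"].tolist()
            raise TraitDataError(f"polyandry must be >= 1; offending species: {bad}")
        dup = df["species"][df["species"].duplicated()].tolist()
        if dup:
            raise TraitDataError(f"duplicated species name(s): {dup}")
        self._df = df.reset_index(drop=True)

    # -- basic container protocol ------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, TraitTable) and self._df.equals(other._df)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying DataFrame (a copy; the table is immutable)."""
        return self._df.copy()

    @property
    def species(self) -> list[str]:
        return self._df["species"].tolist()

    @property
    def has_log_columns(self) -> bool:
        return all(c in self._df.columns for c in LOG_COLUMNS)

    def record(self, species: str) -> pd.Series:
        """Row for one species (name matched after whitespace normalization)."""
        name = _normalize_name(species)
        hit = self._df[self._df["species"] == name]
        if hit.empty:
            raise TraitDataError(f"species {name!r} not in table")
        return hit.iloc[0]

    def reordered(self, species_order: Sequence[str]) -> "TraitTable":
        """Return a copy with rows in ``species_order`` (must be a permutation)."""
        order = [_normalize_name(s) for s in species_order]
        if sorted(order) != sorted(self.species):
            extra = sorted(set(order) - set(self.species))
            miss = sorted(set(self.species) - set(order))
            raise TraitDataError(
                f"species_order is not a permutation of the table "
                f"(unknown: {extra}, missing: {miss})"
            )
        df = self._df.set_index("species").loc[order].reset_index()
        return TraitTable(df)

    def analysis_matrix(self, columns: Sequence[str]) -> np.ndarray:
        """Numeric matrix of analysis columns in row order."""
        if not self.has_log_columns:
            raise TraitDataError("call log10_columns() before extracting analysis columns")
        unknown = [c for c in columns if c not in self._df.columns]
        if unknown:
            raise TraitDataError(f"unknown analysis column(s): {unknown}")
        return self._df[list(columns)].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)


def load_trait_table(source) -> TraitTable:
    """Read a trait table from a CSV path or a named bundled fixture.

    ``load_trait_table("vrech2014")`` returns the published eight-species
    bothriurid dataset (species means and SDs, spermatophore volumes, sperm
    lengths and polyandry levels).
    """
    if isinstance(source, str) and source in _FIXTURES:
        ref = resources.files("scorpallo.data") / _FIXTURES[source]
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        try:
            df = pd.read_csv(source)
        except FileNotFoundError as exc:
            raise TraitDataError(f"trait CSV not found: {source}") from exc
        except pd.errors.ParserError as exc:
            raise TraitDataError(f"could not parse trait CSV {source}: {exc}") from exc
    table = TraitTable(df)
    return log10_columns(table, strict=False)


def gsi(body_mass_g, testes_mass_mg):
    """Gonadosomatic index: gonad mass as a percentage of body mass.

    ``100 * (testes_mass_mg / 1000) / body_mass_g``. Accepts scalars or
    arrays; both inputs must be strictly positive.
    """
    bm = np.asarray(body_mass_g, dtype=float)
    tm = np.asarray(testes_mass_mg, dtype=float)
    if np.any(bm <= 0) or np.any(tm <= 0):
        raise TraitDataError("gsi() requires strictly positive masses")
    out = 100.0 * (tm / 1000.0) / bm
    return float(out) if out.ndim == 0 else out


def log10_columns(table: TraitTable, strict: bool = True) -> TraitTable:
    """Return a table with log10 analysis columns lbm/ltm/lsv/lsl and pol.

    Testes mass is converted to grams before the log (see
    :data:`LOG_COLUMNS`); polyandry is copied untransformed. With
    ``strict=True`` a table that already carries the log columns raises
    (guarding accidental double transformation); ``strict=False`` makes the
    call a no-op in that case.
    """
    if table.has_log_columns:
        if strict:
            raise TraitDataError("table already has log10 columns (lbm/ltm/lsv/lsl)")
        return table
    df = table.df
    for col, (src, factor) in LOG_COLUMNS.items():
        values = df[src] * factor
        if (values <= 0).any():
            bad = df.loc[values <= 0, "species"].tolist()
            raise TraitDataError(f"cannot log-transform non-positive {src} for {bad}")
        df[col] = np.log10(values)
    df["pol"] = df["polyandry"]
    return TraitTable(df)


def summarize(values: Iterable[float]) -> SummaryStats:
    """Mean, sample SD (n-1 divisor), min, max and n of a sample."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise TraitDataError("summarize() requires a non-empty sample")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return SummaryStats(
        mean=float(arr.mean()), sd=sd, min=float(arr.min()), max=float(arr.max()),
        n=int(arr.size),
    )


def shapiro_wilk(values: Iterable[float]) -> NormalityResult:
    """Shapiro-Wilk normality test (Royston's approximation, via scipy).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    arr = np.asarray(list(values), dtype=float)
    if not 3 <= arr.size <= 5000:
        raise TraitDataError(f"shapiro_wilk() needs 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise NumericalError("shapiro_wilk() is undefined for a constant sample")
    res = stats.shapiro(arr)
    return NormalityResult(W=float(res.statistic), p=float(res.pvalue), n=int(arr.size))


def allometry_from_loglog(intercept: float, slope: float) -> AllometricFit:
    """Convert a log10-log10 regression line into the power law y = a x**b."""
    if not (math.isfinite(intercept) and math.isfinite(slope)):
        raise TraitDataError("allometry_from_loglog() requires finite inputs")
    return AllometricFit(a=10.0 ** intercept, b=slope, intercept=intercept, slope=slope)


def spermatophore_volume(trunk_area_mm2: float, trunk_width_mm: float) -> float:
    """Spermatophore trunk volume (mm^3) as trunk area (mm^2) x width (mm)."""
    if trunk_area_mm2 <= 0 or trunk_width_mm <= 0:
        raise TraitDataError("spermatophore_volume() requires positive area and width")
    return float(trunk_area_mm2) * float(trunk_width_mm)
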