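"""Reading, validating and writing composition panels and factor panels.

A *composition panel* is a year-by-category table of percentage shares
(each year sums to 100%), e.g. the age structure of a health workforce.
A *factor panel* holds one positive reference series (a resource count)
and one or more positive comparison series (candidate drivers) over the
same calendar years.

The canonical on-disk form is delimiter-separated text with years as
rows; XLSX sheets with the same layout are ingested through the same
schema. Readers validate and never silently renormalise.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TableDialect",
    "CompositionPanel",
    "FactorPanel",
    "PanelValidationError",
    "read_composition_panel",
    "read_factor_panel",
    "write_composition_panel",
    "write_factor_panel",
    "write_result_table",
    "round_half_up",
]


class PanelValidationError(ValueError):
    """Raised when an input table violates a panel invariant."""


def round_half_up(x: float, decimals: int) -> float:
    """Round to ``decimals`` places with ties going away from zero.

    Matches how published statistical tables are typically rounded
    (``round`` in Python rounds ties to even). Values are first snapped
    at ``decimals + 8`` places so that quantities that are exact decimal
    ties in real arithmetic (e.g. 0.011/0.032 = 0.34375) are not pushed
    off the tie by binary floating-point representation.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    snapped = round(float(x), decimals + 8)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(snapped)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TableDialect:
    """How tables are laid out and rounded on disk.

    ``value_decimals`` applies to dimensionless values (structural change
    values, grey coefficients and degrees); ``percent_decimals`` to
    percentages. Years are always rows.
    """

    delimiter: str = ","
    value_decimals: int = 3
    percent_decimals: int = 2

    def __post_init__(self) -> None:
        if self.value_decimals < 0 or self.percent_decimals < 0:
            raise ValueError("decimal places must be >= 0")


@dataclass(frozen=True)
class CompositionPanel:
    """Percentage shares of one workforce attribute, by year and category.

    Invariants (checked at construction): years strictly increasing with
    no gaps; every row of ``shares`` sums to 100 within ``row_sum_tol``
    percentage points (default 0.5, absorbing published rounding); all
    shares non-negative.
    """

    attribute_name: str
    years: tuple[int, ...]
    categories: tuple[str, ...]
    shares: np.ndarray  # (n_years, n_categories), percent
    row_sum_tol: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        shares = np.asarray(self.shares, dtype=float)
        object.__setattr__(self, "shares", shares)
        if shares.ndim != 2 or shares.shape != (len(self.years), len(self.categories)):
            raise PanelValidationError(
                f"shares must be a {len(self.years)}x{len(self.categories)} matrix, "
                f"got shape {shares.shape}"
            )
        if len(self.years) == 0:
            raise PanelValidationError("panel has no years")
        diffs = np.diff(self.years)
        if np.any(diffs <= 0):
            raise PanelValidationError(f"years must be strictly increasing: {self.years}")
        if np.any(diffs != 1):
            raise PanelValidationError(f"non-consecutive years: {self.years}")
        if not np.all(np.isfinite(shares)):
            raise PanelValidationError("non-numeric or non-finite share value")
        if np.any(shares < 0):
            y, c = np.argwhere(shares < 0)[0]
            raise PanelValidationError(
                f"negative share for year {self.years[y]}, "
                f"category {self.categories[c]!r}"
            )
        sums = shares.sum(axis=1)
        bad = np.abs(sums - 100.0) > self.row_sum_tol
        if np.any(bad):
            i = int(np.argmax(bad))
            raise PanelValidationError(
                f"shares for year {self.years[i]} sum to {sums[i]:.2f}, "
                f"outside 100 ± {self.row_sum_tol}"
            )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.shares, index=pd.Index(self.years, name="year"), columns=self.categories
        )


@dataclass(frozen=True)
class FactorPanel:
    """A positive reference series plus m positive comparison series.

    All series share the same strictly increasing calendar years.
    Positivity is required because initial-value normalisation divides
    by the first observation.
    """

    years: tuple[int, ...]
    reference_name: str
    reference: np.ndarray  # (n,)
    comparison_names: tuple[str, ...]
    comparisons: np.ndarray  # (m, n)

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "comparison_names", tuple(self.comparison_names))
        ref = np.asarray(self.reference, dtype=float)
        comp = np.asarray(self.comparisons, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "comparisons", comp)
        n = len(self.years)
        if n < 2:
            raise PanelValidationError("factor panel needs at least 2 years")
        if np.any(np.diff(self.years) <= 0):
            raise PanelValidationError(f"years must be strictly increasing: {self.years}")
        if ref.shape != (n,):
            raise PanelValidationError(f"reference must have length {n}")
        if comp.ndim != 2 or comp.shape[1] != n or comp.shape[0] < 1:
            raise PanelValidationError(
                f"comparisons must be an m x {n} matrix with m >= 1, got {comp.shape}"
            )
        if len(self.comparison_names) != comp.shape[0]:
            raise PanelValidationError("one name required per comparison series")
        for name, series in [(self.reference_name, ref)] + list(
            zip(self.comparison_names, comp)
        ):
            if not np.all(np.isfinite(series)):
                raise PanelValidationError(f"non-finite value in series {name!r}")
            nonpos = series <= 0
            if np.any(nonpos):
                k = int(np.argmax(nonpos))
                raise PanelValidationError(
                    f"series {name!r} has non-positive value {series[k]} "
                    f"in year {self.years[k]}; all series must be strictly positive"
                )

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_comparisons(self) -> int:
        return self.comparisons.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data = {self.reference_name: self.reference}
        data.update(dict(zip(self.comparison_names, self.comparisons)))
        return pd.DataFrame(data, index=pd.Index(self.years, name="year"))


def _read_table(path: str | Path, dialect: TableDialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=dialect.delimiter)
    if df.shape[1] < 2:
        raise PanelValidationError(
            f"{path}: need a year column plus at least one data column"
        )
    year_col = df.columns[0]
    years = pd.to_numeric(df[year_col], errors="coerce")
    if years.isna().any():
        row = int(years.index[years.isna()][0])
        raise PanelValidationError(f"{path}: missing or non-numeric year in row {row}")
    df = df.set_index(years.astype(int).rename("year")).drop(columns=[year_col])
    df = df.sort_index()
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            year = int(vals.index[vals.isna()][0])
            raise PanelValidationError(
                f"{path}: non-numeric cell in column {col!r}, year {year}"
            )
        df[col] = vals.astype(float)
    return df


def read_composition_panel(
    path: str | Path,
    dialect: TableDialect | None = None,
    *,
    attribute_name: str | None = None,
    row_sum_tol: float = 0.5,
) -> CompositionPanel:
    """Read a year-by-category share table (CSV/TSV or XLSX).

    The header row names the categories; the first column holds calendar
    years. Raises :class:`PanelValidationError` naming the offending
    row/column if the table violates a panel invariant.
    """
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect)
    return CompositionPanel(
        attribute_name=attribute_name or Path(path).stem,
        years=tuple(df.index),
        categories=tuple(str(c) for c in df.columns),
        shares=df.to_numpy(),
        row_sum_tol=row_sum_tol,
    )


def read_factor_panel(
    path: str | Path,
    dialect: TableDialect | None = None,
    *,
    reference: str | None = None,
) -> FactorPanel:
    """Read a factor table: years in the first column, series in the rest.

    By default the first data column is the reference series; pass
    ``reference=<column name>`` to designate any column regardless of
    position.
    """
    dialect = dialect or TableDialect()
    df = _read_table(path, dialect)
    cols = [str(c) for c in df.columns]
    if reference is None:
        ref_name = cols[0]
    else:
        if reference not in cols:
            raise PanelValidationError(
                f"{path}: reference column {reference!r} not found among {cols}"
            )
        ref_name = reference
    comp_names = [c for c in cols if c != ref_name]
    return FactorPanel(
        years=tuple(df.index),
        reference_name=ref_name,
        reference=df[ref_name].to_numpy(),
        comparison_names=tuple(comp_names),
        comparisons=df[comp_names].to_numpy().T,
    )


def _write_frame(df: pd.DataFrame, path: str | Path, dialect: TableDialect) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=dialect.delimiter)


def write_composition_panel(
    panel: CompositionPanel, path: str | Path, dialect: TableDialect | None = None
) -> None:
    dialect = dialect or TableDialect()
    df = panel.to_frame().map(lambda v: round_half_up(v, dialect.percent_decimals))
    _write_frame(df, path, dialect)


def write_factor_panel(
    panel: FactorPanel, path: str | Path, dialect: TableDialect | None = None
) -> None:
    dialect = dialect or TableDialect()
    _write_frame(panel.to_frame(), path, dialect)


def write_result_table(result, path: str | Path, dialect: TableDialect | None = None) -> None:
    """Write a finalized result table to delimited text.

    Accepts a :class:`~greyhealth.structural_change.StructuralChangeTable`
    (one row per period: structural change values, the degree, then the
    contribution rates) or a :class:`~greyhealth.grey_relational.GreyResult`
    (one coefficient row per year, then "Relational degree" and "Rank by
    relational degree" rows). Display rounding (half-up, per the dialect)
    happens here and only here.
    """
    dialect = dialect or TableDialect()
    # imported lazily to avoid a circular import with the analysis modules
    from .grey_relational import GreyResult
    from .structural_change import StructuralChangeTable

    if isinstance(result, StructuralChangeTable):
        if len(result.periods) == 0:
            raise ValueError("empty result: no periods to write")
        _write_frame(result.to_frame(dialect), path, dialect)
    elif isinstance(result, GreyResult):
        if len(result.factor_names) == 0:
            raise ValueError("empty result: no factors to write")
        _write_frame(result.to_frame(dialect), path, dialect)
    else:
        raise TypeError(
            "write_result_table expects a StructuralChangeTable or GreyResult, "
            f"got {type(result).__name__}"
        )
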