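"""Structural change analysis of compositional time series.

For a composition observed annually (category shares summing to 100%),
three quantities summarise how the structure moves between consecutive
years:

* **structural change value (SCV)** — for each category, the
  end-of-period share minus the beginning-of-period share, expressed as
  a signed fraction (a +1.8 percentage-point move is 0.018); positive
  means the category's share is rising;
* **structural change degree (SCD)** — the sum of absolute SCVs across
  categories, in percent: how much the whole composition moved;
* **structural change contribution rate (SCC)** — one category's |SCV|
  as a percentage of the SCD: its share of the period's total movement.

Periods follow the convention (year t-1 → year t) and are labelled by
their end year. An optional baseline share vector for the year before
the panel adds a first period (baseline → first panel year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import CompositionPanel, TableDialect, round_half_up

__all__ = [
    "StructuralChangeTable",
    "structural_change_values",
    "structural_change_degree",
    "contribution_rates",
    "classify_trend",
    "run_structural_change",
]

#: trend label for an all-zero SCV column
NO_CHANGE = "no change"


@dataclass(frozen=True)
class StructuralChangeTable:
    """Full structural-change decomposition of one composition panel.

    ``scv`` is (periods × categories) signed fractions; ``scd`` is the
    per-period degree in percent; ``scc`` is (periods × categories)
    contribution rates in percent. ``degenerate`` flags periods with no
    movement at all (SCD = 0), whose contribution rates are reported as
    zeros rather than NaN. ``trend`` gives one per-category label in
    {"positive", "negative", "mixed", "no change"}.
    """

    attribute_name: str
    periods: tuple[tuple[int, int], ...]
    categories: tuple[str, ...]
    scv: np.ndarray
    scd: np.ndarray
    scc: np.ndarray
    degenerate: np.ndarray  # bool, per period
    trend: tuple[str, ...]
    scd_threshold: float | None = None  # optional user cutoff for "active" change

    @property
    def end_years(self) -> tuple[int, ...]:
        return tuple(p[1] for p in self.periods)

    def active_periods(self) -> tuple[int, ...]:
        """End years whose SCD meets the user-set threshold (if any)."""
        if self.scd_threshold is None:
            return ()
        return tuple(
            y for y, d in zip(self.end_years, self.scd) if d >= self.scd_threshold
        )

    def to_frame(self, dialect: TableDialect | None = None) -> pd.DataFrame:
        """Tabular layout: SCV columns, degree, SCC columns, rounded for display."""
        dialect = dialect or TableDialect()
        vd, pdp = dialect.value_decimals, dialect.percent_decimals
        data: dict[str, list[float]] = {}
        for j, cat in enumerate(self.categories):
            data[f"SCV {cat}"] = [round_half_up(v, vd) for v in self.scv[:, j]]
        data["Structural change degree (%)"] = [round_half_up(v, pdp) for v in self.scd]
        for j, cat in enumerate(self.categories):
            data[f"SCC {cat} (%)"] = [round_half_up(v, pdp) for v in self.scc[:, j]]
        return pd.DataFrame(data, index=pd.Index(self.end_years, name="year"))


def structural_change_values(
    panel: CompositionPanel, baseline: np.ndarray | None = None
) -> np.ndarray:
    """First differences of the share rows, as signed fractions.

    Row t is (shares(t) - shares(t-1)) / 100 for consecutive year pairs.
    If ``baseline`` (the share vector of the year preceding the panel)
    is given, an extra first row covers (baseline → first panel year).
    """
    shares = panel.shares
    if baseline is not None:
        baseline = np.asarray(baseline, dtype=float)
        if baseline.shape != (panel.n_categories,):
            raise ValueError(
                f"baseline must have one share per category ({panel.n_categories})"
            )
        if abs(baseline.sum() - 100.0) > panel.row_sum_tol:
            raise ValueError(
                f"baseline shares sum to {baseline.sum():.2f}, outside "
                f"100 ± {panel.row_sum_tol}"
            )
        shares = np.vstack([baseline, shares])
    if shares.shape[0] < 2:
        raise ValueError("no period to difference: need >= 2 years or a baseline")
    return np.diff(shares, axis=0) / 100.0


def structural_change_degree(scv_row: np.ndarray) -> float:
    """100 × the sum of absolute structural change values, in percent."""
    return float(100.0 * np.abs(np.asarray(scv_row, dtype=float)).sum())


def contribution_rates(scv_row: np.ndarray) -> tuple[np.ndarray, bool]:
    """Each category's |SCV| as a percentage of the period's degree.

    Returns ``(rates, degenerate)``; for an all-zero row the rates are
    all zeros and ``degenerate`` is True (0/0 is never formed).
    """
    a = np.abs(np.asarray(scv_row, dtype=float))
    total = a.sum()
    if total == 0.0:
        return np.zeros_like(a), True
    return 100.0 * a / total, False


def classify_trend(scv_column: np.ndarray, majority: float = 0.5) -> str:
    """Direction label for one category's SCVs across periods.

    "positive" if the column sums above zero and strictly more than
    ``majority`` of the nonzero entries are positive; "negative"
    symmetrically; "no change" for an all-zero column; otherwise "mixed".
    """
    col = np.asarray(scv_column, dtype=float)
    if col.size == 0:
        raise ValueError("need at least one period")
    nonzero = col[col != 0]
    if nonzero.size == 0:
        return NO_CHANGE
    n_pos = int((nonzero > 0).sum())
    n_neg = int((nonzero < 0).sum())
    total = col.sum()
    if total > 0 and n_pos > majority * nonzero.size:
        return "positive"
    if total < 0 and n_neg > majority * nonzero.size:
        return "negative"
    return "mixed"


def run_structural_change(
    panel: CompositionPanel,
    baseline: np.ndarray | None = None,
    *,
    majority: float = 0.5,
    scd_threshold: float | None = None,
) -> StructuralChangeTable:
    """Full decomposition of a panel into SCV, SCD, SCC and trend labels.

    All arithmetic is full precision; display rounding happens only when
    the table is serialised.
    """
    scv = structural_change_values(panel, baseline)
    scd = np.array([structural_change_degree(row) for row in scv])
    scc_rows, degenerate = [], []
    for row in scv:
        rates, degen = contribution_rates(row)
        scc_rows.append(rates)
        degenerate.append(degen)
    if baseline is not None:
        start_years = (panel.years[0] - 1,) + panel.years[:-1]
        end_years = panel.years
    else:
        start_years, end_years = panel.years[:-1], panel.years[1:]
    periods = tuple(zip(start_years, end_years))
    trend = tuple(classify_trend(scv[:, j], majority) for j in range(scv.shape[1]))
    return StructuralChangeTable(
        attribute_name=panel.attribute_name,
        periods=periods,
        categories=panel.categories,
        scv=scv,
        scd=scd,
        scc=np.array(scc_rows),
        degenerate=np.array(degenerate, dtype=bool),
        trend=trend,
        scd_threshold=scd_threshold,
    )
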