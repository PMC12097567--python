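"""Deng-style grey relational analysis (GRA).

GRA scores how similar the geometric *shape* of each comparison series
is to a reference series — here, how closely candidate drivers
(population, economic and social indicators) track an annual resource
count. It is suited to short annual panels ("small sample, poor
information" systems) where regression would be badly overfit.

Pipeline, for reference x0 and comparisons x1..xm over n years:

1. dimensionless normalisation (default: divide each series by its
   first value, so every series starts at 1);
2. absolute difference matrix Δ_i(k) = |x0'(k) - x_i'(k)| and its
   two-level (global) extrema over all i and k;
3. grey relational coefficients
   ξ_i(k) = (Δmin + ρ·Δmax) / (Δ_i(k) + ρ·Δmax)
   with discrimination (resolution) coefficient ρ, conventionally 0.5;
4. relational degree r_i = mean_k ξ_i(k), and ranking (rank 1 = most
   closely related factor).

Note the set dependence inherited from the global extrema: adding or
removing a comparison series can change every coefficient. Degrees are
invariant to the *ordering* of series, and to rescaling any input
series by a positive constant (under initial-value normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .panel_io import FactorPanel, TableDialect, round_half_up

__all__ = [
    "GreyConfig",
    "GreyResult",
    "normalize_initial_value",
    "normalize_mean_value",
    "delta_matrix",
    "grey_coefficients",
    "relational_degree",
    "rank_factors",
    "run_gra",
]


@dataclass(frozen=True)
class GreyConfig:
    """Tunable parameters of the analysis.

    ``rho`` in (0, 1] controls contrast between coefficients (smaller =
    more discrimination); ``normalization`` is "initial_value" (divide
    by the first observation), "mean_value" (divide by the series mean)
    or "none". The degree is always the unweighted arithmetic mean of a
    factor's coefficients over years.
    """

    rho: float = 0.5
    normalization: str = "initial_value"

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.normalization not in {"initial_value", "mean_value", "none"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class GreyResult:
    """Everything the analysis produces, at full precision.

    ``ranks`` assigns 1 to the largest degree; tied degrees share the
    smaller (dense) rank and the tied groups are listed in ``ties``.
    """

    years: tuple[int, ...]
    reference_name: str
    factor_names: tuple[str, ...]
    normalized_reference: np.ndarray  # (n,)
    normalized_comparisons: np.ndarray  # (m, n)
    delta: np.ndarray  # (m, n)
    global_min: float
    global_max: float
    coefficients: np.ndarray  # (m, n)
    degrees: np.ndarray  # (m,)
    ranks: np.ndarray  # (m,) int, 1 = largest degree
    ties: tuple[tuple[str, ...], ...]
    config: GreyConfig

    def to_frame(self, dialect: TableDialect | None = None) -> pd.DataFrame:
        """One coefficient row per year, then degree and rank rows."""
        dialect = dialect or TableDialect()
        vd = dialect.value_decimals
        body = {
            name: [round_half_up(v, vd) for v in self.coefficients[i]]
            for i, name in enumerate(self.factor_names)
        }
        # object dtype so the rank row stays integer alongside float coefficients
        df = pd.DataFrame(body, index=[str(y) for y in self.years]).astype(object)
        df.loc["Relational degree"] = [round_half_up(v, vd) for v in self.degrees]
        df.loc["Rank by relational degree"] = [int(r) for r in self.ranks]
        df.index.name = "Year"
        return df


def normalize_initial_value(series: np.ndarray) -> np.ndarray:
    """Divide a strictly positive series by its first value (x'(1) = 1)."""
    x = np.asarray(series, dtype=float)
    if np.any(x <= 0):
        raise ValueError("initial-value normalization requires strictly positive series")
    return x / x[0]


def normalize_mean_value(series: np.ndarray) -> np.ndarray:
    """Divide a strictly positive series by its arithmetic mean."""
    x = np.asarray(series, dtype=float)
    if np.any(x <= 0):
        raise ValueError("mean-value normalization requires strictly positive series")
    return x / x.mean()


def delta_matrix(
    ref_norm: np.ndarray, comp_norms: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Absolute differences from the reference, with two-level extrema.

    Returns ``(delta, global_min, global_max)`` where the extrema are
    taken over all comparison series and all time points.
    """
    ref = np.asarray(ref_norm, dtype=float)
    comp = np.atleast_2d(np.asarray(comp_norms, dtype=float))
    if comp.shape[1] != ref.shape[0]:
        raise ValueError(
            f"length mismatch: reference has {ref.shape[0]} points, "
            f"comparisons have {comp.shape[1]}"
        )
    delta = np.abs(comp - ref[np.newaxis, :])
    return delta, float(delta.min()), float(delta.max())


def grey_coefficients(
    delta: np.ndarray, global_min: float, global_max: float, rho: float = 0.5
) -> np.ndarray:
    """Pointwise similarity ξ = (Δmin + ρ·Δmax) / (Δ + ρ·Δmax) in (0, 1].

    If ``global_max`` is 0 every comparison series is identical to the
    reference and all coefficients are 1.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    if global_max < global_min or global_min < 0:
        raise ValueError("need global_max >= global_min >= 0")
    delta = np.asarray(delta, dtype=float)
    if global_max == 0.0:
        return np.ones_like(delta)
    return (global_min + rho * global_max) / (delta + rho * global_max)


def relational_degree(coefficient_row: np.ndarray) -> float:
    """Arithmetic mean of one factor's coefficients over the years."""
    row = np.asarray(coefficient_row, dtype=float)
    if row.size == 0:
        raise ValueError("empty coefficient row")
    return float(row.mean())


def rank_factors(degrees: np.ndarray) -> np.ndarray:
    """Dense ranks, 1 for the largest degree; ties share the smaller rank."""
    d = np.asarray(degrees, dtype=float)
    if d.size == 0:
        raise ValueError("empty degree vector")
    return rankdata(-d, method="dense").astype(int)


def _tie_groups(names: tuple[str, ...], degrees: np.ndarray) -> tuple[tuple[str, ...], ...]:
    groups: dict[float, list[str]] = {}
    for name, d in zip(names, degrees):
        groups.setdefault(float(d), []).append(name)
    return tuple(tuple(g) for g in groups.values() if len(g) > 1)


def run_gra(panel: FactorPanel, config: GreyConfig | None = None) -> GreyResult:
    """Run the whole analysis on a factor panel."""
    config = config or GreyConfig()
    if config.normalization == "initial_value":
        norm = normalize_initial_value
    elif config.normalization == "mean_value":
        norm = normalize_mean_value
    else:
        norm = lambda x: np.asarray(x, dtype=float)
    ref_norm = norm(panel.reference)
    comp_norms = np.vstack([norm(row) for row in panel.comparisons])
    delta, gmin, gmax = delta_matrix(ref_norm, comp_norms)
    xi = grey_coefficients(delta, gmin, gmax, config.rho)
    degrees = np.array([relational_degree(row) for row in xi])
    ranks = rank_factors(degrees)
    return GreyResult(
        years=panel.years,
        reference_name=panel.reference_name,
        factor_names=panel.comparison_names,
        normalized_reference=ref_norm,
        normalized_comparisons=comp_norms,
        delta=delta,
        global_min=gmin,
        global_max=gmax,
        coefficients=xi,
        degrees=degrees,
        ranks=ranks,
        ties=_tie_groups(panel.comparison_names, degrees),
        config=config,
    )
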