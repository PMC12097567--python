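"""Synthetic composition and factor panels with known, planted structure.

The generator emulates the statistical shape of annual health-workforce
yearbook data: a handful of years, category shares summing to 100% with
smooth drifts, and positive driver series growing at a few percent a
year. Drifts and per-factor association strengths are *planted*, so
recovery (estimated drift ≈ specified drift; the high-association
factor ranking first in grey relational analysis) is testable without
any external data.

Shares follow a linear trend in percentage points, perturbed on the
log-odds scale and renormalised — the simplest construction that keeps
every share in (0, 100) and every row summing to 100. Factor series are
a convex blend (weight = association) of the reference's normalised
trajectory with an independent smooth growth path, rescaled to the
factor's own level, with multiplicative log-normal noise — positive
levels stay positive.

One integer seed drives a single `numpy.random.Generator` for the whole
panel, so every generated object is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import CompositionPanel, FactorPanel

__all__ = [
    "SyntheticSpec",
    "generate_composition_panel",
    "generate_factor_panel",
    "study_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic panel pair.

    Composition side: ``start_shares`` (percent, summing to 100) drift
    by ``drift`` percentage points per year with log-odds noise of scale
    ``share_noise``. Factor side: the reference grows at
    ``reference_growth`` per year from ``reference_level``; factor i
    tracks the reference's normalised shape with weight
    ``association[i]`` in [0, 1], grows independently at
    ``factor_growth[i]`` otherwise, and carries multiplicative
    log-normal noise of scale ``factor_noise``.
    """

    n_years: int = 6
    start_year: int = 2017
    categories: tuple[str, ...] = ("A", "B", "C", "D", "E")
    start_shares: tuple[float, ...] = (30.0, 25.0, 20.0, 15.0, 10.0)
    drift: tuple[float, ...] = (1.0, 0.5, 0.0, -0.5, -1.0)  # points/year
    share_noise: float = 0.02
    factor_names: tuple[str, ...] = ("F1", "F2", "F3")
    factor_levels: tuple[float, ...] = (1000.0, 50.0, 10000.0)
    factor_growth: tuple[float, ...] = (0.03, 0.02, 0.05)
    association: tuple[float, ...] = (0.5, 0.5, 0.5)
    factor_noise: float = 0.02
    reference_name: str = "resource count"
    reference_level: float = 200000.0
    reference_growth: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("need n_years >= 2")
        if len(self.start_shares) != len(self.categories) or len(self.drift) != len(
            self.categories
        ):
            raise ValueError("start_shares and drift must match categories")
        if abs(sum(self.start_shares) - 100.0) > 1e-6:
            raise ValueError(f"start_shares must sum to 100, got {sum(self.start_shares)}")
        if abs(sum(self.drift)) > 1e-6:
            raise ValueError("drifts must sum to 0 so shares keep summing to 100")
        m = len(self.factor_names)
        if not (len(self.factor_levels) == len(self.factor_growth) == len(self.association) == m):
            raise ValueError("factor_levels, factor_growth, association must match factor_names")
        if any(not 0.0 <= a <= 1.0 for a in self.association):
            raise ValueError("association weights must lie in [0, 1]")
        if self.share_noise < 0 or self.factor_noise < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.start_year + self.n_years))


def generate_composition_panel(spec: SyntheticSpec) -> CompositionPanel:
    """Shares drifting linearly with compositional (log-odds) noise.

    Deterministic given ``spec.seed``. Raises if any drifting share
    would leave (0, 100) within the horizon. With zero noise the panel's
    per-period structural change values equal ``drift/100`` exactly; the
    log-odds perturbation keeps noisy rows valid compositions.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_years)[:, np.newaxis]
    mean = np.asarray(spec.start_shares) + t * np.asarray(spec.drift)
    if np.any(mean <= 0) or np.any(mean >= 100):
        bad = np.argwhere((mean <= 0) | (mean >= 100))[0]
        raise ValueError(
            f"infeasible drift: share of {spec.categories[bad[1]]!r} reaches "
            f"{mean[bad[0], bad[1]]:.2f}% in year {spec.years[bad[0]]}"
        )
    if spec.share_noise > 0:
        p = mean / 100.0
        logits = np.log(p / (1 - p)) + rng.normal(0, spec.share_noise, mean.shape)
        p = 1 / (1 + np.exp(-logits))
        shares = 100.0 * p / p.sum(axis=1, keepdims=True)
    else:
        shares = mean
    return CompositionPanel(
        attribute_name="synthetic",
        years=spec.years,
        categories=spec.categories,
        shares=shares,
    )


def _smooth_growth(level: float, rate: float, n: int, rng: np.random.Generator,
                   wobble: float = 0.01) -> np.ndarray:
    """A positive, smoothly growing path: compound growth with a mild
    random but serially smooth modulation of the annual rate."""
    rates = rate + wobble * np.cumsum(rng.normal(0, 1, n - 1)) / np.sqrt(n)
    return level * np.concatenate([[1.0], np.cumprod(1.0 + np.clip(rates, -0.5, None))])


def generate_factor_panel(spec: SyntheticSpec) -> FactorPanel:
    """Reference plus factor series with planted association strengths.

    Deterministic given ``spec.seed``. A factor with association 1 and
    zero noise is exactly proportional to the reference (grey relational
    degree 1); association 0 gives an independent smooth growth path.
    Multiplicative log-normal noise keeps all series strictly positive.
    """
    rng = np.random.default_rng(spec.seed + 1)  # independent of the share stream
    n = spec.n_years
    reference = spec.reference_level * np.cumprod(
        np.concatenate([[1.0], np.full(n - 1, 1.0 + spec.reference_growth)])
    )
    ref_shape = reference / reference[0]
    rows = []
    for level, growth, assoc in zip(
        spec.factor_levels, spec.factor_growth, spec.association
    ):
        own = _smooth_growth(1.0, growth, n, rng)
        shape = assoc * ref_shape + (1.0 - assoc) * own
        series = level * shape
        if spec.factor_noise > 0:
            for _ in range(10):  # bounded retries; log-normal noise stays positive
                noisy = series * rng.lognormal(0.0, spec.factor_noise, n)
                if np.all(noisy > 0):
                    series = noisy
                    break
            else:
                raise RuntimeError("could not generate a strictly positive series")
        rows.append(series)
    return FactorPanel(
        years=spec.years,
        reference_name=spec.reference_name,
        reference=reference,
        comparison_names=spec.factor_names,
        comparisons=np.vstack(rows),
    )


#: category rosters mirroring the four attributes of a national
#: oral-health workforce panel (ages, experience, education, title).
_FIXTURE_ATTRIBUTES = {
    "age": (
        ("<25", "25-34", "35-44", "45-54", "55-59", ">=60"),
        (3.0, 36.0, 32.0, 17.0, 5.0, 7.0),
        (0.3, 0.9, 0.2, -0.6, -0.3, -0.5),
    ),
    "experience": (
        ("<5", "5-9", "10-19", "20-29", ">=30"),
        (24.0, 21.0, 27.0, 17.0, 11.0),
        (1.0, 0.4, -0.4, -0.6, -0.4),
    ),
    "education": (
        ("postgraduate", "undergraduate", "college", "junior college", "high school or below"),
        (9.0, 31.0, 39.0, 17.0, 4.0),
        (0.2, 0.8, 0.7, -1.4, -0.3),
    ),
    "qualification": (
        ("senior", "associate senior", "intermediate", "junior", "pending", "unspecified"),
        (2.0, 7.0, 22.5, 46.6, 12.0, 9.9),
        (0.1, 0.2, 0.4, 1.1, -0.6, -1.2),
    ),
}

_FIXTURE_FACTORS = (
    ("resident population", 140000.0, 0.002, 0.2),
    ("share aged 65+", 11.0, 0.04, 0.7),
    ("dependency ratio", 40.0, 0.01, 0.6),
    ("urbanization level", 58.0, 0.015, 0.3),
    ("per capita GDP", 60000.0, 0.07, 0.75),
    ("per capita disposable income", 26000.0, 0.07, 0.8),
    ("per capita health expenditure", 3700.0, 0.09, 0.9),
    ("health expenditure / GDP", 6.3, 0.01, 0.5),
)


def study_fixture(seed: int = 20170) -> tuple[dict[str, CompositionPanel], FactorPanel]:
    """A deterministic panel set with the dimensions of a national
    oral-health workforce study: four composition panels (6/5/5/6
    categories) over six years, and one reference series with eight
    candidate drivers.

    All magnitudes are synthetic; only the dimensions, the positivity and
    the smooth-trend character of yearbook data are emulated.
    """
    panels: dict[str, CompositionPanel] = {}
    for i, (name, (cats, start, drift)) in enumerate(_FIXTURE_ATTRIBUTES.items()):
        spec = SyntheticSpec(
            categories=cats, start_shares=start, drift=drift,
            share_noise=0.02, seed=seed + i,
        )
        panel = generate_composition_panel(spec)
        panels[name] = CompositionPanel(
            attribute_name=name, years=panel.years,
            categories=panel.categories, shares=panel.shares,
        )
    names, levels, growths, assocs = zip(*_FIXTURE_FACTORS)
    fspec = SyntheticSpec(
        factor_names=names, factor_levels=levels, factor_growth=growths,
        association=assocs, factor_noise=0.02,
        reference_name="oral health workforce", reference_level=200000.0,
        reference_growth=0.06, seed=seed + 100,
    )
    return panels, generate_factor_panel(fspec)
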