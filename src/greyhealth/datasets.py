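"""Published summary statistics of China's oral-health workforce, 2017–2022.

These are the printed decomposition inputs and grey-relational
coefficient tables from a national analysis of oral licensed (assistant)
physicians: per-period structural change values (signed fractions) for
four workforce attributes, and yearly grey relational coefficients of
eight candidate driver factors against the workforce count. They serve
as real-world desk-scale inputs for the package's operations; each row
or column can be fed to :func:`~greyhealth.structural_change.structural_change_degree`,
:func:`~greyhealth.structural_change.contribution_rates` or
:func:`~greyhealth.grey_relational.relational_degree` directly.

Shares themselves are not reproduced here — only the published
derived rows needed to exercise the analysis operations.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "age_scv",
    "experience_scv",
    "education_scv",
    "qualification_scv",
    "gra_coefficients",
    "published_degrees",
    "published_ranks",
]

_YEARS = [2017, 2018, 2019, 2020, 2021, 2022]

_AGE_CATEGORIES = ["<25", "25-34", "35-44", "45-54", "55-59", ">=60"]
_AGE_SCV = [
    [0.001, -0.014, 0.007, -0.001, 0.001, 0.006],
    [0.001, -0.012, 0.011, -0.012, 0.013, -0.001],
    [0.003, 0.021, -0.009, -0.012, 0.000, -0.003],
    [0.018, 0.050, -0.024, -0.023, -0.008, -0.013],
    [-0.001, -0.004, 0.009, -0.004, 0.001, -0.001],
    [0.000, -0.002, 0.014, 0.000, -0.005, -0.007],
]

_EXPERIENCE_CATEGORIES = ["<5", "5-9", "10-19", "20-29", ">=30"]
_EXPERIENCE_SCV = [
    [0.008, 0.005, -0.002, -0.006, -0.005],
    [-0.010, 0.010, 0.006, -0.004, -0.002],
    [0.030, -0.002, -0.005, -0.016, -0.007],
    [0.085, -0.007, -0.025, -0.025, -0.028],
    [-0.003, 0.006, 0.005, -0.009, 0.001],
    [-0.009, 0.008, 0.014, -0.004, -0.009],
]

_EDUCATION_CATEGORIES = [
    "postgraduate", "undergraduate", "college", "junior college", "high school or below",
]
_EDUCATION_SCV = [
    [0.004, 0.009, 0.000, -0.011, -0.002],
    [0.001, 0.010, 0.013, -0.022, -0.002],
    [-0.002, 0.004, 0.012, -0.011, -0.003],
    [-0.002, 0.020, 0.006, -0.021, -0.003],
    [0.008, 0.010, -0.006, -0.011, -0.001],
    [0.001, -0.002, 0.009, -0.008, 0.000],
]

_QUALIFICATION_CATEGORIES = [
    "senior", "associate", "intermediate", "divisional/assistant", "bachelor", "unspecified",
]
_QUALIFICATION_SCV = [
    [-0.001, -0.002, -0.010, -0.005, -0.003, 0.021],
    [0.000, -0.003, -0.005, 0.024, 0.012, -0.028],
    [-0.001, -0.003, -0.007, 0.008, 0.007, -0.004],
    [0.000, -0.001, -0.003, -0.001, 0.005, 0.000],
    [0.002, 0.004, 0.023, 0.015, -0.003, -0.041],
    [-0.001, -0.001, 0.010, 0.011, 0.001, -0.020],
]

_FACTOR_NAMES = [
    "resident population",
    "share aged 65+",
    "dependency ratio",
    "urbanization level",
    "per capita GDP",
    "per capita disposable income",
    "per capita health expenditure",
    "health expenditure / GDP",
]
# yearly grey relational coefficients, one column per factor
_GRA_COEFFICIENTS = [
    [0.335, 0.476, 0.424, 0.369, 0.569, 0.569, 0.726, 0.383],
    [0.451, 0.634, 0.574, 0.487, 0.645, 0.672, 0.803, 0.519],
    [0.677, 0.832, 0.860, 0.699, 0.805, 0.778, 0.855, 0.703],
    [0.708, 0.833, 0.998, 0.750, 0.674, 0.781, 0.932, 1.000],
    [0.432, 0.582, 0.544, 0.467, 0.698, 0.662, 0.671, 0.424],
    [0.339, 0.509, 0.413, 0.368, 0.612, 0.574, 0.814, 0.384],
]
_PUBLISHED_DEGREES = [0.490, 0.644, 0.635, 0.523, 0.667, 0.673, 0.800, 0.569]
_PUBLISHED_RANKS = [8, 4, 5, 7, 3, 2, 1, 6]


def _scv_frame(rows, categories) -> pd.DataFrame:
    return pd.DataFrame(rows, index=pd.Index(_YEARS, name="year"), columns=categories)


def age_scv() -> pd.DataFrame:
    """Structural change values of the age structure (signed fractions)."""
    return _scv_frame(_AGE_SCV, _AGE_CATEGORIES)


def experience_scv() -> pd.DataFrame:
    """Structural change values of years of work experience."""
    return _scv_frame(_EXPERIENCE_SCV, _EXPERIENCE_CATEGORIES)


def education_scv() -> pd.DataFrame:
    """Structural change values of educational qualifications."""
    return _scv_frame(_EDUCATION_SCV, _EDUCATION_CATEGORIES)


def qualification_scv() -> pd.DataFrame:
    """Structural change values of professional/technical qualifications."""
    return _scv_frame(_QUALIFICATION_SCV, _QUALIFICATION_CATEGORIES)


def gra_coefficients() -> pd.DataFrame:
    """Yearly grey relational coefficients, factors as columns."""
    return pd.DataFrame(
        _GRA_COEFFICIENTS, index=pd.Index(_YEARS, name="year"), columns=_FACTOR_NAMES
    )


def published_degrees() -> pd.Series:
    """The published relational degree of each factor (3 d.p.)."""
    return pd.Series(_PUBLISHED_DEGREES, index=_FACTOR_NAMES, name="relational degree")


def published_ranks() -> pd.Series:
    """The published rank of each factor (1 = most closely related)."""
    return pd.Series(_PUBLISHED_RANKS, index=_FACTOR_NAMES, name="rank")
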