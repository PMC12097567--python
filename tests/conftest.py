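import numpy as np
import pytest

from greyhealth import SyntheticSpec, study_fixture
from greyhealth.synthetic_data import generate_factor_panel


@pytest.fixture(scope="session")
def fixture_panels():
    """Four composition panels + one factor panel with study-scale dims."""
    return study_fixture()


@pytest.fixture(scope="session")
def composition_panels(fixture_panels):
    return fixture_panels[0]


@pytest.fixture(scope="session")
def factor_panel(fixture_panels):
    return fixture_panels[1]


def recovery_spec(seed: int) -> SyntheticSpec:
    """One factor (index 0) planted with association 0.95; seven
    competitors with association <= 0.3 whose own growth paths differ
    appreciably from the reference's 6%/yr."""
    return SyntheticSpec(
        factor_names=tuple(f"f{i}" for i in range(8)),
        factor_levels=(1000.0, 50.0, 40.0, 60.0, 6e4, 2.6e4, 3.7e3, 6.3),
        factor_growth=(0.002, 0.10, 0.00, 0.12, 0.09, -0.02, 0.13, 0.11),
        association=(0.95, 0.3, 0.3, 0.2, 0.1, 0.25, 0.15, 0.0),
        reference_growth=0.06,
        seed=seed,
    )


def random_composition(rng: np.random.Generator, n_years: int = 6, n_cats: int = 5):
    """A random valid composition panel (Dirichlet rows, percent)."""
    from greyhealth import CompositionPanel

    shares = 100.0 * rng.dirichlet(np.full(n_cats, 5.0), size=n_years)
    return CompositionPanel(
        attribute_name="random",
        years=tuple(range(2017, 2017 + n_years)),
        categories=tuple(f"c{j}" for j in range(n_cats)),
        shares=shares,
    )


def random_factor_panel(rng: np.random.Generator, m: int = 4, n: int = 6):
    from greyhealth import FactorPanel

    return FactorPanel(
        years=tuple(range(2017, 2017 + n)),
        reference_name="ref",
        reference=np.exp(rng.normal(5, 0.5, n)),
        comparison_names=tuple(f"x{i}" for i in range(m)),
        comparisons=np.exp(rng.normal(3, 0.8, (m, n))),
    )
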