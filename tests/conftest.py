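import numpy as np
import pytest

import forestadapt as fa


@pytest.fixture(scope="session")
def plots_small():
    """A compact landscape shared by fast tests."""
    return fa.generate_plots(800, n_ecoregions=6, seed=11)


@pytest.fixture(scope="session")
def true_params():
    return fa.generate_true_parameters(3)


@pytest.fixture(scope="session")
def curve_df():
    return fa.YieldCurve("DF", 400.0, 0.05, 2.0)


def random_context(rng, params=None):
    """A random but valid single-plot choice context."""
    viable = tuple(
        np.random.default_rng(rng.integers(1 << 30)).choice(
            fa.FOREST_TYPES, size=rng.integers(2, 7), replace=False
        )
    )
    ft = viable[rng.integers(len(viable))]
    clim = np.array(
        [rng.uniform(100, 1200), rng.uniform(8, 20), 0.0, 0.0]
    )
    clim[2] = clim[1] + rng.uniform(5, 12)
    clim[3] = clim[1] - rng.uniform(8, 16)
    return fa.ChoiceContext(
        forest_type=ft,
        stand_age=float(rng.uniform(0, 90)),
        volume=float(rng.uniform(0, 600)),
        elevation=float(rng.uniform(0, 2000)),
        climate=clim,
        viable_types=viable,
        rents={t: float(rng.uniform(20, 250)) for t in viable},
        prices={t: float(rng.uniform(20, 60)) for t in fa.FOREST_TYPES},
        carbon_tax_clear=float(rng.uniform(0, 2000)),
        carbon_tax_partial=float(rng.uniform(0, 800)),
        yield_curve=fa.YieldCurve(ft, 400.0, 0.05, 2.0),
    )
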