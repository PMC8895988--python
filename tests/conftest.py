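import warnings

import numpy as np
import pandas as pd
import pytest

from phenopred import simulate


@pytest.fixture(scope="session")
def balanced_plots():
    """Balanced 20-genotype, 3-env, 2-rep design without block structure."""
    rng = np.random.default_rng(11)
    g = pd.Series(rng.normal(0, 2, 20), index=[f"G{i:02d}" for i in range(20)])
    vc = dict(sigma2_env=1.0, sigma2_gxe=2.0, sigma2_rep=0.5,
              sigma2_block=0.0, sigma2_eps=4.0, mu=10.0)
    plots = simulate.simulate_plots(
        g, simulate.DesignConfig(n_env=3, n_rep=2, n_blocks=1), vc, seed=11
    )
    return plots, g, vc


@pytest.fixture(scope="session")
def small_dataset():
    """Two-group synthetic dataset small enough for fast end-to-end tests."""
    cfg = simulate.SimConfig(
        population=simulate.PopulationConfig(
            group_sizes={"A": 40, "B": 40}, n_markers=300, fst=0.2
        ),
        trait=simulate.TraitConfig(n_qtl=40, h2_target=0.6),
        design=simulate.DesignConfig(n_env=2, n_rep=2, n_blocks=4),
        spectra=simulate.SpectraConfig(grid=(1250, 1349), n_bands=6),
        seed=5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def confounded_scenario():
    from phenopred import scenarios

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scenarios.confounded_landraces(seed=1)


@pytest.fixture(scope="session")
def panel_scenario():
    from phenopred import scenarios

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return scenarios.elite_landrace_panel(seed=1)
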