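import numpy as np
import pytest

import mmlst


CONGENERIC = dict(
    equivalence_trait="congeneric",
    equivalence_occasion="congeneric",
)


@pytest.fixture(scope="session")
def design_full():
    """The two-occasion, two-situation, two-method, three-indicator design."""
    return mmlst.make_design(3, 2, 2, 2)


@pytest.fixture(scope="session")
def options_congeneric():
    """Congeneric trait/occasion loadings; identified occasion-method
    factors (unit loadings)."""
    return mmlst.ModelOptions(**CONGENERIC)


@pytest.fixture(scope="session")
def fitted_full(design_full):
    """A converged fit of the full design on data from its own population."""
    opts = mmlst.ModelOptions(**CONGENERIC)
    config = mmlst.SimulationConfig(design_full, opts, n_subjects=3000, seed=42)
    data = mmlst.simulate_dataset(config)
    graph, theta_true = config.build()
    fit = mmlst.fit_model(data, graph, seed=1)
    return fit, graph, theta_true


@pytest.fixture(scope="session")
def small_lst_config():
    """A compact single-situation, single-method LST population (fast fits)."""
    design = mmlst.make_design(3, 1, 2, 1)
    opts = mmlst.ModelOptions(**CONGENERIC)
    return mmlst.SimulationConfig(design, opts, n_subjects=500, seed=7)


def make_interaction_config(n_subjects=800, seed=11, mean_structure=True):
    """A two-situation population with a person-by-situation interaction."""
    design = mmlst.make_design(3, 2, 2, 2)
    opts = mmlst.ModelOptions(
        structural="trait_interactions",
        mean_structure=mean_structure,
        cov_occasion=True,
        **CONGENERIC,
    )
    return mmlst.SimulationConfig(design, opts, n_subjects=n_subjects, seed=seed)
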