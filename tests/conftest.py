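import logging

import numpy as np
import pandas as pd
import pytest

import saiplan as sp

logging.getLogger("saiplan").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_occurrence():
    """Three plots, target species sets {A,B}, {B,C}, {C}."""
    df = pd.DataFrame(
        {"A": [1, 0, 0], "B": [1, 1, 0], "C": [0, 1, 1]},
        index=pd.Index(["p1", "p2", "p3"], name="plot_id"),
    )
    return sp.OccurrenceMatrix(df)


@pytest.fixture(scope="session")
def small_landscape():
    """A reduced synthetic landscape shared by read-only tests."""
    cfg = sp.SyntheticConfig(
        n_plots=60, n_species=80, n_threatened=12, n_covariates=4, collinear_pairs=1, seed=7
    )
    return sp.generate_landscape(cfg)


@pytest.fixture(scope="session")
def default_landscape():
    """The full emulated network (145 plots, 470 species, 37 threatened)."""
    return sp.generate_landscape(sp.default_config())
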