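"""Shared fixtures: one small synthetic study reused across test modules."""

import dendropy
import numpy as np
import pytest

from ornmeta import dataset as ds
from ornmeta import mcmc, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic study: 20 species, 150 associations, 2 trees."""
    cfg = simulate.SimConfig(n_species=20, n_rows=150, paired_rows=60,
                             seed=9, n_trees=2)
    df, trees, truth = simulate.simulate_dataset(cfg)
    return cfg, df, trees, truth


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    _, df, _, _ = small_sim
    return ds.build_dataset(df, dimorphism=df.attrs["dimorphism"])


@pytest.fixture(scope="session")
def small_trees(small_sim):
    _, _, trees, _ = small_sim
    return [dendropy.Tree.get(data=t, schema="newick", preserve_underscores=True)
            for t in trees]


@pytest.fixture(scope="session")
def small_fit(small_dataset, small_trees):
    """A quick pooled fit of the intercept+year model on the small study."""
    spec, _ = mcmc.model_registry()["1"]
    settings = mcmc.MCMCSettings(n_iter=800, burn_in=200, thin=5, n_trees=2)
    draws = mcmc.fit_model(small_dataset, small_trees, spec,
                           settings=settings, seed=7)
    design = mcmc.build_design(small_dataset, spec)
    return draws, design
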