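import numpy as np
import pandas as pd
import pytest

from nichesize import exposure_covariates as cov
from nichesize import phylo_mixed_model as pm
from nichesize import trait_cleaning as tc
from nichesize.synthetic_world import WorldConfig, generate_world


TINY = dict(n_species=6, obs_per_species=150, years=(1961, 1990),
            sites_per_species=8, n_lat=16, n_lon=24)


@pytest.fixture(scope="session")
def tiny_world():
    """A small but complete synthetic study (contamination at defaults)."""
    return generate_world(WorldConfig(seed=11, **TINY))


@pytest.fixture(scope="session")
def clean_world():
    """Same scale, no planted contamination (for model-level tests)."""
    return generate_world(WorldConfig(seed=12, juvenile_frac=0.0,
                                      outlier_frac=0.0, **TINY))


def model_table(world):
    """Covariate-complete z-scored table, as the fit stage builds it."""
    obs = world.observations.copy()
    obs = tc.assign_sites(obs)
    obs = tc.derive_size_metrics(obs)
    zed, _, _ = cov.zscore_columns(
        obs, ["log10_mass", "tpi", "api", "alu", "ulu", "year"])
    return cov.add_interactions(zed, [("tpi", "api"), ("tpi", "alu"),
                                      ("tpi", "ulu")])


@pytest.fixture(scope="session")
def clean_fit(clean_world):
    """A fitted PGLMM on the clean tiny world (shared across tests)."""
    table = model_table(clean_world)
    C = pm.phylo_correlation(clean_world.tree,
                             sorted(table["species_id"].unique()))
    design = pm.assemble(table, pm.ModelSpec(), C)
    result = pm.fit(design, vc_intervals=False)
    return table, design, result
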