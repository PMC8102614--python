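import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

import phyloyawn as py
from phyloyawn.io_data import aggregate_species, match_tree
from phyloyawn.pipeline import AnalysisPlan, fit_with_retry
from phyloyawn.bayes_model import ModelSpec


def prepared_clade(seed, n_species=25, clade="mammal", **cfg_kw):
    """Simulate a clade and return its tree-aligned species table."""
    cfg = py.SimulationConfig(seed=seed, n_species=n_species, **cfg_kw)
    ds = py.generate_dataset(cfg, clade=clade)
    table = aggregate_species(ds.events, ds.records)
    tree, table = match_tree(table, ds.tree)
    return ds, tree, table


@pytest.fixture(scope="session")
def plan():
    return AnalysisPlan(seed=11)


@pytest.fixture(scope="session")
def mammal_clade():
    return prepared_clade(101, n_species=25, clade="mammal",
                          beta0=np.log(3.4), beta=0.35)


@pytest.fixture(scope="session")
def bird_clade():
    return prepared_clade(102, n_species=25, clade="bird",
                          beta0=np.log(1.46), beta=0.20)


@pytest.fixture(scope="session")
def fitted_pair(plan, mammal_clade, bird_clade):
    """One Gamma GLMM fit per clade (shared across tests to bound runtime)."""
    fits = {}
    for label, (ds, tree, table) in (("mammal", mammal_clade),
                                     ("bird", bird_clade)):
        spec = ModelSpec(fixed_effects=("z_brain",))
        fits[label] = fit_with_retry(spec, table, plan, tree=tree,
                                     seed=plan.seed, attempts=4)
    return fits
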