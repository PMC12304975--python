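import numpy as np
import pandas as pd
import pytest

from rhizoface.config import DesignSpec, EffectSpec
from rhizoface import synthetic
from rhizoface.metabolomics import FeatureMatrix


@pytest.fixture(scope="session")
def noiseless_effects() -> EffectSpec:
    return EffectSpec(residual_cv=0.0, array_sd=0.0)


@pytest.fixture(scope="session")
def default_design() -> DesignSpec:
    return DesignSpec(seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset(default_design, noiseless_effects):
    tables, truth = synthetic.generate_measurements(default_design, noiseless_effects)
    bags, bag_truth = synthetic.generate_bags(default_design, noiseless_effects)
    tables["bags"] = bags
    return tables, truth.merge(bag_truth)


def make_feature_matrix(values_e, values_a, masses=None) -> FeatureMatrix:
    """One-or-more-feature matrix from explicit per-group abundances."""
    values_e = np.atleast_2d(np.asarray(values_e, dtype=float))
    values_a = np.atleast_2d(np.asarray(values_a, dtype=float))
    nf, ne = values_e.shape
    na = values_a.shape[1]
    features = pd.DataFrame({
        "feature_id": [f"F{i}" for i in range(nf)],
        "mz": np.linspace(100, 200, nf),
        "rt": np.linspace(1, 2, nf),
        "mode": ["positive"] * nf,
    })
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(ne + na)],
        "treatment": ["elevated"] * ne + ["ambient"] * na,
        "compartment": ["exudate"] * (ne + na),
        "root_dry_mass_g": masses if masses is not None else np.ones(ne + na),
    })
    return FeatureMatrix(features, samples, np.hstack([values_e, values_a]))
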