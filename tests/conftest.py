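import numpy as np
import pandas as pd
import pytest

import phenomix as px
from phenomix.data import Feature, FeatureSchema, PhenotypeCohort


def make_cohort(features: pd.DataFrame, schema: FeatureSchema, role=None, true_class=None):
    """Assemble a cohort with trivial covariates around a feature frame."""
    n = len(features)
    features = features.copy()
    features.index = pd.Index([f"I{i:05d}" for i in range(n)], name="individual_id")
    covs = pd.DataFrame({"sex": np.zeros(n), "age_years": np.full(n, 10.0)}, index=features.index)
    role = np.array(["proband"] * n, dtype=object) if role is None else np.asarray(role, dtype=object)
    return PhenotypeCohort(features=features, covariates=covs, role=role,
                           schema=schema, true_class=true_class)


@pytest.fixture(scope="session")
def small_schema():
    return FeatureSchema(
        (
            Feature("x_cont", "continuous", None, "attention"),
            Feature("x_bin", "binary", None, "anxiety/mood"),
            Feature("x_cat", "categorical", 4, "self-injury"),
        )
    )


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated 4-class demo cohort (probands only), used by several suites."""
    spec = px.spark_like_spec(n_individuals=800, n_siblings=0, separation=3.0, seed=42)
    return px.generate_cohort(spec).probands()


@pytest.fixture(scope="session")
def separated_fit(separated_cohort):
    return px.fit(separated_cohort, separated_cohort.schema, 4, px.FitConfig(n_init=4, seed=0))


@pytest.fixture(scope="session")
def null_cohort():
    """Zero-separation cohort: all classes share one distribution."""
    spec = px.spark_like_spec(n_individuals=600, n_siblings=0, separation=0.0, seed=7)
    return px.generate_cohort(spec).probands()
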