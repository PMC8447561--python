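import numpy as np
import pandas as pd
import pytest

from lipophen.cohort import CohortTable, FeatureSpec, PatientRecord
from lipophen.pipeline import run_derivation
from lipophen.simulate import default_derivation_config, generate_cohort


@pytest.fixture(scope="session")
def derivation_cohort():
    """One default synthetic derivation cohort with its latent labels."""
    table, labels = generate_cohort(default_derivation_config(n=172, seed=0))
    return table, labels


@pytest.fixture(scope="session")
def derivation_run(derivation_cohort):
    table, _ = derivation_cohort
    return run_derivation(table)


@pytest.fixture()
def tiny_cohort():
    """Three patients, two features, one missing cell."""
    schema = [
        FeatureSpec("hdl_c", "lipid", units="mg/dL", transform="log"),
        FeatureSpec("icam1", "endothelial", units="ng/mL", transform="log"),
    ]
    patients = [
        PatientRecord("p1", {"hdl_c": 22.0, "icam1": 390.5}, icu_days=3,
                      disposition="home", mortality_28d=False),
        PatientRecord("p2", {"hdl_c": 7.25}, icu_days=20,
                      organ_dysfunction_at_day14=True, disposition="ltac",
                      mortality_28d=False),
        PatientRecord("p3", {"hdl_c": 8.0, "icam1": 495.0}, icu_days=5,
                      death_day=5, disposition="died", mortality_28d=True),
    ]
    return CohortTable("tiny", schema, patients)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def planted_z_matrix(n=40, sep=3.0, seed=0):
    """Two well-separated blobs in z-space with ground-truth labels.

    Each cluster gets its own random feature-profile center (scale ``sep``)
    with small isotropic noise, so same-cluster profiles are strongly
    rank-correlated and cross-cluster profiles are not.  A uniform shift of
    all features would be invisible to the Spearman profile distance (it
    preserves within-profile rank order), hence distinct center patterns.
    """
    r = np.random.default_rng(seed)
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    centers = r.standard_normal((2, 12)) * sep
    X = centers[labels] + r.standard_normal((n, 12)) * 0.5
    return pd.DataFrame(X, index=[f"s{i:02d}" for i in range(n)]), labels
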