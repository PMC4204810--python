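import numpy as np
import pytest

from trajmix.latent_models import ModelParams, ModelSpec
from trajmix.synthetic_cohort import (
    AgeGrid,
    CohortTable,
    GenerativeTruth,
    MissingnessPlan,
    SYMPTOMS,
)


def build_cohort(y, y_mask, cohort=None, **aux) -> CohortTable:
    """Assemble a CohortTable straight from (N, S, T) arrays."""
    y = np.asarray(y, dtype=np.int8)
    y_mask = np.asarray(y_mask, dtype=bool)
    N = y.shape[0]
    table = CohortTable(
        ages=AgeGrid(),
        symptoms=SYMPTOMS[: y.shape[1]],
        child_id=np.array([f"c{i:04d}" for i in range(N)]),
        cohort=np.asarray(cohort) if cohort is not None else np.array(["A"] * N),
        y=y,
        y_mask=y_mask,
        **aux,
    )
    table.validate()
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_truth():
    """Well-separated two-class latent-profile truth (S=3, T=5)."""
    emit = np.stack([np.full((3, 5), 0.95), np.full((3, 5), 0.05)])
    params = ModelParams("latent_profile", np.array([0.5, 0.5]), emit=emit)
    return GenerativeTruth(
        model_spec=ModelSpec("latent_profile", 2),
        params=params,
        cohort_sizes=(2000,),
        missingness=MissingnessPlan(),
        seed=99,
    )
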