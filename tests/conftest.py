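import numpy as np
import pandas as pd
import pytest

import dietmet as dm
from dietmet import dietscores as ds


@pytest.fixture(scope="session")
def planted_single_mediator():
    """n=5000 cohort with one planted mediator (a=0.5, b=0.4, c'=0.3),
    no exclusions, no covariate liability effects: the canonical recovery
    condition.  Returns (analysis frame, truth)."""
    cfg = dm.SimConfig(
        n_raw=5000, seed=1, use_registry=False, n_mediators=1, n_null=3,
        a_diet_metab=0.5, b_metab_gms=0.4, c_direct=0.3,
        exclusion_counts=(0, 0, 0, 0, 0), cov_effects={},
    )
    participants, matrix, truth = dm.generate_cohort(cfg)
    registry = dm.build_registry(cfg)
    cohort, _ = dm.apply_exclusion_cascade(participants, matrix)
    cohort = dm.impute_covariates(cohort)
    scores = dm.score_cohort(cohort, cohort["sex"])
    prepped, _ = dm.preprocess(matrix.loc[cohort.index], registry, seed=1)
    frame = pd.concat([cohort, scores, prepped.data], axis=1)
    return frame, truth


@pytest.fixture(scope="session")
def reference_cutoffs():
    """Sex-specific cut-offs from a small synthetic intake cohort."""
    rng = np.random.default_rng(42)
    n = 200
    intakes = pd.DataFrame({
        c: np.exp(rng.normal(np.log(50), 0.5, n))
        for c in ds.REFERENCE_COMPONENTS
    })
    intakes["sex"] = np.where(rng.random(n) < 0.5, "male", "female")
    intakes["alcohol"] = np.exp(rng.normal(2.0, 1.0, n))
    return intakes, ds.compute_reference_cutoffs(intakes, intakes["sex"])
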