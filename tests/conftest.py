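import numpy as np
import pytest

from lzpk import CohortSpec, PopPKModel, REFERENCE_PARAMS, generate


@pytest.fixture(scope="session")
def ref_params():
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def study_ds():
    """One synthetic study cohort (40 subjects, 23 CRRT, q12h design)."""
    return generate(CohortSpec.study(seed=7), REFERENCE_PARAMS)


@pytest.fixture(scope="session")
def study_fit(study_ds):
    """Final-model fit of the session study cohort (no RSE for speed)."""
    res = PopPKModel(study_ds).fit(compute_rse=False)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def small_ds():
    """A 12-subject cohort for fast fitting tests."""
    spec = CohortSpec.study(seed=11, n_subjects=12, crrt_fraction=0.5)
    return generate(spec, REFERENCE_PARAMS)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
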