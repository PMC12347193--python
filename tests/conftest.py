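import numpy as np
import pytest

from omisurv.matrix import OmicsMatrix


def make_matrix(values, modality="protein", cohort=None, feature_ids=None):
    """Small OmicsMatrix from a nested list; None entries become NaN."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n, p = arr.shape
    return OmicsMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_ids=feature_ids or [f"f{j}" for j in range(p)],
        values=arr,
        modality=modality,
        cohort=None if cohort is None else np.asarray(cohort, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
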