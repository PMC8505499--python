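import numpy as np
import pytest

from ntra import (
    TrimodalParams,
    generate_cohort,
    histogram_from_voxels,
    make_paper_like_scenario,
    sample_voxels,
)

#: Reference cohort-mean trimodal parameters (baseline visit).
REFERENCE_THETA = np.array(
    [62.0, -117.8, 8.2, -2.5, 41.6, -24.1, 25.1, 78.0, 61.5, 8.6, 2.8]
)
REFERENCE_TOTAL_MASS = float(REFERENCE_THETA[[0, 4, 7]].sum())


@pytest.fixture(scope="session")
def reference_params() -> TrimodalParams:
    return TrimodalParams.from_array(REFERENCE_THETA)


@pytest.fixture(scope="session")
def sampled_histogram(reference_params):
    """100k voxels sampled from the reference parameters, binned at 1 HU.

    Shared round-trip fixture: the generating parameters are known, so
    fitting the histogram must recover them.
    """
    voxels = sample_voxels(reference_params, 100_000, seed=1)
    return histogram_from_voxels(voxels)


@pytest.fixture(scope="session")
def paper_like_cohort():
    """n=3000 cohort with muscle_N and muscle_mu as planted mediators."""
    config = make_paper_like_scenario(n_subjects=3000, seed=2)
    cohort, truth = generate_cohort(config)
    return cohort, truth
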