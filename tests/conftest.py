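import numpy as np
import pytest

from mzmarker.io import IntensityMatrix
from mzmarker.synthetic import DependentGroupSpec, NoiseModel, SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast cohort: 12+12 patients, 3 replicates, 30 channels.

    Channels outnumbered by rows, so only planted dependence is
    eliminated and unit tests can reason about exact group recovery.
    """
    return SyntheticSpec(
        n_per_class=12,
        replicates_per_patient=3,
        n_channels=30,
        channel_mz_start=250,
        marker_channels=((5, 3.0), (17, 3.0)),
        dependent_groups=(DependentGroupSpec(22, (25, 28), (0.7, 0.4)),),
        noise_model=NoiseModel(base_peak_channels=(10,)),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def tiny_matrix() -> IntensityMatrix:
    """Four replicate rows, two patients, three channels, by hand."""
    return IntensityMatrix(
        values=np.array(
            [[2.0, 4.0, 8.0], [1.0, 3.0, 6.0], [5.0, 1.0, 2.0], [4.0, 2.0, 1.0]]
        ),
        mz=np.array([250, 251, 252]),
        patient_id=np.array(["a", "a", "b", "b"], dtype=object),
        replicate=np.array([1, 2, 1, 2]),
        patient_class={"a": "case", "b": "control"},
    )
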