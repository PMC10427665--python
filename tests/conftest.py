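import numpy as np
import pandas as pd
import pytest

from neobrainage import CohortManifest, LabelVolume, default_phantom_spec, generate_cohort


def make_random_volume(shape=(20, 20, 20), n_labels=5, seed=0):
    rng = np.random.default_rng(seed)
    vox = rng.integers(0, n_labels + 1, size=shape)
    return LabelVolume(voxels=vox)


@pytest.fixture
def random_volume():
    return make_random_volume()


@pytest.fixture
def single_session_manifest():
    def _make(n):
        rows = pd.DataFrame(
            {
                "subject_id": [f"sub-{i:04d}" for i in range(n)],
                "session_id": "ses-1",
                "pma_weeks": 37.0,
            }
        )
        return CohortManifest(rows=rows)

    return _make


@pytest.fixture(scope="session")
def small_phantom_cohort(tmp_path_factory):
    """A 5-subject phantom cohort on a small grid, shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    template = default_phantom_spec(grid_shape=(40, 40, 40), seed=11)
    cohort = generate_cohort(n=5, template=template, seed=11, out_dir=out)
    return cohort, out
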