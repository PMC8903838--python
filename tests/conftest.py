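import numpy as np
import pytest

from synmorph.data_model import SizeRecord
from synmorph.synthetic import KestenParams, simulate_kesten_pair


@pytest.fixture
def small_records():
    """Two spines, three time points each, one mouse."""
    recs = []
    areas = {
        "s1": [(0, 1.00, 0.30), (30, 1.20, 0.25), (60, 0.90, 0.35)],
        "s2": [(0, 0.50, 0.10), (30, 0.55, 0.12), (60, 0.60, 0.11)],
    }
    for spine_id, samples in areas.items():
        for t, a_s, a_p in samples:
            recs.append(
                SizeRecord(
                    spine_id=spine_id,
                    mouse_id="m1",
                    condition="EE",
                    fov_id="f1",
                    time_min=t,
                    spine_head_area=a_s,
                    psd95_area=a_p,
                )
            )
    return recs


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort at the calibrated default parameters."""
    return simulate_kesten_pair(KestenParams(n_spines=1500, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
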