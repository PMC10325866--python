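import numpy as np
import pytest

from ratqeeg import synthetic_data as syn
from ratqeeg.montage import default_layout
from ratqeeg.signal_io import StudyManifest


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def stationary_recording():
    """120 s of default-condition signal with its analytic ground truth."""
    cfg = syn.default_config(
        seed=2024,
        epoch_schedule={"baseline": (0.0, 120.0)},
        duration=120.0,
        admin_time=60.0,
    )
    return syn.generate_recording(cfg)


@pytest.fixture(scope="session")
def compressed_manifest():
    e = 60.0
    return StudyManifest(
        baseline_window=(0.0, e),
        post_windows={"E1": (0.0, e), "E2": (e, 2 * e), "E3": (2 * e, 3 * e)},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
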