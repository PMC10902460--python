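import numpy as np
import pytest

from gazescreen import ScreenGeometry, build_pst


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    return ScreenGeometry(width_px=800, height_px=600, px_per_mm=4.0,
                          viewing_distance_mm=500.0)


@pytest.fixture(scope="session")
def pst_timeline():
    return build_pst(seed=7)


def make_recording(t, x, y, valid=None, geometry=None, task_id="PST",
                   subject_id="s0", rate=30.0):
    """Convenience constructor for hand-built recordings."""
    from gazescreen import GazeRecording

    t = np.asarray(t, dtype=float)
    if valid is None:
        valid = np.ones(t.size, dtype=bool)
    return GazeRecording(subject_id=subject_id, task_id=task_id, t=t,
                         x=np.asarray(x, dtype=float), y=np.asarray(y, dtype=float),
                         valid=np.asarray(valid, dtype=bool),
                         geometry=geometry or ScreenGeometry(),
                         nominal_rate_hz=rate)
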