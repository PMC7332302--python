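import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from etaxis.io_tracks import Calibration, Trajectory
from etaxis.metrics import FieldVector


@pytest.fixture
def unit_cal() -> Calibration:
    """Calibration with an effective pixel size of exactly 1 μm."""
    return Calibration(pixel_pitch=1.0, binning=1, objective_mag=1.0,
                       intermediate_mag=1.0, frame_interval=10.0)


@pytest.fixture
def paper_cal() -> Calibration:
    """The study's optics: 6.5 μm pitch, 2×2 binning, 10× + 1.5×."""
    return Calibration()


@pytest.fixture
def field_x() -> FieldVector:
    """Anode→cathode field along +x."""
    return FieldVector(direction=(1.0, 0.0), strength=300.0)


def straight_trajectory(cell_id: str, direction, speed_um_h: float = 2.0,
                        n_frames: int = 37, dt_h: float = 1 / 6,
                        start=(0.0, 0.0)) -> Trajectory:
    """A constant-velocity trajectory along ``direction``."""
    d = np.asarray(direction, float)
    d = d / np.hypot(*d)
    times = np.arange(n_frames) * dt_h
    pos = np.asarray(start, float) + times[:, None] * d * speed_um_h
    return Trajectory(cell_id, times, pos)


@pytest.fixture
def straight_cohort():
    return straight_trajectory
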