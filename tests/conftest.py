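import numpy as np
import pytest

from cellheading.simulate import SimConfig
from cellheading.tracking import Trajectory


def make_traj(xy_um, frame_interval_min=15.0, cell_id=0, pixel_size_um=1.0):
    """Trajectory from a list of (x, y) positions in micrometers."""
    xy = np.asarray(xy_um, dtype=float)
    return Trajectory(
        cell_id=cell_id,
        frames=np.arange(len(xy)),
        x_um=xy[:, 0],
        y_um=xy[:, 1],
        frame_interval_min=frame_interval_min,
        pixel_size_um=pixel_size_um,
    )


def random_trajectory(rng, n_steps=40, step_scale=6.0, interval=15.0):
    """Unstructured random walk for oracle comparisons."""
    steps = rng.normal(0.0, step_scale, size=(n_steps, 2))
    xy = np.cumsum(np.vstack([[50.0, 50.0], steps]), axis=0)
    return make_traj(xy, frame_interval_min=interval)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_config():
    """A few cells in a small field; cheap to render."""
    return SimConfig(n_cells=4, n_frames=8, image_size_px=(256, 256),
                     min_separation_um=40.0, seed=7)
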