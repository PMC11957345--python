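import numpy as np
import pytest

from thgswell.io import AcquisitionGeometry
from thgswell.pipeline import PipelineConfig, train_classifier_on_truth
from thgswell.synthetic import MS_PRESET, simulate_timelapse


@pytest.fixture(scope="session")
def small_geometry():
    """40×40 µm FOV at 0.4 µm/px, 0.4 µm z-step: fast but resolvable."""
    return AcquisitionGeometry(fov_um=40.0, grid_px=100, z_step_um=0.4)


@pytest.fixture(scope="session")
def small_scene(small_geometry):
    """One noisy MS-preset z-stack (25 planes) plus ground truth."""
    stack, truth = simulate_timelapse(
        MS_PRESET, small_geometry, 25, [0.0], seed=1234
    )
    return stack, truth


@pytest.fixture(scope="session")
def small_model(small_scene):
    """Classifier trained on the small scene's synthetic annotations."""
    stack, truth = small_scene
    return train_classifier_on_truth(stack, truth, seed=7, n_per_class=200)


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(seed=0, fov_um=40.0, grid_px=100, z_step_um=0.4, n_z=25)


def hysteresis_oracle(values, core=0.85, final=0.5):
    """Brute-force flood fill: 26-connected components of {p >= final} that
    contain a voxel with p >= core.  Independent of scipy labeling."""
    values = np.asarray(values)
    low = values >= final
    visited = np.zeros(values.shape, dtype=bool)
    keep = np.zeros(values.shape, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    nz, ny, nx = values.shape
    for start in zip(*np.nonzero(low & ~visited)):
        if visited[start]:
            continue
        component = [start]
        visited[start] = True
        frontier = [start]
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if 0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx \
                        and low[q] and not visited[q]:
                    visited[q] = True
                    component.append(q)
                    frontier.append(q)
        if any(values[v] >= core for v in component):
            for v in component:
                keep[v] = True
    return keep
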