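import numpy as np
import pytest

from rtnf import AcquisitionGrid, SimulationTruth, default_roi_voxels, simulate_run


@pytest.fixture(scope="session")
def small_grid():
    return AcquisitionGrid(shape=(12, 12, 8))


@pytest.fixture(scope="session")
def noise_free_run(small_grid):
    """Noise-free neurofeedback run with a planted 1% upregulation."""
    truth = SimulationTruth(
        roi_voxels=default_roi_voxels(small_grid),
        base_amplitude=1.0,
        learning_slope=0.0,
        ar_coefficient=0.0,
        noise_sd=0.0,
    )
    run, motion = simulate_run(truth, grid=small_grid, seed=11)
    return truth, run, motion


@pytest.fixture(scope="session")
def noisy_run(small_grid):
    """Realistic-noise run with a 1.2 mm motion spike at volume 40."""
    truth = SimulationTruth(
        roi_voxels=default_roi_voxels(small_grid),
        base_amplitude=1.0,
        learning_slope=0.0,
        ar_coefficient=0.3,
        noise_sd=1.0,
        spike_times=(40,),
        spike_magnitude=1.2,
    )
    run, motion = simulate_run(truth, grid=small_grid, seed=17)
    return truth, run, motion
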