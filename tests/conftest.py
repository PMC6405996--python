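import numpy as np
import pytest

import chemoscope as cs


@pytest.fixture(scope="session")
def calibration_line():
    """Noiseless pHluorin calibration: ratio = 0.3 * pH - 1.3."""
    return cs.CalibrationCurve(slope=0.3, intercept=-1.3)


@pytest.fixture(scope="session")
def foci_scene_single():
    """200+ cells with exactly one bright planted focus each (fixed seed)."""
    spec = cs.FociSceneSpec(
        n_cells=220,
        image_shape=(560, 560),
        foci_per_cell_dist=(0, 1, 0, 0, 0, 0),
        focus_amplitude_mean=13.0,
        focus_amplitude_sd=1.0,
        background_noise_sd=1.0,
        seed=11,
    )
    return cs.gen_foci_scene(spec)


@pytest.fixture(scope="session")
def buffer_fits():
    """400 decay fits of buffer-condition traces at default conditions."""
    traces, truth = cs.gen_foci_traces(cs.TraceSimSpec(n_traces=400, seed=7))
    return cs.fit_traces(traces), truth
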