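import numpy as np
import pytest

import flyca as fc


@pytest.fixture(scope="session")
def flash_protocol():
    return fc.build_flash_protocol(7, 5.0)


@pytest.fixture(scope="session")
def edge_protocol():
    return fc.build_edge_protocol(20.0, 3, 2.0, seed=3)


@pytest.fixture(scope="session")
def on_cell():
    return fc.CellSpec(id=1, center_px=(20, 20), radius_px=3,
                       amp_transient=1.0, amp_plateau=0.4, tau_rise_s=0.05)


@pytest.fixture()
def noiseless_config():
    return fc.MovieConfig(height_px=48, width_px=48, frame_rate_hz=15.0,
                          photon_gain=100.0, read_noise_sd=0.0,
                          motion_walk_sd=0.0, shot_noise=False, seed=0)


def make_trace_set(values, times, protocol=None, roi_ids=None):
    """Hand-built TraceSet for small arithmetic examples."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if roi_ids is None:
        roi_ids = list(range(1, values.shape[0] + 1))
    return fc.TraceSet(times=np.asarray(times, dtype=float), values=values,
                       roi_ids=roi_ids, background=np.zeros(values.shape[1]),
                       protocol=protocol)
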