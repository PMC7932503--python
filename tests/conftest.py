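import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bari.phantom import CycleParams, PhantomSpec, simulate_cine, _default_roi

settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: Compact single-cycle vessel used by segmentation unit tests: ~1.5 mm
#: baseline diameter at 21 um spacing keeps frames at 120x32 px.
SMALL_CYCLE = CycleParams(a_d=1.9, b_d=0.4, tau_d=0.2, a_r=1.5,
                          b_r1=0.25, b_r2=0.15, tau_r1=0.08, tau_r2=1.0)


def small_spec(**overrides) -> PhantomSpec:
    base = dict(peak_times=(0.5,), trough_times=(0.2, 1.1),
                frame_rate=25.0, duration=1.2, n_rows=120, n_cols=32,
                cycle=SMALL_CYCLE)
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_loop():
    spec = small_spec()
    loop, truth = simulate_cine(spec, seed=7)
    return spec, loop, truth


@pytest.fixture(scope="session")
def small_roi(small_loop):
    spec, _, truth = small_loop
    return _default_roi(spec, truth)


@pytest.fixture(scope="session")
def segmented_small_loop(small_loop, small_roi):
    from bari.segmentation import (LevelSetConfig, extract_wall_traces,
                                   segment_lumen)

    _, loop, truth = small_loop
    config = LevelSetConfig()
    contours = segment_lumen(loop, small_roi, config)
    traces = extract_wall_traces(contours, small_roi, loop, config)
    return contours, traces


def wall_errors_px(traces, truth):
    cols = traces.x_px.astype(int)
    et = np.abs(traces.y_t - truth.y_t[cols, :])[traces.qc_mask]
    eb = np.abs(traces.y_b - truth.y_b[cols, :])[traces.qc_mask]
    return np.concatenate([et, eb])
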