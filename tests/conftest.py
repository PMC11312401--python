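import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest

import ciliabeat as cb


@pytest.fixture(scope="session")
def sinusoid_stack():
    """Noise-free render of a 5 Hz, ±0.5 µm sinusoidal crossing, 2 s at 250 fps."""
    t = np.arange(500) * cb.FRAME_MS
    pos = 0.5 * np.sin(2 * np.pi * 5.0 * t / 1000.0)
    params = cb.BeatParameters(t_eff=100, t_rec=100, interval_mean=0, amplitude=0.5)
    traj = cb.BeatTrajectory(times=t, positions=pos, event_log=[], params=params)
    geo = cb.CiliumGeometry()
    from dataclasses import replace

    cfg = replace(cb.ImagingConfig(), noise_sd=0.0)
    stack = cb.render_stack(traj, geo, cfg, None)
    line, offset = cb.scanline_for(geo, amplitude=0.5)
    return stack, line, offset, traj


@pytest.fixture(scope="session")
def clean_ph70_result():
    """Noise-free pH 7.0 component-matched recording with zero interval
    variance, quantified end to end (shared by boundary-accuracy tests)."""
    from dataclasses import replace

    from ciliabeat.cohort_analysis import simulate_measure_cilium

    params = replace(
        cb.get_preset("pH7.0").params.with_mode("component_matched"),
        interval_sigma_log=0.0,
    )
    return simulate_measure_cilium(params, 42, 0, 0, duration_s=5.0, noise=False)
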