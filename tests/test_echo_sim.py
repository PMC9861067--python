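"""Physics and reproducibility of the echo simulator."""

import numpy as np
import pytest

from ssavmd import ChestMotion, RadarConfig, Scene, synthesize_echo
from ssavmd.echo_sim import (
    chest_distance,
    chest_row_index,
    pulse_waveform,
    sample_motion,
    snr_to_noise_sigma,
    study_scene,
)
from ssavmd.preprocess import select_max_gate


def test_chest_distance_bounds_and_mean(motion):
    t = np.linspace(0.0, 50.0, 5000)
    d = chest_distance(t, motion)
    span = motion.Ar + motion.Ah
    assert np.all(d <= motion.d0 + span + 1e-12)
    assert np.all(d >= motion.d0 - span - 1e-12)
    assert abs(d.mean() - motion.d0) < 1e-3


def test_pulse_is_odd_and_localised(radar):
    tau = np.linspace(-5 * radar.pulse_sigma, 5 * radar.pulse_sigma, 1001)
    s = pulse_waveform(tau, radar)
    assert np.allclose(pulse_waveform(-tau, radar), -s, atol=1e-12)
    # energy is concentrated within a few sigma
    far = pulse_waveform(20 * radar.pulse_sigma, radar)
    assert abs(far) < 1e-12


def test_synthesis_is_seed_deterministic(radar, motion):
    scene = study_scene(radar, motion)
    a = synthesize_echo(radar, scene, motion, seed=7)
    b = synthesize_echo(radar, scene, motion, seed=7)
    c = synthesize_echo(radar, scene, motion, seed=8)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_static_reflectors_are_constant_along_slow_time(radar, motion):
    scene = Scene(av=0.0, statics=[(0.3, 3.0), (0.9, 2.0)], dc_offset=0.5)
    echo = synthesize_echo(radar, scene, motion, seed=None)
    assert np.allclose(echo.values, echo.values[:, [0]])


def test_max_energy_gate_sits_near_the_chest(radar, motion, noiseless_chest):
    gate = select_max_gate(noiseless_chest).gate_index
    row = chest_row_index(radar, motion)
    # the monocycle's energy peak is offset from its onset by a few
    # pulse-widths of fast-time samples
    pulse_bins = radar.pulse_sigma / radar.delta_T
    assert abs(gate - row) <= 3 * pulse_bins


def test_scene_beyond_range_window_is_rejected(radar, motion):
    scene = Scene(av=1.0, statics=[(radar.max_range + 0.5, 1.0)])
    with pytest.raises(ValueError, match="range"):
        synthesize_echo(radar, scene, motion, seed=0)


def test_snr_to_noise_sigma_decibel_scaling(radar, motion):
    s0 = snr_to_noise_sigma(radar, motion, 0.0)
    s20 = snr_to_noise_sigma(radar, motion, 20.0)
    assert s0 > 0
    assert np.isclose(s0 / s20, 10.0)


def test_sample_motion_ranges_and_harmonic_margin():
    rng = np.random.default_rng(42)
    for _ in range(50):
        m = sample_motion(rng)
        assert 0.2 <= m.fr <= 0.35
        assert 1.0 <= m.fh <= 1.7
        for k in range(2, 6):
            assert abs(m.fh - k * m.fr) > 0.1


def test_motion_validation():
    with pytest.raises(ValueError):
        ChestMotion(d0=-1.0)
    with pytest.raises(ValueError):
        ChestMotion(d0=0.001, Ar=0.004)


def test_radar_validation():
    with pytest.raises(ValueError, match="Nyquist"):
        RadarConfig(delta_T=1e-9)  # 1 GHz sampling vs 7.29 GHz carrier
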