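"""Variational mode decomposition: parameters, tone recovery, duals."""

import numpy as np
import pytest

from ssavmd import SlowTimeSignal, VMDConfig, vmd_decompose


def _tone(freq, n=1000, Ts=1.0):
    t = np.arange(n)
    return SlowTimeSignal(values=np.sin(2 * np.pi * freq * t), Ts=Ts)


def test_config_validation():
    with pytest.raises(ValueError):
        VMDConfig(k=0)
    with pytest.raises(ValueError):
        VMDConfig(alpha=0)
    with pytest.raises(ValueError):
        VMDConfig(tau=-1)
    with pytest.raises(ValueError):
        VMDConfig(eps=0)
    with pytest.raises(ValueError):
        VMDConfig(init=3)


def test_single_tone_centre_and_waveform():
    sig = _tone(0.1)
    res = vmd_decompose(sig, VMDConfig(k=2, dc=True))
    assert abs(res.omegas[1] - 0.1) < 0.005
    # central half of the tone mode tracks the input (edges are relaxed)
    n = sig.n
    c = n // 4
    corr = np.corrcoef(res.modes[1][c:-c], sig.values[c:-c])[0, 1]
    assert corr > 0.99


def test_dc_mode_pinned_at_zero():
    res = vmd_decompose(_tone(0.1), VMDConfig(k=3, dc=True))
    assert res.omegas[0] == 0.0


def test_centre_frequencies_sorted_ascending():
    t = np.arange(1000)
    x = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.2 * t)
    res = vmd_decompose(SlowTimeSignal(values=x, Ts=1.0), VMDConfig(k=3))
    assert np.all(np.diff(res.omegas) >= 0)


def test_zero_signal_converges_to_zero_modes():
    res = vmd_decompose(SlowTimeSignal(values=np.zeros(64), Ts=1.0), VMDConfig(k=3))
    assert res.converged
    assert np.abs(res.modes).max() < 1e-12


def test_dual_ascent_tightens_reconstruction():
    t = np.arange(1000)
    x = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.2 * t)
    sig = SlowTimeSignal(values=x, Ts=1.0)
    res = vmd_decompose(sig, VMDConfig(k=3, tau=1.0, max_iter=2000))
    rel = np.linalg.norm(res.residual) / np.linalg.norm(x)
    assert rel < 0.01


def test_omegas_hz_scaling():
    res_a = vmd_decompose(_tone(0.1, Ts=1.0), VMDConfig(k=2))
    res_b = vmd_decompose(_tone(0.1, Ts=0.05), VMDConfig(k=2))
    assert np.allclose(res_b.omegas_hz, res_a.omegas_hz / 0.05)


def test_input_validation():
    with pytest.raises(ValueError, match="short"):
        vmd_decompose(SlowTimeSignal(values=np.zeros(4), Ts=1.0))
    with pytest.raises(ValueError):
        SlowTimeSignal(values=np.array([1.0, np.nan, 0.0]), Ts=1.0)
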