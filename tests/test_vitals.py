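"""Spectral readout, mode classification and error reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssavmd import (
    BandEmptyError,
    SlowTimeSignal,
    VMDConfig,
    classify_modes,
    error_report,
    extract_vitals,
    load_reference_table,
    magnitude_spectrum,
    peak_frequency,
    vmd_decompose,
)


def _multi_tone(amps_freqs, n=1000, fs=20.0):
    t = np.arange(n) / fs
    x = sum(a * np.sin(2 * np.pi * f * t) for a, f in amps_freqs)
    return SlowTimeSignal(values=x, Ts=1.0 / fs)


def test_spectrum_grid_density():
    sig = _multi_tone([(1.0, 1.5)])
    spec = magnitude_spectrum(sig, pad_factor=16)
    df = spec.freqs[1] - spec.freqs[0]
    assert np.isclose(df, 1.0 / (sig.n * 16 * sig.Ts))
    with pytest.raises(ValueError):
        magnitude_spectrum(sig, pad_factor=0)


def test_peak_frequency_tone_accuracy():
    for f0, band in [(1.5, (0.8, 2.5)), (0.267, (0.1, 0.7))]:
        est = peak_frequency(_multi_tone([(1.0, f0)]), band)
        assert abs(est - f0) < 1e-3


def test_peak_frequency_band_validation():
    sig = _multi_tone([(1.0, 1.5)])
    with pytest.raises(ValueError):
        peak_frequency(sig, (0.7, 0.1))
    with pytest.raises(ValueError, match="Nyquist"):
        peak_frequency(sig, (1.0, 50.0))


def test_peak_frequency_exclusion_windows():
    sig = _multi_tone([(2.0, 1.0), (1.0, 1.4)])
    assert abs(peak_frequency(sig, (0.8, 2.5)) - 1.0) < 1e-3
    est = peak_frequency(sig, (0.8, 2.5), exclude=((0.9, 1.1),))
    assert abs(est - 1.4) < 1e-3
    # exclusions covering the whole band are dropped, not fatal
    est = peak_frequency(sig, (0.8, 2.5), exclude=((0.0, 10.0),))
    assert abs(est - 1.0) < 1e-3


def test_classification_rejects_respiratory_harmonic():
    # strong 0.25 Hz breath, moderate 4th harmonic at 1.0 Hz, weak pulse
    sig = _multi_tone([(10.0, 0.25), (1.0, 1.0), (0.5, 1.4)])
    res = extract_vitals(sig, use_ssa=False)
    assert abs(res.fr_hat - 0.25) < 0.01
    assert abs(res.fh_hat - 1.4) < 0.02


def test_classification_without_heart_content_raises():
    sig = _multi_tone([(1.0, 0.1), (1.0, 0.3)])
    res = vmd_decompose(sig, VMDConfig(k=3))
    with pytest.raises(BandEmptyError) as exc:
        classify_modes(res)
    assert exc.value.band_name == "heartbeat"
    assert exc.value.band == (0.8, 2.5)


def test_error_report_values_and_rounding():
    rep = error_report([1.4, 1.25], [1.45, 1.20])
    assert rep.mae == 0.05
    assert list(rep.records["subject"]) == ["A", "B"]
    assert np.allclose(rep.records["error_hz"], [0.05, -0.05])


def test_error_report_validation():
    with pytest.raises(ValueError):
        error_report([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        error_report([], [])


@given(
    st.lists(
        st.floats(min_value=0.5, max_value=3.0, allow_nan=False),
        min_size=1,
        max_size=8,
    ),
    st.floats(min_value=-0.5, max_value=0.5, allow_nan=False),
)
def test_error_report_mae_properties(standards, offset):
    estimates = [s + offset for s in standards]
    rep = error_report(standards, estimates)
    assert rep.mae >= 0.0
    assert rep.mae == pytest.approx(round(abs(offset), 3), abs=5e-4)


def test_reference_tables_load():
    for key in ("0.6m", "1.2m"):
        table = load_reference_table(key)
        assert list(table.columns) == [
            "object",
            "standard_hr_hz",
            "vmd_hz",
            "ssa_vmd_hz",
        ]
        assert len(table) == 5
        assert pd.api.types.is_float_dtype(table["standard_hr_hz"])
    with pytest.raises((FileNotFoundError, OSError)):
        load_reference_table("3.0m")
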