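"""Singular spectrum analysis: embedding, grouping, reconstruction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssavmd import SlowTimeSignal, ssa_denoise
from ssavmd.ssa import (
    decompose,
    default_window,
    embed,
    group_count,
    reconstruct,
)


def test_default_window_rule():
    assert default_window(1000) == 400
    assert default_window(100) == 40
    # capped under N/2 for short records
    assert default_window(20) == 8  # 0.4*20, below the cap 20//2 - 1 = 9
    assert default_window(12) == 5  # rule value 0.4*12 = 4.8 -> 5 = cap 12//2 - 1
    assert default_window(1000) < 1000 // 2


def test_group_count_rounds_half_up():
    assert group_count(10) == 1
    assert group_count(35) == 4  # 3.5 rounds up
    assert group_count(123) == 12
    with pytest.raises(ValueError):
        group_count(9)


def test_embed_shape_and_hankel_structure():
    x = np.arange(10.0)
    traj = embed(x, 4)
    assert traj.shape == (4, 7)
    # constant anti-diagonals
    assert np.allclose(traj[1:, :-1], traj[:-1, 1:])
    assert traj[0, 0] == 0.0 and traj[-1, -1] == 9.0


def test_embed_window_bounds():
    x = np.arange(10.0)
    with pytest.raises(ValueError):
        embed(x, 1)
    with pytest.raises(ValueError):
        embed(x, 6)  # exceeds N/2


def test_decompose_rejects_non_hankel():
    with pytest.raises(ValueError, match="Hankel"):
        decompose(np.eye(4))


def test_reconstruct_r_bounds():
    dec = decompose(embed(np.sin(np.arange(40.0)), 10))
    with pytest.raises(ValueError):
        reconstruct(dec, 0)
    with pytest.raises(ValueError):
        reconstruct(dec, dec.d + 1)


def test_component_additivity():
    rng = np.random.default_rng(11)
    dec = decompose(embed(rng.normal(size=60), 20))
    both = reconstruct(dec, r=2).values
    first = reconstruct(dec, r=1, components=np.array([0])).values
    second = reconstruct(dec, r=1, components=np.array([1])).values
    assert np.allclose(both, first + second, atol=1e-10)


@given(st.integers(min_value=0, max_value=500))
def test_full_rank_reconstruction_is_identity(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=64)
    dec = decompose(embed(x, 20))
    back = reconstruct(dec, r=dec.d).values
    assert np.linalg.norm(back - x) <= 1e-8 * np.linalg.norm(x)


def test_denoising_recovers_a_buried_sinusoid():
    rng = np.random.default_rng(2)
    t = np.arange(1000) * 0.05
    clean = np.sin(2 * np.pi * 0.25 * t)
    noisy = clean + rng.normal(0.0, 1.0, size=t.size)
    den = ssa_denoise(SlowTimeSignal(values=noisy, Ts=0.05)).values
    err_before = np.linalg.norm(noisy - clean)
    err_after = np.linalg.norm(den - clean)
    assert err_after < 0.5 * err_before
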