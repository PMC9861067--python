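"""Singular spectrum analysis denoising of the slow-time vital-sign series.

SSA lag-embeds a 1-D series into an L x K Hankel trajectory matrix
(K = N - L + 1), takes its SVD, keeps the leading r rank-1 components, and
maps the rank-r matrix back to a series by averaging each anti-diagonal
(Hankelization). The retained count r follows the critical-value rule
r = round(0.1 * L): with the default window L = 400 on a 1000-sample
record, the first 40 singular values are kept and the noise tail, which
otherwise smears spectral energy around the weak heartbeat line, is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import hankel

from .containers import SlowTimeSignal

__all__ = [
    "SSAConfig",
    "SSADecomposition",
    "default_window",
    "group_count",
    "embed",
    "decompose",
    "reconstruct",
    "ssa_denoise",
]

_RANK_TOL = 1e-12


@dataclass
class SSAConfig:
    """Window length L and retained-component count r.

    None means rule-derived: L = 0.4*N capped under N/2 (400 on a 1000
    sample record), r = round(0.1*L).
    """

    L: int | None = None
    r: int | None = None


@dataclass
class SSADecomposition:
    """Singular system of a trajectory matrix.

    d counts the numerically non-zero singular values; the full factors are
    kept so any leading group can be reconstructed.
    """

    singulars: np.ndarray
    left_vectors: np.ndarray
    right_vectors_h: np.ndarray
    n: int  # original series length
    Ts: float

    @property
    def L(self) -> int:
        return self.left_vectors.shape[0]

    @property
    def K(self) -> int:
        return self.right_vectors_h.shape[1]

    @property
    def d(self) -> int:
        if self.singulars.size == 0 or self.singulars[0] <= 0:
            return 0
        return int(np.sum(self.singulars > _RANK_TOL * self.singulars[0]))


def default_window(n: int) -> int:
    """Default SSA window: 0.4*N, capped just under N/2.

    Keeps the 400/1000 window-to-record ratio for records of other lengths
    while respecting the L < N/2 symmetry constraint.
    """
    return min(int(round(0.4 * n)), n // 2 - 1)


def group_count(L: int) -> int:
    """Retained-component count from the critical-value position 0.1*L.

    Round-half-up so L = 400 gives r = 40 and any L >= 10 gives r >= 1.
    """
    if L < 10:
        raise ValueError("window length must be at least 10 for the 0.1*L rule")
    return int(np.floor(0.1 * L + 0.5))


def embed(signal: SlowTimeSignal | np.ndarray, L: int) -> np.ndarray:
    """Hankel trajectory matrix: column j is the lagged window x[j : j+L]."""
    x = signal.values if isinstance(signal, SlowTimeSignal) else np.asarray(signal, float)
    n = x.size
    if not 2 <= L <= n // 2:
        raise ValueError(f"window length must satisfy 2 <= L <= N/2 (got L={L}, N={n})")
    return hankel(x[:L], x[L - 1 :])


def decompose(trajectory: np.ndarray, Ts: float = 1.0) -> SSADecomposition:
    """SVD of a trajectory matrix.

    The input must be a Hankel matrix (constant anti-diagonals); this is
    checked so that reconstruction always maps back to a well-defined
    series.
    """
    traj = np.asarray(trajectory, dtype=float)
    if not np.all(np.isfinite(traj)):
        raise ValueError("trajectory matrix contains non-finite entries")
    L, K = traj.shape
    if L > 1 and K > 1 and not np.allclose(traj[1:, :-1], traj[:-1, 1:]):
        raise ValueError("input is not a Hankel (trajectory) matrix")
    U, s, Vh = np.linalg.svd(traj, full_matrices=False)
    return SSADecomposition(
        singulars=s, left_vectors=U, right_vectors_h=Vh, n=L + K - 1, Ts=Ts
    )


def _diagonal_average(matrix: np.ndarray) -> np.ndarray:
    """Map an L x K matrix to a length L+K-1 series by anti-diagonal means."""
    L, K = matrix.shape
    idx = np.add.outer(np.arange(L), np.arange(K)).ravel()
    sums = np.bincount(idx, weights=matrix.ravel(), minlength=L + K - 1)
    counts = np.bincount(idx, minlength=L + K - 1)
    return sums / counts


def reconstruct(
    decomposition: SSADecomposition,
    r: int,
    components: np.ndarray | None = None,
) -> SlowTimeSignal:
    """Series reconstructed from the leading r rank-1 components.

    `components` may instead name an arbitrary 0-based component subset
    (used by the additivity property); when given, r is ignored.
    """
    if components is None:
        if not 1 <= r <= max(decomposition.d, 1):
            raise ValueError(f"r must lie in 1..{decomposition.d}")
        components = np.arange(r)
    components = np.asarray(components, dtype=int)
    U = decomposition.left_vectors[:, components]
    s = decomposition.singulars[components]
    Vh = decomposition.right_vectors_h[components, :]
    series = _diagonal_average((U * s) @ Vh)
    return SlowTimeSignal(values=series, Ts=decomposition.Ts)


def ssa_denoise(
    signal: SlowTimeSignal,
    L: int | None = None,
    r: int | None = None,
) -> SlowTimeSignal:
    """Full SSA pass: embed, decompose, keep the leading group, reconstruct."""
    if L is None:
        L = default_window(signal.n)
    dec = decompose(embed(signal, L), Ts=signal.Ts)
    if r is None:
        r = min(group_count(L), dec.d)
    return reconstruct(dec, r)
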