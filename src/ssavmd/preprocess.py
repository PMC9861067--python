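"""Echo-matrix preprocessing: SVD clutter suppression and gate selection.

Static reflectors and receiver DC offset are constant along slow time, so
they concentrate in the leading singular component of the echo matrix.
Zeroing every singular value except a chosen keep-set (by default the
second, which carries the chest-motion modulation) removes clutter and
most wide-band noise in one step. The vital-sign time series is then the
single most energetic range gate of the cleaned matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .containers import EchoMatrix, SlowTimeSignal

__all__ = [
    "SVDFactors",
    "GateSelection",
    "svd_factorize",
    "svd_reconstruct",
    "clutter_suppress",
    "select_max_gate",
]


@dataclass
class SVDFactors:
    """Full singular system of an echo matrix.

    left_vectors is M x M orthonormal, right_vectors_h is N x N orthonormal
    (stored as V^H), singulars the non-increasing singular values. Sampling
    metadata is carried along so reconstructions stay valid EchoMatrix
    instances.
    """

    left_vectors: np.ndarray
    singulars: np.ndarray
    right_vectors_h: np.ndarray
    delta_T: float
    Ts: float

    @property
    def A(self) -> int:
        """Number of singular values, min(M, N)."""
        return self.singulars.size


@dataclass
class GateSelection:
    """Result of maximum-distance-gate selection."""

    energies: np.ndarray
    gate_index: int
    signal: SlowTimeSignal


def svd_factorize(echo: EchoMatrix) -> SVDFactors:
    """Full SVD of the echo matrix with a fixed sign convention.

    Each left singular vector is flipped so its largest-magnitude entry is
    positive, which makes reconstructions reproducible across linear
    algebra backends.
    """
    if not np.all(np.isfinite(echo.values)):
        raise ValueError("echo matrix contains non-finite entries")
    U, s, Vh = np.linalg.svd(echo.values, full_matrices=True)
    for i in range(s.size):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vh[i, :] = -Vh[i, :]
    return SVDFactors(
        left_vectors=U,
        singulars=s,
        right_vectors_h=Vh,
        delta_T=echo.delta_T,
        Ts=echo.Ts,
    )


def svd_reconstruct(factors: SVDFactors, keep: Iterable[int] = (2,)) -> EchoMatrix:
    """Rank-limited reconstruction keeping 1-based singular indices.

    The default keep-set {2} retains the dominant motion component while
    discarding static clutter (component 1) and the noise tail; {2, 3, 4}
    keeps additional weaker vital-sign components.
    """
    keep = sorted(set(int(k) for k in keep))
    if not keep:
        raise ValueError("keep set must not be empty")
    if keep[0] < 1 or keep[-1] > factors.A:
        raise ValueError(f"keep indices must lie in 1..{factors.A}")
    idx = np.array(keep) - 1
    U = factors.left_vectors[:, idx]
    s = factors.singulars[idx]
    Vh = factors.right_vectors_h[idx, :]
    values = (U * s) @ Vh
    return EchoMatrix(values=values, delta_T=factors.delta_T, Ts=factors.Ts)


def clutter_suppress(echo: EchoMatrix, keep: Iterable[int] = (2,)) -> EchoMatrix:
    """Convenience wrapper: factorize then reconstruct with the keep-set."""
    return svd_reconstruct(svd_factorize(echo), keep=keep)


def select_max_gate(echo: EchoMatrix) -> GateSelection:
    """Pick the range gate (row) with maximum slow-time energy.

    energies[m] = sum_i R[m, i]^2; ties break to the smallest row index.
    An all-zero matrix has no defined gate and is rejected.
    """
    energies = np.sum(echo.values**2, axis=1)
    if not np.any(energies > 0):
        raise ValueError("all-zero echo matrix: no range gate defined")
    gate = int(np.argmax(energies))
    signal = SlowTimeSignal(values=echo.values[gate].copy(), Ts=echo.Ts)
    return GateSelection(energies=energies, gate_index=gate, signal=signal)
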