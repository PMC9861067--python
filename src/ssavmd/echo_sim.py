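"""Physics-based UWB impulse-radar echo simulator.

The chest of a resting subject moves as the sum of two sinusoids — a
respiration component (a few millimetres, ~0.2-0.35 Hz) and a much weaker
heartbeat component (a few tenths of a millimetre, ~1-1.7 Hz):

    d(t) = d0 + Ar*sin(2*pi*fr*t) + Ah*sin(2*pi*fh*t)

A transmitted first-order Gaussian pulse reflects off the chest with
round-trip delay 2*d(t)/c and off static reflectors with constant delays,
so the sampled echo matrix is

    R[m, n] = av*s(m*dT - 2*d(n*Ts)/c) + sum_i ai*s(m*dT - 2*range_i/c)
              + dc + noise[m, n]

with rows m indexing fast time (range) and columns n indexing slow time
(frames). Because the carrier phase 4*pi*fc*d(t)/c is modulated by the two
sinusoids, the slow-time spectrum at the chest range gate carries lines at
the respiration fundamental, its harmonics k*fr, and the heartbeat
frequency fh — the structure every downstream stage relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import C_LIGHT, EchoMatrix

__all__ = [
    "ChestMotion",
    "Scene",
    "RadarConfig",
    "chest_distance",
    "pulse_waveform",
    "synthesize_echo",
    "chest_row_index",
    "snr_to_noise_sigma",
    "sample_motion",
    "study_scene",
]

# Pulse width giving roughly a 1.4 GHz -10 dB two-sided bandwidth for the
# Gaussian envelope: |S(f)|^2 = exp(-4 pi^2 sigma^2 f^2) = 0.1 at f = B/2.
DEFAULT_PULSE_SIGMA = math.sqrt(math.log(10.0)) / (math.pi * 1.4e9)


@dataclass
class ChestMotion:
    """Ground-truth dual-sinusoid chest kinematics.

    d0 : mean chest range (m); Ar, fr : respiration displacement amplitude
    (m) and frequency (Hz); Ah, fh : heartbeat displacement amplitude (m)
    and frequency (Hz). Defaults are a physiologically typical seated adult
    at 0.6 m.
    """

    d0: float = 0.6
    Ar: float = 0.004
    fr: float = 0.267
    Ah: float = 0.0003
    fh: float = 1.5

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if min(self.Ar, self.Ah, self.fr, self.fh) < 0:
            raise ValueError("amplitudes and frequencies must be non-negative")
        if self.Ar + self.Ah >= self.d0:
            raise ValueError("displacement amplitudes must be small against d0")


@dataclass
class Scene:
    """Reflectivity environment: chest coefficient, static reflectors,
    receiver DC offset and additive white Gaussian noise level."""

    av: float = 1.0
    statics: Sequence[tuple[float, float]] = field(default_factory=tuple)
    dc_offset: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.statics = tuple((float(r), float(a)) for r, a in self.statics)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class RadarConfig:
    """Sampling geometry of the simulated impulse radar.

    Fast time is sampled at 1/delta_T (defaults to 23.328 GHz, comfortably
    above twice the 7.29 GHz pulse centre frequency), M rows covering a
    1.5 m window. Slow time is one frame every Ts seconds (default 20 Hz
    frame rate, N = 1000 frames for a 50 s record).
    """

    delta_T: float = 1.0 / 23.328e9
    Ts: float = 0.05
    M: int = 234
    N: int = 1000
    fc: float = 7.29e9
    pulse_sigma: float = DEFAULT_PULSE_SIGMA
    c: float = C_LIGHT

    def __post_init__(self) -> None:
        if self.M < 2 or self.N < 2:
            raise ValueError("M and N must each be at least 2")
        if min(self.delta_T, self.Ts, self.pulse_sigma) <= 0:
            raise ValueError("delta_T, Ts and pulse_sigma must be positive")
        if 1.0 / self.delta_T <= 2.0 * self.fc:
            raise ValueError(
                "fast-time rate 1/delta_T must exceed twice the pulse "
                "centre frequency (RF Nyquist)"
            )

    @property
    def max_range(self) -> float:
        """Unambiguous range window covered by the fast-time axis (m)."""
        return self.M * self.delta_T * self.c / 2.0

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.Ts


def chest_distance(t, motion: ChestMotion):
    """Instantaneous antenna-to-thorax range d(t) in metres.

    Accepts a scalar or array of times; broadcasts accordingly.
    """
    t = np.asarray(t, dtype=float)
    two_pi = 2.0 * np.pi
    out = (
        motion.d0
        + motion.Ar * np.sin(two_pi * motion.fr * t)
        + motion.Ah * np.sin(two_pi * motion.fh * t)
    )
    return out if out.ndim else float(out)


def pulse_waveform(tau, config: RadarConfig):
    """First-order Gaussian pulse modulated to the carrier frequency.

    s(tau) = -(tau/sigma) * exp(-tau^2 / (2 sigma^2)) * exp(1/2)
             * cos(2 pi fc tau)

    i.e. the derivative of a Gaussian envelope, scaled to near-unit peak
    amplitude, carrying the radar centre frequency. Vanishes rapidly for
    |tau| beyond a few sigma.
    """
    tau = np.asarray(tau, dtype=float)
    x = tau / config.pulse_sigma
    out = -x * np.exp(0.5 - 0.5 * x * x) * np.cos(2.0 * np.pi * config.fc * tau)
    return out if out.ndim else float(out)


def _check_coverage(config: RadarConfig, scene: Scene, motion: ChestMotion) -> None:
    ranges = [motion.d0 + motion.Ar + motion.Ah] + [r for r, _ in scene.statics]
    worst = max(ranges)
    if worst > config.max_range:
        raise ValueError(
            f"scene range {worst:.3f} m exceeds the fast-time window "
            f"{config.max_range:.3f} m"
        )
    if any(r < 0 for r, _ in scene.statics):
        raise ValueError("static reflector ranges must be non-negative")


def synthesize_echo(
    config: RadarConfig,
    scene: Scene,
    motion: ChestMotion,
    seed: int | None = 0,
) -> EchoMatrix:
    """Simulate a full fast-time x slow-time echo matrix.

    Chest return, static-reflector returns, DC offset and seeded i.i.d.
    Gaussian noise are summed per the impulse-response model. The same
    (config, scene, motion, seed) always yields a bit-identical matrix.
    """
    _check_coverage(config, scene, motion)
    tau_fast = np.arange(config.M) * config.delta_T  # (M,)
    t_slow = np.arange(config.N) * config.Ts  # (N,)

    values = np.zeros((config.M, config.N))
    if scene.av != 0.0:
        delays = 2.0 * chest_distance(t_slow, motion) / config.c  # (N,)
        values += scene.av * pulse_waveform(
            tau_fast[:, None] - delays[None, :], config
        )
    for range_i, ai in scene.statics:
        col = ai * pulse_waveform(tau_fast - 2.0 * range_i / config.c, config)
        values += col[:, None]
    values += scene.dc_offset
    if scene.noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        values += rng.normal(0.0, scene.noise_sigma, size=values.shape)
    return EchoMatrix(values=values, delta_T=config.delta_T, Ts=config.Ts)


def chest_row_index(config: RadarConfig, motion: ChestMotion) -> int:
    """Fast-time row nearest the mean chest round-trip delay."""
    return int(round(2.0 * motion.d0 / config.c / config.delta_T))


def snr_to_noise_sigma(
    config: RadarConfig,
    motion: ChestMotion,
    snr_db: float,
    av: float = 1.0,
) -> float:
    """Noise standard deviation giving a target chest-return SNR in dB.

    SNR is defined at the most energetic range gate of the noiseless,
    clutter-free chest echo: 10*log10(P_chest / sigma^2) with P_chest the
    mean-square value of that row.
    """
    clean = synthesize_echo(config, Scene(av=av), motion, seed=None)
    energies = np.sum(clean.values**2, axis=1)
    row = int(np.argmax(energies))
    p_chest = float(np.mean(clean.values[row] ** 2))
    return math.sqrt(p_chest * 10.0 ** (-snr_db / 10.0))


def sample_motion(
    rng: np.random.Generator,
    d0: float = 0.6,
    fr_range: tuple[float, float] = (0.2, 0.35),
    fh_range: tuple[float, float] = (1.0, 1.7),
    harmonic_margin: float = 0.1,
) -> ChestMotion:
    """Draw a random subject for a simulated cohort.

    Respiration and heartbeat frequencies are sampled uniformly from
    physiological resting-state ranges. Draws where the heart rate falls
    within harmonic_margin of a low multiple (2-5x) of the breathing rate
    are rejected: a subject whose pulse sits exactly on a breathing
    harmonic is spectrally ambiguous for any frequency-domain estimator,
    and such coincidences are transient in real subjects because the two
    rhythms drift independently.
    """
    while True:
        fr = float(rng.uniform(*fr_range))
        fh = float(rng.uniform(*fh_range))
        if all(abs(fh - k * fr) > harmonic_margin for k in range(2, 6)):
            return ChestMotion(d0=d0, fr=fr, fh=fh)


def study_scene(
    config: RadarConfig,
    motion: ChestMotion,
    snr_db: float = 0.0,
    statics: Sequence[tuple[float, float]] = ((0.3, 3.0), (0.9, 2.0)),
    dc_offset: float = 0.5,
) -> Scene:
    """Standard simulated measurement environment.

    Two strong static reflectors (furniture/wall-like, brighter than the
    chest return), a receiver DC offset, and white noise set to the given
    chest-return SNR (default 0 dB — noise power equal to the chest-gate
    signal power, a deliberately harsh condition for the weak heartbeat).
    """
    sigma = snr_to_noise_sigma(config, motion, snr_db)
    return Scene(av=1.0, statics=statics, dc_offset=dc_offset, noise_sigma=sigma)
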