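"""File round-trips: CSV matrices/signals, HDF5 containers, YAML configs."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EchoMatrix, SlowTimeSignal
from .echo_sim import ChestMotion

__all__ = [
    "write_echo_csv",
    "read_echo_csv",
    "write_echo_h5",
    "read_echo_h5",
    "write_signal_csv",
    "read_signal_csv",
    "load_yaml",
    "dump_yaml",
]


def write_echo_csv(echo: EchoMatrix, path: str | Path) -> None:
    """Plain CSV: rows fast-time, columns slow-time, no header."""
    pd.DataFrame(echo.values).to_csv(path, header=False, index=False)


def read_echo_csv(path: str | Path, delta_T: float, Ts: float) -> EchoMatrix:
    values = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return EchoMatrix(values=values, delta_T=delta_T, Ts=Ts)


def write_echo_h5(
    echo: EchoMatrix, path: str | Path, motion: ChestMotion | None = None
) -> None:
    """HDF5 container with sampling metadata and optional ground truth."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("echo", data=echo.values)
        ds.attrs["delta_T"] = echo.delta_T
        ds.attrs["Ts"] = echo.Ts
        if motion is not None:
            g = f.create_group("motion")
            for k in ("d0", "Ar", "fr", "Ah", "fh"):
                g.attrs[k] = getattr(motion, k)


def read_echo_h5(path: str | Path) -> tuple[EchoMatrix, ChestMotion | None]:
    with h5py.File(path, "r") as f:
        ds = f["echo"]
        echo = EchoMatrix(
            values=ds[()],
            delta_T=float(ds.attrs["delta_T"]),
            Ts=float(ds.attrs["Ts"]),
        )
        motion = None
        if "motion" in f:
            motion = ChestMotion(**{k: float(v) for k, v in f["motion"].attrs.items()})
    return echo, motion


def write_signal_csv(signal: SlowTimeSignal, path: str | Path) -> None:
    """One-column CSV, no header."""
    np.savetxt(path, signal.values, delimiter=",")


def read_signal_csv(path: str | Path, Ts: float) -> SlowTimeSignal:
    values = np.loadtxt(path, delimiter=",")
    return SlowTimeSignal(values=values, Ts=Ts)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
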