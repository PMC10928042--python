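"""Diffusion acquisition protocol bookkeeping and gradient math.

The protocol couples the b-value table to the pulsed-gradient timing
(gradient-lobe separation ``Δ`` and lobe duration ``δ``) through the
rectangular-lobe Stejskal–Tanner relation

    b = (γ · G_d · δ)² · (Δ − δ/3)

which lets the gradient amplitude ``G_d`` be recovered from a nominal
b-value.  Internal units are mm, s and T throughout, so diffusivities are
mm²/s and G_d is T/mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752e8

#: The 11-b acquisition used throughout: b (s/mm²) -> number of averaged excitations.
DEFAULT_B_TABLE: tuple[tuple[float, int], ...] = (
    (0, 1), (50, 1), (80, 1), (150, 1), (300, 2), (500, 2),
    (800, 3), (1000, 3), (1500, 4), (2000, 4), (3000, 5),
)

#: b-value subsets used by the individual models (s/mm²).
IVIM_B_SUBSET: tuple[float, ...] = (0, 50, 80, 150, 300, 500, 800)
HIGH_B_SUBSET: tuple[float, ...] = (0, 500, 800, 1000, 1500, 2000, 3000)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-b-value diffusion acquisition description.

    Parameters
    ----------
    b_values
        Diffusion weightings in s/mm²; non-negative, strictly increasing,
        starting at 0.
    averages
        Number of averaged excitations per b-value (same length).
    big_delta
        Separation Δ between the two diffusion gradient lobes, in seconds.
    small_delta
        Duration δ of each gradient lobe, in seconds.
    gamma
        Gyromagnetic ratio in rad s^-1 T^-1 (proton by default).
    """

    b_values: tuple[float, ...] = tuple(b for b, _ in DEFAULT_B_TABLE)
    averages: tuple[int, ...] = tuple(n for _, n in DEFAULT_B_TABLE)
    big_delta: float = 42.7e-3
    small_delta: float = 29.4e-3
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size == 0 or b[0] != 0:
            raise ValueError("b_values must start at 0")
        if np.any(b < 0) or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be non-negative and strictly increasing")
        if len(self.averages) != len(self.b_values):
            raise ValueError("averages must match b_values in length")
        if any(n < 1 or int(n) != n for n in self.averages):
            raise ValueError("averages must be positive integers")
        if not (0 < self.small_delta < self.big_delta):
            raise ValueError("need 0 < small_delta < big_delta")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def diffusion_time(self) -> float:
        """Effective diffusion time Δ − δ/3 in seconds."""
        return self.big_delta - self.small_delta / 3.0

    def b_index(self, b: float) -> int:
        """Index of b in the table (exact match)."""
        try:
            return self.b_values.index(b)
        except ValueError:
            raise KeyError(f"b={b} not in protocol table") from None

    def subset_indices(self, b_subset: Sequence[float]) -> np.ndarray:
        return np.array([self.b_index(b) for b in b_subset], dtype=int)


def gradient_amplitude_from_b(b, protocol: AcquisitionProtocol):
    """Diffusion gradient amplitude G_d (T/mm) producing weighting ``b`` (s/mm²).

    Inverts b = (γ G_d δ)² (Δ − δ/3).  Vectorised over ``b``.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b must be non-negative")
    g = np.sqrt(b_arr / protocol.diffusion_time) / (protocol.gamma * protocol.small_delta)
    return g if g.ndim else float(g)


def b_from_gradient(g_d, protocol: AcquisitionProtocol):
    """Forward Stejskal–Tanner: b (s/mm²) from gradient amplitude G_d (T/mm)."""
    g_arr = np.asarray(g_d, dtype=float)
    if np.any(g_arr < 0):
        raise ValueError("G_d must be non-negative")
    b = (protocol.gamma * g_arr * protocol.small_delta) ** 2 * protocol.diffusion_time
    return b if b.ndim else float(b)


def load_protocol(path: str | Path) -> AcquisitionProtocol:
    """Read a protocol from a small key=value config file.

    Recognised keys: ``b_values`` (comma-separated, s/mm²), ``averages``
    (comma-separated ints), ``big_delta_ms``, ``small_delta_ms``, ``gamma``.
    Missing keys fall back to the default 11-b protocol.
    """
    fields: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"cannot parse protocol line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        fields[key.lower()] = val

    kwargs: dict = {}
    if "b_values" in fields:
        kwargs["b_values"] = tuple(float(x) for x in fields["b_values"].split(","))
    if "averages" in fields:
        kwargs["averages"] = tuple(int(x) for x in fields["averages"].split(","))
    elif "b_values" in fields:
        kwargs["averages"] = tuple(1 for _ in kwargs["b_values"])
    if "big_delta_ms" in fields:
        kwargs["big_delta"] = float(fields["big_delta_ms"]) * 1e-3
    if "small_delta_ms" in fields:
        kwargs["small_delta"] = float(fields["small_delta_ms"]) * 1e-3
    if "gamma" in fields:
        kwargs["gamma"] = float(fields["gamma"])
    return AcquisitionProtocol(**kwargs)


def save_protocol(protocol: AcquisitionProtocol, path: str | Path) -> None:
    """Write a protocol config readable by :func:`load_protocol`."""
    lines = [
        "b_values = " + ", ".join(f"{b:g}" for b in protocol.b_values),
        "averages = " + ", ".join(str(n) for n in protocol.averages),
        f"big_delta_ms = {protocol.big_delta * 1e3:g}",
        f"small_delta_ms = {protocol.small_delta * 1e3:g}",
        f"gamma = {protocol.gamma:g}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
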