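"""Magnetization-transfer-ratio mapping from an MT ON / MT OFF image pair.

MTR% = 100 * (S0 - S_MT) / S0 per pixel, where S0 is the unsaturated
(MT OFF) and S_MT the saturated (MT ON) signal.  Noise-driven negative
values are retained by default so ROI means stay unbiased; ``clip=True``
restricts the map to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SENTINEL, Geometry, ParameterMap

__all__ = ["MtPair", "compute_mtr"]


@dataclass
class MtPair:
    """Co-registered MT OFF (s_off = S0) and MT ON (s_on = S_MT) images."""

    s_off: np.ndarray
    s_on: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.s_off = np.asarray(self.s_off, dtype=float)
        self.s_on = np.asarray(self.s_on, dtype=float)
        if self.s_off.shape != self.s_on.shape:
            raise ValueError("MT ON and MT OFF shapes differ")
        if np.any(self.s_off < 0) or np.any(self.s_on < 0):
            raise ValueError("magnitude images must be >= 0")


def compute_mtr(pair: MtPair, mask: np.ndarray | None = None, clip: bool = False) -> ParameterMap:
    """Pixelwise MTR map in percent.

    Masked pixels with S0 = 0 are set to the NaN sentinel and counted in
    ``n_unfittable`` rather than raising.
    """
    if mask is None:
        mask = pair.s_off > 0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pair.s_off.shape:
        raise ValueError("mask shape does not match images")

    values = np.full(pair.s_off.shape, SENTINEL)
    ok = mask & (pair.s_off > 0)
    values[ok] = 100.0 * (pair.s_off[ok] - pair.s_on[ok]) / pair.s_off[ok]
    if clip:
        values[ok] = np.clip(values[ok], 0.0, 100.0)
    n_zero = int(np.sum(mask & ~ok))
    return ParameterMap(
        values, "MTR", "%", mask, geometry=pair.geometry, n_unfittable=n_zero
    )
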