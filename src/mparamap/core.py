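"""Shared in-memory containers for acquisition stacks and parameter maps.

All image-like arrays are indexed ``(row, col, slice)`` with an optional
trailing acquisition axis ``(row, col, slice, n_points)``.  Pixels that were
not (or could not be) fitted carry NaN as the not-a-value sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Not-a-value sentinel used in every map for background / unfittable pixels.
SENTINEL = np.nan


@dataclass(frozen=True)
class Geometry:
    """In-plane pixel size and slice thickness, both in mm."""

    pixel_size_mm: float = 0.2734
    slice_thickness_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("pixel size and slice thickness must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm ** 2


@dataclass
class AcquisitionSeries:
    """A stack of magnitude images sharing geometry with one varying parameter.

    Parameters
    ----------
    data:
        Array ``(rows, cols, slices, n_points)``, signal units, finite, >= 0.
    axis:
        The acquisition parameter per volume: TE (ms) for ``mse``/``mge``,
        TR (ms) for ``satrec``, the scheme row index for ``dwi``, and
        ``[0, 1]`` (OFF, ON) for ``mt``.
    modality:
        One of ``mse | mge | satrec | mt | dwi``.
    """

    data: np.ndarray
    axis: np.ndarray
    modality: str
    geometry: Geometry = field(default_factory=Geometry)

    MODALITIES = ("mse", "mge", "satrec", "mt", "dwi")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (rows, cols, slices, n), got {self.data.ndim}D")
        if self.axis.ndim != 1 or self.data.shape[3] != self.axis.size:
            raise ValueError(
                f"axis length {self.axis.size} does not match {self.data.shape[3]} volumes"
            )
        if self.modality not in self.MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {self.MODALITIES}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series data must be finite")
        if np.any(self.data < 0):
            raise ValueError("magnitude image data must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.axis.size)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ParameterMap:
    """A per-pixel scalar map (T2, T1, MTR, MD, FA, ...) with fit diagnostics.

    ``values`` carries NaN outside ``mask``; ``s0_map`` and ``r_squared``
    are optional diagnostics from the pixelwise fit.
    """

    values: np.ndarray
    param_name: str
    units: str
    mask: np.ndarray
    s0_map: np.ndarray | None = None
    r_squared: np.ndarray | None = None
    geometry: Geometry = field(default_factory=Geometry)
    n_unfittable: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.r_squared is not None:
            r2 = np.asarray(self.r_squared, dtype=float)
            ok = np.isfinite(r2)
            if np.any(r2[ok] > 1 + 1e-9):
                raise ValueError("r_squared above 1")
            self.r_squared = r2

    def masked_values(self) -> np.ndarray:
        """Finite values inside the mask, flattened."""
        v = self.values[self.mask]
        return v[np.isfinite(v)]
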