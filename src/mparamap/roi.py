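"""ROI aggregation and tumor volumetry.

Region summaries pool pixels across all selected slices before averaging
(the per-animal value used by the group statistics), and tumor volume is the
sum of per-slice areas times the slice thickness:

    volume [mm^3] = (TA_slice1 + TA_slice2 + ...) * ST
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Geometry, ParameterMap

__all__ = ["RoiSet", "RegionSummary", "tumor_volume", "mask_area", "summarize", "summaries_frame"]


@dataclass
class RoiSet:
    """Integer-label image with a label table (id -> region name)."""

    label_image: np.ndarray  # (rows, cols, slices), 0 = background
    labels: dict[int, str]
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if not np.issubdtype(self.label_image.dtype, np.integer):
            raise ValueError("label image must be integer-typed")
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("region names must be unique")
        present = set(np.unique(self.label_image)) - {0}
        unknown = present - set(self.labels)
        if unknown:
            raise ValueError(f"label image contains ids without names: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self.labels.values())

    def mask(self, name: str) -> np.ndarray:
        for lid, lname in self.labels.items():
            if lname == name:
                return self.label_image == lid
        raise KeyError(f"unknown region {name!r}; known: {self.names}")

    def slice_areas_mm2(self, name: str) -> np.ndarray:
        """Per-slice region area in mm²."""
        m = self.mask(name)
        return m.sum(axis=(0, 1)) * self.geometry.pixel_area_mm2


@dataclass
class RegionSummary:
    """Pooled per-animal statistics of one parameter over one region."""

    animal_id: str
    region: str
    parameter: str
    mean: float
    sd: float
    n_pixels: int
    n_slices: int
    valid: bool = True


def mask_area(mask_slice: np.ndarray, pixel_area_mm2: float) -> float:
    """Area of a binary slice mask in mm²."""
    mask_slice = np.asarray(mask_slice, dtype=bool)
    return float(mask_slice.sum()) * pixel_area_mm2


def tumor_volume(areas_mm2, st_mm: float) -> float:
    """Tumor volume in mm³ from per-slice areas and the slice thickness."""
    areas = np.asarray(areas_mm2, dtype=float)
    if np.any(areas < 0):
        raise ValueError("slice areas must be >= 0")
    if st_mm <= 0:
        raise ValueError("slice thickness must be > 0")
    return float(areas.sum() * st_mm)


def summarize(pmap: ParameterMap, rois: RoiSet, animal_id: str = "") -> list[RegionSummary]:
    """One pooled summary per region: pixels of all slices pooled, then
    averaged (not a mean of per-slice means)."""
    if pmap.values.shape != rois.label_image.shape:
        raise ValueError("map and label image are not aligned")
    out = []
    for name in rois.names:
        m = rois.mask(name) & pmap.mask
        vals = pmap.values[m]
        vals = vals[np.isfinite(vals)]
        n_slices = int(np.sum(rois.mask(name).any(axis=(0, 1))))
        if vals.size == 0:
            out.append(
                RegionSummary(animal_id, name, pmap.param_name, np.nan, np.nan, 0, n_slices, valid=False)
            )
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(
            RegionSummary(animal_id, name, pmap.param_name, float(np.mean(vals)), sd, int(vals.size), n_slices)
        )
    return out


def summaries_frame(summaries: list[RegionSummary], group: str | None = None) -> pd.DataFrame:
    """Tidy DataFrame (animal, group, region, parameter, mean, sd, n_pixels)."""
    df = pd.DataFrame(
        {
            "animal": [s.animal_id for s in summaries],
            "region": [s.region for s in summaries],
            "parameter": [s.parameter for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
            "n_pixels": [s.n_pixels for s in summaries],
            "n_slices": [s.n_slices for s in summaries],
            "valid": [s.valid for s in summaries],
        }
    )
    if group is not None:
        df.insert(1, "group", group)
    return df
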