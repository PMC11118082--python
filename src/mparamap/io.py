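"""NIfTI / CSV / JSON readers and writers.

Conventions: 4D acquisition stacks go to ``.nii.gz`` with a sidecar
``.json`` naming the varying parameter (``te_ms``, ``tr_ms``, ``mt_state``
or a ``bval``/``bvec`` pair of FSL-style text tables); parameter maps go to
3D NIfTI plus a JSON summary; spectra are two-column CSV (ppm, intensity)
with a JSON header; tidy tables are plain CSV written at full float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import AcquisitionSeries, Geometry, ParameterMap
from .dti import DiffusionScheme
from .mrs import Spectrum
from .roi import RoiSet

__all__ = [
    "write_series",
    "read_series",
    "write_map",
    "read_map",
    "write_labels",
    "read_labels",
    "write_scheme",
    "read_scheme",
    "write_spectrum",
    "read_spectrum",
    "write_table",
]

_AXIS_KEY = {"mse": "te_ms", "mge": "te_ms", "satrec": "tr_ms", "mt": "mt_state", "dwi": "row_index"}


def _affine(geometry: Geometry) -> np.ndarray:
    return np.diag([geometry.pixel_size_mm, geometry.pixel_size_mm, geometry.slice_thickness_mm, 1.0])


def write_series(series: AcquisitionSeries, path: str | Path, scheme: DiffusionScheme | None = None) -> Path:
    """Write a 4D stack as NIfTI + sidecar JSON (+ bval/bvec for DWI)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(series.data, _affine(series.geometry)), path)
    sidecar = {
        "modality": series.modality,
        _AXIS_KEY[series.modality]: series.axis.tolist(),
        "pixel_size_mm": series.geometry.pixel_size_mm,
        "slice_thickness_mm": series.geometry.slice_thickness_mm,
    }
    base = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    if series.modality == "dwi":
        if scheme is None:
            raise ValueError("a DiffusionScheme is required to write a dwi series")
        write_scheme(scheme, base)
        sidecar["bval"] = base.name + ".bval"
        sidecar["bvec"] = base.name + ".bvec"
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_series(path: str | Path) -> AcquisitionSeries:
    """Read a 4D stack written by :func:`write_series`."""
    path = Path(path)
    base = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar JSON missing: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    modality = sidecar["modality"]
    axis = np.asarray(sidecar[_AXIS_KEY[modality]], dtype=float)
    if data.shape[3] != axis.size:
        raise ValueError(f"sidecar lists {axis.size} volumes but image has {data.shape[3]}")
    geometry = Geometry(sidecar["pixel_size_mm"], sidecar["slice_thickness_mm"])
    return AcquisitionSeries(data, axis, modality, geometry)


def write_scheme(scheme: DiffusionScheme, base: str | Path) -> None:
    """FSL-style text tables: one row of b-values, three rows of components."""
    base = Path(base)
    np.savetxt(base.with_suffix(".bval"), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(base.with_suffix(".bvec"), scheme.bvecs.T, fmt="%.17g")


def read_scheme(bval_path: str | Path, bvec_path: str | Path) -> DiffusionScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise ValueError(f"bval lists {bvals.size} rows but bvec has {bvecs.shape[0]}")
    return DiffusionScheme(bvals, bvecs)


def write_map(pmap: ParameterMap, path: str | Path) -> Path:
    """Parameter map as 3D NIfTI + JSON metadata (units, diagnostics)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(pmap.values, _affine(pmap.geometry)), path)
    base = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    meta = {
        "param_name": pmap.param_name,
        "units": pmap.units,
        "n_unfittable": pmap.n_unfittable,
        "pixel_size_mm": pmap.geometry.pixel_size_mm,
        "slice_thickness_mm": pmap.geometry.slice_thickness_mm,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    base = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    meta = json.loads(base.with_suffix(".json").read_text())
    img = nib.load(path)
    values = np.asarray(img.dataobj, dtype=float)
    return ParameterMap(
        values, meta["param_name"], meta["units"], np.isfinite(values),
        geometry=Geometry(meta["pixel_size_mm"], meta["slice_thickness_mm"]),
        n_unfittable=meta.get("n_unfittable", 0),
    )


def write_labels(rois: RoiSet, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(rois.label_image.astype(np.int16), _affine(rois.geometry)), path)
    base = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    meta = {
        "labels": {str(k): v for k, v in rois.labels.items()},
        "pixel_size_mm": rois.geometry.pixel_size_mm,
        "slice_thickness_mm": rois.geometry.slice_thickness_mm,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_labels(path: str | Path) -> RoiSet:
    path = Path(path)
    base = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    meta = json.loads(base.with_suffix(".json").read_text())
    img = nib.load(path)
    labels = {int(k): v for k, v in meta["labels"].items()}
    return RoiSet(
        np.asarray(img.dataobj).astype(np.int32), labels,
        Geometry(meta["pixel_size_mm"], meta["slice_thickness_mm"]),
    )


def write_spectrum(spectrum: Spectrum, path: str | Path, noise_sigma: float = 0.0, seed: int | None = None) -> Path:
    """Two-column CSV (ppm, intensity) plus a JSON header."""
    path = Path(path)
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity}).to_csv(path, index=False)
    header = {
        "ppm_min": float(spectrum.ppm.min()),
        "ppm_max": float(spectrum.ppm.max()),
        "n_points": int(spectrum.ppm.size),
        "te_ms": spectrum.te_ms,
        "sample_id": spectrum.sample_id,
        "region": spectrum.region,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    header_path = path.with_suffix(".json")
    meta = json.loads(header_path.read_text()) if header_path.exists() else {}
    return Spectrum(
        df["ppm"].to_numpy(), df["intensity"].to_numpy(),
        te_ms=meta.get("te_ms", 36.0), sample_id=meta.get("sample_id", ""),
        region=meta.get("region", ""),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV at full (repr-faithful) float precision."""
    path = Path(path)
    df.to_csv(path, index=False, float_format=None)
    return path
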