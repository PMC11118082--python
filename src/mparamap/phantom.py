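"""Synthetic multiparametric-MRI phantom with known ground truth.

The phantom emulates an axial preclinical acquisition of a rat brain bearing
an orthotopic C6 glioma: a disc-shaped "tumor" region in one hemisphere and a
mirrored "contralateral" disc, each carrying its own relaxation times
(T2, T2*, T1), magnetization-transfer ratio, diffusion tensor (from MD + FA)
and metabolite profile.  Forward models:

* multi-echo spin echo          S(TE) = S0 * exp(-TE / T2)
* multi-gradient echo           S(TE) = S0 * exp(-TE / T2*)
* saturation recovery           S(TR) = S0 * (1 - exp(-TR / T1))
* magnetization transfer pair   S_on  = S0 * (1 - MTR / 100), S_off = S0
* diffusion (Stejskal-Tanner)   S(b,g) = S0 * exp(-b * g^T D g)

Noise is Rician (magnitude reconstruction of complex Gaussian noise); the
noiseless phantom round-trips exactly through every fitting stage, which is
what makes the downstream modules testable without any acquired data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SENTINEL, AcquisitionSeries, Geometry, ParameterMap
from .dti import DiffusionScheme, default_scheme
from .roi import RoiSet

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_phantom",
    "simulate_mse",
    "simulate_mge",
    "simulate_satrec",
    "simulate_mt_pair",
    "simulate_dwi",
    "add_rician_noise",
    "tensor_from_md_fa",
    "c6_study_regions",
    "c6_study_sems",
    "simulate_study_values",
    "GROUP_SIZES",
    "default_phantom_spec",
]

# TE / TR grids emulating a 7 T preclinical protocol: 75 spin echoes
# 12-900 ms, 20 gradient echoes 2.73-83.86 ms, 8 saturation-recovery TRs
# spanning 125-6000 ms.
DEFAULT_MSE_TE_MS = np.linspace(12.0, 900.0, 75)
DEFAULT_MGE_TE_MS = np.linspace(2.73, 83.86, 20)
DEFAULT_SATREC_TR_MS = np.array([125.0, 250.0, 500.0, 1000.0, 1500.0, 2500.0, 4000.0, 6000.0])


@dataclass
class RegionSpec:
    """Tissue parameters of one disc-shaped phantom region.

    ``center_px`` is the (row, col) disc centre and ``radius_px`` the radius,
    both in pixels; the disc is replicated on every slice.  ``md_um2s`` is in
    µm²/s, relaxation times in ms, ``mtr_percent`` in percent and ``fa``
    dimensionless in [0, 1).  ``metabolite_ratios`` maps metabolite name to
    its concentration relative to total creatine (PCr + Cr = 1).
    """

    label: str
    center_px: tuple[float, float]
    radius_px: float
    t2_ms: float = 50.0
    t2star_ms: float = 22.0
    t1_ms: float = 2000.0
    mtr_percent: float = 30.0
    md_um2s: float = 800.0
    fa: float = 0.0
    principal_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    s0: float = 1000.0
    metabolite_ratios: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("t2_ms", "t2star_ms", "t1_ms", "md_um2s", "s0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.label}: {name} must be > 0")
        if not 0.0 <= self.fa < 1.0:
            raise ValueError(f"{self.label}: fa must be in [0, 1)")
        if not 0.0 <= self.mtr_percent <= 100.0:
            raise ValueError(f"{self.label}: mtr_percent must be in [0, 100]")
        if self.radius_px <= 0:
            raise ValueError(f"{self.label}: radius_px must be > 0")
        if any(v < 0 for v in self.metabolite_ratios.values()):
            raise ValueError(f"{self.label}: metabolite ratios must be >= 0")
        ax = np.asarray(self.principal_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError(f"{self.label}: principal_axis must be non-zero")
        self.principal_axis = tuple(ax / n)

    def mask(self, grid_shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.ogrid[: grid_shape[0], : grid_shape[1]]
        r0, c0 = self.center_px
        return (rows - r0) ** 2 + (cols - c0) ** 2 <= self.radius_px ** 2


@dataclass
class PhantomSpec:
    """Geometry, regions, noise level and seed of one synthetic phantom."""

    grid_shape: tuple[int, int] = (64, 64)
    n_slices: int = 5
    pixel_size_mm: float = 0.2734
    slice_thickness_mm: float = 1.5
    regions: list[RegionSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) <= 0 or self.n_slices <= 0:
            raise ValueError("grid_shape and n_slices must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def geometry(self) -> Geometry:
        return Geometry(self.pixel_size_mm, self.slice_thickness_mm)


@dataclass
class GroundTruth:
    """Per-pixel true parameter maps plus the tensor field behind them."""

    maps: dict[str, ParameterMap]
    tensor_mm2s: np.ndarray  # (rows, cols, slices, 3, 3)
    s0: np.ndarray  # (rows, cols, slices)
    rois: RoiSet
    spec: PhantomSpec

    @property
    def mask(self) -> np.ndarray:
        return self.rois.label_image > 0

    def region_mask(self, label: str) -> np.ndarray:
        return self.rois.mask(label)


def tensor_from_md_fa(
    md_um2s: float, fa: float, principal_axis: tuple[float, float, float]
) -> np.ndarray:
    """Axially symmetric (prolate) 3x3 tensor in mm²/s with the given MD and FA.

    For lambda2 = lambda3 the fractional anisotropy reduces to
    FA = (l1 - l2) / sqrt(l1² + 2 l2²); inverting for the eigenvalue ratio
    r = l1/l2 gives r = (1 + FA sqrt(3 - 2 FA²)) / (1 - FA²).
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must be in [0, 1)")
    md_mm2s = md_um2s * 1e-6
    r = (1.0 + fa * np.sqrt(3.0 - 2.0 * fa ** 2)) / (1.0 - fa ** 2)
    lam_perp = 3.0 * md_mm2s / (r + 2.0)
    lam_par = r * lam_perp
    n = np.asarray(principal_axis, dtype=float)
    n = n / np.linalg.norm(n)
    return lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(n, n)


def make_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterize the region specs into ground-truth maps and a tensor field.

    Background pixels carry NaN in every map and 0 in the label image;
    overlapping regions or regions extending beyond the grid are errors.
    """
    shape3 = (*spec.grid_shape, spec.n_slices)
    geometry = spec.geometry

    label_image = np.zeros(shape3, dtype=np.int32)
    labels: dict[int, str] = {}
    masks_2d: dict[str, np.ndarray] = {}
    for i, region in enumerate(spec.regions, start=1):
        m2 = region.mask(spec.grid_shape)
        r0, c0 = region.center_px
        if (
            r0 - region.radius_px < -0.5
            or c0 - region.radius_px < -0.5
            or r0 + region.radius_px > spec.grid_shape[0] - 0.5
            or c0 + region.radius_px > spec.grid_shape[1] - 0.5
        ):
            raise ValueError(f"region {region.label!r} extends outside the grid")
        for other, m_other in masks_2d.items():
            if np.any(m2 & m_other):
                raise ValueError(f"regions {other!r} and {region.label!r} overlap")
        masks_2d[region.label] = m2
        label_image[m2, :] = i
        labels[i] = region.label

    param_fields = {
        "t2_ms": ("T2", "ms"),
        "t2star_ms": ("T2*", "ms"),
        "t1_ms": ("T1", "ms"),
        "mtr_percent": ("MTR", "%"),
        "md_um2s": ("MD", "um^2/s"),
        "fa": ("FA", ""),
    }
    mask3 = label_image > 0
    maps: dict[str, ParameterMap] = {}
    for attr, (name, units) in param_fields.items():
        values = np.full(shape3, SENTINEL)
        for region in spec.regions:
            values[masks_2d[region.label], :] = getattr(region, attr)
        maps[attr] = ParameterMap(values, name, units, mask3.copy(), geometry=geometry)

    s0 = np.zeros(shape3)
    tensor = np.zeros((*shape3, 3, 3))
    for region in spec.regions:
        s0[masks_2d[region.label], :] = region.s0
        tensor[masks_2d[region.label], :, :, :] = tensor_from_md_fa(
            region.md_um2s, region.fa, region.principal_axis
        )

    rois = RoiSet(label_image, labels, geometry)
    return GroundTruth(maps=maps, tensor_mm2s=tensor, s0=s0, rois=rois, spec=spec)


def _finalize(spec: PhantomSpec, data: np.ndarray, axis, modality: str) -> AcquisitionSeries:
    series = AcquisitionSeries(data, np.asarray(axis, dtype=float), modality, spec.geometry)
    if spec.noise_sigma > 0:
        series = add_rician_noise(series, spec.noise_sigma, spec.seed)
    return series


def simulate_mse(gt: GroundTruth, te_list=DEFAULT_MSE_TE_MS) -> AcquisitionSeries:
    """Multi-echo spin-echo stack: S(TE) = S0 exp(-TE/T2), background 0."""
    return _simulate_decay(gt, te_list, "t2_ms", "mse")


def simulate_mge(gt: GroundTruth, te_list=DEFAULT_MGE_TE_MS) -> AcquisitionSeries:
    """Multi-gradient-echo stack: S(TE) = S0 exp(-TE/T2*)."""
    return _simulate_decay(gt, te_list, "t2star_ms", "mge")


def _simulate_decay(gt: GroundTruth, te_list, param: str, modality: str) -> AcquisitionSeries:
    te = np.asarray(te_list, dtype=float)
    if te.size == 0:
        raise ValueError("te_list must not be empty")
    if np.any(te <= 0) or np.any(np.diff(te) <= 0):
        raise ValueError("te_list must be strictly increasing and positive")
    t = gt.maps[param].values
    with np.errstate(invalid="ignore", divide="ignore"):
        signal = gt.s0[..., None] * np.exp(-te / t[..., None])
    signal[~gt.mask, :] = 0.0
    return _finalize(gt.spec, signal, te, modality)


def simulate_satrec(gt: GroundTruth, tr_list=DEFAULT_SATREC_TR_MS) -> AcquisitionSeries:
    """Saturation-recovery stack: S(TR) = S0 (1 - exp(-TR/T1))."""
    tr = np.asarray(tr_list, dtype=float)
    if tr.size == 0:
        raise ValueError("tr_list must not be empty")
    if np.any(tr <= 0) or np.any(np.diff(tr) <= 0):
        raise ValueError("tr_list must be strictly increasing and positive")
    t1 = gt.maps["t1_ms"].values
    with np.errstate(invalid="ignore", divide="ignore"):
        signal = gt.s0[..., None] * (1.0 - np.exp(-tr / t1[..., None]))
    signal[~gt.mask, :] = 0.0
    return _finalize(gt.spec, signal, tr, "satrec")


def simulate_mt_pair(gt: GroundTruth) -> tuple[AcquisitionSeries, AcquisitionSeries]:
    """(MT OFF, MT ON) pair with S_on = S0 * (1 - MTR/100) per pixel."""
    mtr = gt.maps["mtr_percent"].values
    s_off = gt.s0.copy()
    s_on = np.where(gt.mask, gt.s0 * (1.0 - mtr / 100.0), 0.0)
    spec = gt.spec
    off = _finalize(spec, s_off[..., None], [0.0], "mt")
    # distinct sub-seed so ON/OFF noise realizations are independent
    on_spec = PhantomSpec(
        spec.grid_shape, spec.n_slices, spec.pixel_size_mm, spec.slice_thickness_mm,
        [], spec.noise_sigma, spec.seed + 1,
    )
    on = _finalize(on_spec, s_on[..., None], [1.0], "mt")
    return off, on


def simulate_dwi(gt: GroundTruth, scheme: DiffusionScheme | None = None) -> AcquisitionSeries:
    """Diffusion-weighted stack, one volume per scheme row.

    Per pixel S = S0 exp(-b g^T D g); the b = 0 rows return S0 exactly.
    """
    if scheme is None:
        scheme = default_scheme()
    # attenuation exponent per pixel and row: b * g^T D g
    quad = np.einsum("...ij,ni,nj->...n", gt.tensor_mm2s, scheme.bvecs, scheme.bvecs)
    signal = gt.s0[..., None] * np.exp(-scheme.bvals * quad)
    signal[~gt.mask, :] = 0.0
    return _finalize(gt.spec, signal, np.arange(len(scheme.bvals)), "dwi")


def add_rician_noise(series: AcquisitionSeries, sigma: float, seed: int) -> AcquisitionSeries:
    """Apply magnitude (Rician) noise: M = sqrt((S + n1)² + n2²), n ~ N(0, σ²)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return series
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, series.data.shape)
    n2 = rng.normal(0.0, sigma, series.data.shape)
    noisy = np.sqrt((series.data + n1) ** 2 + n2 ** 2)
    return AcquisitionSeries(noisy, series.axis, series.modality, series.geometry)


# ---------------------------------------------------------------------------
# Study conditions: region parameters of an advanced-stage C6 glioma model
# at 7 T (group means) and its ex vivo metabolite profile relative to total
# creatine.  The free choline/phosphocholine remainder of the composite
# Cho+GPC+PCh pool is split evenly between Cho and PCh (only the composite
# and GPC are separately identified).
# ---------------------------------------------------------------------------

_C6_REGIONS: dict[str, dict] = {
    "gbm_tumor": dict(
        t2_ms=66.52, t2star_ms=22.75, t1_ms=2574.0, mtr_percent=15.15,
        md_um2s=1064.0, fa=0.255,
        metabolite_ratios={
            "Ala": 0.25, "Lac": 0.53, "Tau": 0.93, "NAA": 0.70,
            "GPC": 0.16, "Cho": 0.08, "PCh": 0.08, "mI": 0.77,
        },
    ),
    "gbm_contralateral": dict(
        t2_ms=51.26, t2star_ms=21.85, t1_ms=2090.0, mtr_percent=30.56,
        md_um2s=816.0, fa=0.284,
        metabolite_ratios={
            "Ala": 0.03, "Lac": 0.26, "Tau": 0.48, "NAA": 1.39,
            "GPC": 0.17, "Cho": 0.02, "PCh": 0.02, "mI": 0.75,
        },
    ),
    "sham_ipsilateral": dict(
        t2_ms=49.64, t2star_ms=22.59, t1_ms=1937.0, mtr_percent=30.03,
        md_um2s=815.0, fa=0.232,
        metabolite_ratios={
            "Ala": 0.07, "Lac": 0.26, "Tau": 0.36, "NAA": 1.59,
            "GPC": 0.07, "Cho": 0.02, "PCh": 0.02, "mI": 0.35,
        },
    ),
    "sham_contralateral": dict(
        t2_ms=49.91, t2star_ms=21.81, t1_ms=1942.0, mtr_percent=29.79,
        md_um2s=836.0, fa=0.231,
        metabolite_ratios={
            "Ala": 0.08, "Lac": 0.26, "Tau": 0.51, "NAA": 1.59,
            "GPC": 0.09, "Cho": 0.015, "PCh": 0.015, "mI": 0.43,
        },
    ),
}


#: Standard errors of the group means for each imaging parameter, same
#: region order/keys as ``_C6_REGIONS`` (GBM n = 10, sham n = 4).
_C6_SEM: dict[str, dict[str, float]] = {
    "gbm_tumor": dict(t2_ms=2.43, t2star_ms=1.30, t1_ms=37.0, mtr_percent=1.46, md_um2s=52.0, fa=0.045),
    "gbm_contralateral": dict(t2_ms=0.56, t2star_ms=1.54, t1_ms=45.0, mtr_percent=1.99, md_um2s=30.0, fa=0.035),
    "sham_ipsilateral": dict(t2_ms=0.35, t2star_ms=3.23, t1_ms=17.0, mtr_percent=0.95, md_um2s=9.0, fa=0.012),
    "sham_contralateral": dict(t2_ms=0.21, t2star_ms=2.69, t1_ms=38.0, mtr_percent=1.10, md_um2s=16.0, fa=0.013),
}

#: Group sizes of the emulated design.
GROUP_SIZES = {"gbm": 10, "sham": 4}


def c6_study_regions() -> dict[str, dict]:
    """Reference tissue parameters (group means) of the emulated C6 model."""
    return {k: dict(v, metabolite_ratios=dict(v["metabolite_ratios"])) for k, v in _C6_REGIONS.items()}


def c6_study_sems() -> dict[str, dict[str, float]]:
    """Standard errors of the group means (imaging parameters)."""
    return {k: dict(v) for k, v in _C6_SEM.items()}


def simulate_study_values(
    attr: str,
    seed: int,
    n_gbm: int = GROUP_SIZES["gbm"],
    n_sham: int = GROUP_SIZES["sham"],
):
    """Draw per-animal region values for one imaging parameter.

    Animal values are Normal(group mean, SEM * sqrt(n)) so that the sample
    mean of each simulated cell has the reported standard error.  Returns a
    tidy DataFrame (animal, group, region, parameter, value) whose region
    names are harmonized to ipsilateral/contralateral for the 2x2 design.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cells = [
        ("gbm", "ipsilateral", "gbm_tumor", n_gbm),
        ("gbm", "contralateral", "gbm_contralateral", n_gbm),
        ("sham", "ipsilateral", "sham_ipsilateral", n_sham),
        ("sham", "contralateral", "sham_contralateral", n_sham),
    ]
    for group, region, key, n in cells:
        mean = _C6_REGIONS[key][attr]
        sd = _C6_SEM[key][attr] * np.sqrt(n)
        values = rng.normal(mean, sd, n)
        for i, v in enumerate(values):
            rows.append(
                dict(animal=f"{group}{i + 1:02d}", group=group, region=region,
                     parameter=attr, value=float(v))
            )
    return pd.DataFrame(rows)


def default_phantom_spec(
    group: str = "gbm",
    noise_sigma: float = 0.0,
    seed: int = 0,
    grid_shape: tuple[int, int] = (64, 64),
    n_slices: int = 5,
    radius_px: float = 10.0,
    overrides: dict[str, dict] | None = None,
) -> PhantomSpec:
    """Default two-region phantom: a right-hemisphere tumor (or sham
    ipsilateral) disc and its mirrored contralateral disc.

    ``overrides`` patches individual region parameters, e.g.
    ``{"tumor": {"t2_ms": 70.0}}``.
    """
    ref = c6_study_regions()
    if group == "gbm":
        ipsi_name, ipsi_params = "tumor", ref["gbm_tumor"]
        contra_params = ref["gbm_contralateral"]
    elif group == "sham":
        ipsi_name, ipsi_params = "ipsilateral", ref["sham_ipsilateral"]
        contra_params = ref["sham_contralateral"]
    else:
        raise ValueError(f"unknown group {group!r}; expected 'gbm' or 'sham'")

    rows, cols = grid_shape
    offset = cols / 4.0
    centers = {"ipsi": (rows / 2.0, cols / 2.0 + offset - 0.5), "contra": (rows / 2.0, cols / 2.0 - offset - 0.5)}
    overrides = overrides or {}
    ipsi = dict(ipsi_params, **overrides.get(ipsi_name, {}))
    contra = dict(contra_params, **overrides.get("contralateral", {}))
    regions = [
        RegionSpec(label=ipsi_name, center_px=centers["ipsi"], radius_px=radius_px, **ipsi),
        RegionSpec(label="contralateral", center_px=centers["contra"], radius_px=radius_px, **contra),
    ]
    return PhantomSpec(
        grid_shape=grid_shape, n_slices=n_slices, regions=regions,
        noise_sigma=noise_sigma, seed=seed,
    )
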