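"""Diffusion-tensor estimation and MD / FA scalar maps.

The signal model is the Stejskal-Tanner mono-exponential tensor model
``ln S = ln S0 - b g^T D g``.  Per pixel the six unique tensor elements plus
``ln S0`` are estimated by ordinary least squares on the log-signal over all
volumes; eigenvalues are sorted descending and clamped at zero before the
scalar maps

    MD = (l1 + l2 + l3) / 3
    FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2)

are computed.  Tensors are kept in mm²/s internally; MD maps are reported in
µm²/s (1e-3 mm²/s = 1000 µm²/s), matching the convention of preclinical
brain studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SENTINEL, AcquisitionSeries, Geometry, ParameterMap

__all__ = [
    "DiffusionScheme",
    "TensorField",
    "default_scheme",
    "design_matrix",
    "fit_tensor",
    "eigenvalues_to_md",
    "eigenvalues_to_fa",
    "mean_diffusivity",
    "fractional_anisotropy",
]

MM2S_TO_UM2S = 1.0e6

# Seven non-degenerate directions used when no scheme is supplied:
# the three axes, three face diagonals and the body diagonal.
_DEFAULT_DIRECTIONS = np.array(
    [
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 0),
        (1, 0, 1),
        (0, 1, 1),
        (1, 1, 1),
    ],
    dtype=float,
)
_DEFAULT_DIRECTIONS /= np.linalg.norm(_DEFAULT_DIRECTIONS, axis=1, keepdims=True)


@dataclass
class DiffusionScheme:
    """b-value / gradient-direction table defining the DWI design matrix.

    ``delta_ms`` (gradient duration) and ``Delta_ms`` (gradient separation)
    are carried as acquisition metadata only; b-values are used as given.
    """

    bvals: np.ndarray  # (n,), s/mm^2
    bvecs: np.ndarray  # (n, 3), unit vectors for b > 0 rows
    delta_ms: float = 4.0
    Delta_ms: float = 20.0

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be >= 0")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit vectors for b > 0 rows")
        X = design_matrix(self)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient diffusion scheme: need >= 6 non-collinear directions")

    def __len__(self) -> int:
        return int(self.bvals.size)


def default_scheme(bvals=(300.0, 1400.0)) -> DiffusionScheme:
    """One b=0 volume plus 7 directions at each supplied b factor."""
    rows_b = [0.0]
    rows_g = [(0.0, 0.0, 0.0)]
    for b in bvals:
        for g in _DEFAULT_DIRECTIONS:
            rows_b.append(float(b))
            rows_g.append(tuple(g))
    return DiffusionScheme(np.array(rows_b), np.array(rows_g))


def design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """OLS design: columns (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0)."""
    b = scheme.bvals
    g = scheme.bvecs
    X = np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
            np.ones_like(b),
        ]
    )
    return X


@dataclass
class TensorField:
    """Per-pixel symmetric tensors (mm²/s) with sorted eigen-decomposition."""

    tensors: np.ndarray  # (rows, cols, slices, 3, 3)
    eigenvalues: np.ndarray  # (rows, cols, slices, 3), descending
    principal_direction: np.ndarray  # (rows, cols, slices, 3)
    mask: np.ndarray
    s0_map: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)
    n_clamped: int = 0
    n_unfittable: int = 0


def _coeffs_to_tensor(beta: np.ndarray) -> np.ndarray:
    """(..., 6) tensor coefficients -> (..., 3, 3) symmetric matrices."""
    out = np.empty(beta.shape[:-1] + (3, 3))
    out[..., 0, 0] = beta[..., 0]
    out[..., 1, 1] = beta[..., 1]
    out[..., 2, 2] = beta[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = beta[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = beta[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = beta[..., 5]
    return out


def fit_tensor(
    series: AcquisitionSeries, scheme: DiffusionScheme, mask: np.ndarray | None = None
) -> TensorField:
    """Log-linear OLS tensor fit per masked pixel.

    Pixels with non-positive signal on the b = 0 row are unfittable; rows with
    non-positive diffusion-weighted signal are dropped for that pixel (at
    least 7 usable rows required, else sentinel).  Negative eigenvalues are
    clamped at zero after decomposition; the clamp count is reported.
    """
    if len(scheme) != series.n_points:
        raise ValueError(
            f"scheme has {len(scheme)} rows but series has {series.n_points} volumes"
        )
    shape3 = series.spatial_shape
    if mask is None:
        mask = np.any(series.data > 0, axis=-1)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape3:
        raise ValueError("mask shape does not match series")

    X = design_matrix(scheme)
    n_rows = X.shape[0]
    signals = series.data[mask]  # (npix, n_rows)
    b0 = scheme.bvals == 0
    usable_pix = signals[:, b0].max(axis=1) > 0 if b0.any() else np.ones(len(signals), bool)

    beta = np.full((signals.shape[0], 7), np.nan)
    pos = signals > 0
    all_pos = pos.all(axis=1) & usable_pix
    # vectorized path: every row positive
    if np.any(all_pos):
        Y = np.log(signals[all_pos])
        coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        beta[all_pos] = coef.T
    # per-pixel path: some rows dropped
    n_unfittable = int(np.sum(~usable_pix))
    for i in np.nonzero(usable_pix & ~all_pos)[0]:
        keep = pos[i]
        if keep.sum() < 7:
            n_unfittable += 1
            continue
        coef, *_ = np.linalg.lstsq(X[keep], np.log(signals[i, keep]), rcond=None)
        beta[i] = coef

    tensors = np.zeros((*shape3, 3, 3))
    evals = np.full((*shape3, 3), SENTINEL)
    evecs1 = np.full((*shape3, 3), SENTINEL)
    s0_map = np.full(shape3, SENTINEL)

    fitted = np.isfinite(beta).all(axis=1)
    D = _coeffs_to_tensor(beta[fitted, :6])
    w, V = np.linalg.eigh(D)  # ascending
    order = np.argsort(w, axis=-1)[..., ::-1]
    w = np.take_along_axis(w, order, axis=-1)
    n_clamped = int(np.sum(w < 0))
    w = np.clip(w, 0.0, None)
    v1 = np.take_along_axis(V, order[..., None, :], axis=-1)[..., :, 0]

    full_idx = np.zeros(shape3, dtype=bool)
    full_idx[mask] = fitted
    tensors[full_idx] = D
    evals[full_idx] = w
    evecs1[full_idx] = v1
    s0_full = np.full(mask.sum(), np.nan)
    s0_full[fitted] = np.exp(beta[fitted, 6])
    s0_map[mask] = s0_full

    return TensorField(
        tensors=tensors,
        eigenvalues=evals,
        principal_direction=evecs1,
        mask=full_idx,
        s0_map=s0_map,
        geometry=series.geometry,
        n_clamped=n_clamped,
        n_unfittable=n_unfittable,
    )


def eigenvalues_to_md(evals: np.ndarray) -> np.ndarray:
    """MD = mean eigenvalue, same units as the eigenvalues."""
    return np.mean(evals, axis=-1)


def eigenvalues_to_fa(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) ||l - MD|| / ||l||; defined as 0 for an all-zero tensor."""
    md = np.mean(evals, axis=-1, keepdims=True)
    num = np.sum((evals - md) ** 2, axis=-1)
    den = np.sum(evals ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, np.where(np.isfinite(den), 0.0, np.nan))


def mean_diffusivity(field: TensorField) -> ParameterMap:
    """Per-pixel MD map in µm²/s."""
    md = eigenvalues_to_md(field.eigenvalues) * MM2S_TO_UM2S
    return ParameterMap(
        md, "MD", "um^2/s", field.mask, s0_map=field.s0_map,
        geometry=field.geometry, n_unfittable=field.n_unfittable,
    )


def fractional_anisotropy(field: TensorField) -> ParameterMap:
    """Per-pixel FA map (dimensionless, in [0, 1] after eigenvalue clamping)."""
    fa = eigenvalues_to_fa(field.eigenvalues)
    return ParameterMap(
        fa, "FA", "", field.mask, s0_map=field.s0_map,
        geometry=field.geometry, n_unfittable=field.n_unfittable,
    )
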