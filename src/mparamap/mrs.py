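"""Simplified linear-combination modeling of 1H spectra.

A measured (or synthetic) spectrum is fitted as a non-negative weighted sum
of per-metabolite model spectra plus a low-order polynomial baseline that
stands in for broad lipid/macromolecule contributions:

    y(ppm) = sum_m c_m * B_m(ppm) + baseline(ppm) + noise,   c_m >= 0

Model spectra are sums of Lorentzian lines, each normalized to unit
integrated area so coefficients are directly comparable across metabolites.
Per-metabolite uncertainty is reported as a percent standard deviation from
the linear-model coefficient covariance (an analogue of the Cramér-Rao-style
%SD that dedicated packages print); metabolites with %SD >= 20 are excluded
from the final analysis, and concentrations are reported as ratios to total
creatine (PCr + Cr).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, nnls

__all__ = [
    "BasisSet",
    "Spectrum",
    "SpectrumFit",
    "DEFAULT_BASIS_LINES",
    "build_basis",
    "default_basis",
    "simulate_spectrum",
    "fit_spectrum",
    "ratios_table",
    "PERCENT_SD_CUTOFF",
]

PERCENT_SD_CUTOFF = 20.0
CHOLINE_POOL = ("Cho", "GPC", "PCh")

# Standard literature chemical shifts (ppm); entries are
# (shift_ppm, relative_amplitude, linewidth_hz).  Doublets are encoded as
# two lines split by a ~7 Hz J-coupling at 500.13 MHz (0.014 ppm).
DEFAULT_BASIS_LINES: dict[str, list[tuple[float, float, float]]] = {
    "NAA": [(2.01, 3.0, 1.5)],
    "Cr": [(3.03, 3.0, 1.5), (3.93, 2.0, 1.5)],
    "PCr": [(3.03, 3.0, 1.5), (3.94, 2.0, 1.5)],
    "Cho": [(3.19, 9.0, 1.5)],
    "GPC": [(3.21, 9.0, 1.5)],
    "PCh": [(3.22, 9.0, 1.5)],
    "mI": [(3.52, 4.0, 1.5), (3.61, 2.0, 1.5)],
    "Tau": [(3.25, 2.0, 1.5), (3.42, 2.0, 1.5)],
    "Ala": [(1.463, 1.5, 1.5), (1.477, 1.5, 1.5)],
    "Lac": [(1.303, 1.5, 1.5), (1.317, 1.5, 1.5), (4.10, 1.0, 1.5)],
}


@dataclass
class BasisSet:
    """Model spectra on a shared ppm grid, unit integrated area each."""

    ppm: np.ndarray  # ascending
    names: list[str]
    spectra: np.ndarray  # (n_points, n_metabolites)
    frequency_mhz: float = 500.13

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate metabolite names in basis")
        if self.spectra.shape != (self.ppm.size, len(self.names)):
            raise ValueError("basis spectra shape does not match grid/names")
        if "Cr" not in self.names or "PCr" not in self.names:
            raise ValueError("basis must include Cr and PCr (the normalization reference)")

    def column(self, name: str) -> np.ndarray:
        return self.spectra[:, self.names.index(name)]

    def gram_condition(self, names: tuple[str, ...] = CHOLINE_POOL) -> float:
        """Condition number of the Gram matrix of a metabolite subset."""
        cols = [self.names.index(n) for n in names if n in self.names]
        if len(cols) < 2:
            return 1.0
        B = self.spectra[:, cols]
        return float(np.linalg.cond(B.T @ B))


@dataclass
class Spectrum:
    """A 1D spectrum on a ppm axis with acquisition metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    te_ms: float = 36.0
    sample_id: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be matching 1D arrays")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")


@dataclass
class SpectrumFit:
    """Result of one linear-combination fit."""

    names: list[str]
    coefficients: np.ndarray  # c_m >= 0
    percent_sd: np.ndarray
    included: np.ndarray  # bool, percent_sd < cutoff
    residual_norm: float
    baseline_coefficients: np.ndarray
    total_creatine: float
    valid: bool
    ill_conditioned: bool = False
    sample_id: str = ""
    region: str = ""
    te_ms: float = 36.0

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def ratio(self, name: str) -> float:
        """Coefficient over total creatine; NaN when the fit is invalid."""
        if not self.valid:
            return float("nan")
        return self.coefficient(name) / self.total_creatine

    @property
    def ratios(self) -> dict[str, float]:
        """Creatine-normalized ratios of the included metabolites."""
        if not self.valid:
            return {}
        return {
            n: float(c / self.total_creatine)
            for n, c, inc in zip(self.names, self.coefficients, self.included)
            if inc and n not in ("Cr", "PCr")
        }

    def choline_pool_ratio(self) -> float:
        """Composite Cho + GPC + PCh over total creatine (always reported:
        the sum is well-conditioned even when the members are not)."""
        if not self.valid:
            return float("nan")
        total = sum(self.coefficient(n) for n in CHOLINE_POOL if n in self.names)
        return total / self.total_creatine


def _lorentzian(ppm: np.ndarray, center: float, fwhm_ppm: float) -> np.ndarray:
    gamma = fwhm_ppm / 2.0
    return (gamma / np.pi) / ((ppm - center) ** 2 + gamma ** 2)


def build_basis(
    lines: dict[str, list[tuple[float, float, float]]],
    ppm_range: tuple[float, float] = (0.5, 4.5),
    n_points: int = 8192,
    frequency_mhz: float = 500.13,
) -> BasisSet:
    """Synthesize unit-area Lorentzian model spectra on a shared ppm grid.

    ``lines`` maps metabolite name to (shift ppm, relative amplitude,
    linewidth Hz) entries; linewidths are converted to ppm through the
    spectrometer frequency.
    """
    if not lines:
        raise ValueError("basis configuration is empty")
    ppm = np.linspace(ppm_range[0], ppm_range[1], n_points)
    names, cols = [], []
    for name, entries in lines.items():
        if name in names:
            raise ValueError(f"duplicate metabolite {name!r}")
        spec = np.zeros_like(ppm)
        for shift, amplitude, width_hz in entries:
            if width_hz <= 0 or amplitude < 0:
                raise ValueError(f"{name}: line width must be > 0 and amplitude >= 0")
            spec += amplitude * _lorentzian(ppm, shift, width_hz / frequency_mhz)
        area = np.trapezoid(spec, ppm)
        if area <= 0:
            raise ValueError(f"{name}: basis spectrum has non-positive area")
        names.append(name)
        cols.append(spec / area)
    return BasisSet(ppm, names, np.column_stack(cols), frequency_mhz)


def default_basis(**kwargs) -> BasisSet:
    """The built-in brain-metabolite basis (config-editable via build_basis)."""
    return build_basis(DEFAULT_BASIS_LINES, **kwargs)


def simulate_spectrum(
    metabolite_ratios: dict[str, float],
    basis: BasisSet,
    noise_sigma: float = 0.0,
    seed: int = 0,
    pcr_fraction: float = 0.5,
    te_ms: float = 36.0,
    sample_id: str = "",
    region: str = "",
) -> Spectrum:
    """Forward model of the linear-combination fit.

    ``metabolite_ratios`` are concentrations relative to total creatine;
    PCr + Cr is set to 1 (split ``pcr_fraction`` / 1 - ``pcr_fraction``) so
    ratios act as absolute coefficients.  Noise is additive Gaussian.
    """
    unknown = sorted(set(metabolite_ratios) - set(basis.names))
    if unknown:
        raise ValueError(f"unknown metabolites {unknown}; basis knows {basis.names}")
    coeffs = dict(metabolite_ratios)
    coeffs.setdefault("PCr", pcr_fraction)
    coeffs.setdefault("Cr", 1.0 - pcr_fraction)
    y = np.zeros_like(basis.ppm)
    for name, c in coeffs.items():
        if c < 0:
            raise ValueError(f"{name}: ratio must be >= 0")
        y += c * basis.column(name)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, y.shape)
    return Spectrum(basis.ppm, y, te_ms=te_ms, sample_id=sample_id, region=region)


def fit_spectrum(
    spectrum: Spectrum,
    basis: BasisSet,
    baseline_order: int = 2,
    sd_cutoff: float = PERCENT_SD_CUTOFF,
    condition_limit: float = 1e6,
) -> SpectrumFit:
    """Non-negative linear-combination fit with a polynomial baseline.

    Metabolite coefficients are constrained >= 0; the ``baseline_order + 1``
    Legendre baseline terms (the lipid/macromolecule stand-in) are
    unconstrained.  %SD per metabolite comes from the residual-variance
    estimate times the diagonal of the inverted normal matrix, as
    100 * sd(c_m) / c_m; metabolites at %SD >= ``sd_cutoff`` are excluded.
    A fit with zero total creatine is flagged invalid (ratios undefined).
    """
    if spectrum.ppm.shape != basis.ppm.shape or not np.allclose(spectrum.ppm, basis.ppm):
        raise ValueError("spectrum and basis must share the same ppm grid")
    n_met = len(basis.names)
    x = np.linspace(-1.0, 1.0, basis.ppm.size)
    baseline_cols = np.polynomial.legendre.legvander(x, baseline_order) if baseline_order >= 0 else np.empty((x.size, 0))
    A = np.column_stack([basis.spectra, baseline_cols])
    y = spectrum.intensity

    if baseline_cols.shape[1] == 0:
        coef, _ = nnls(A, y)
    else:
        lo = np.concatenate([np.zeros(n_met), np.full(baseline_cols.shape[1], -np.inf)])
        hi = np.full(A.shape[1], np.inf)
        res = lsq_linear(A, y, bounds=(lo, hi), tol=1e-14)
        coef = res.x
        coef[:n_met] = np.clip(coef[:n_met], 0.0, None)
    c_met = coef[:n_met]
    resid = y - A @ coef
    residual_norm = float(np.linalg.norm(resid))

    # linear-model covariance of the coefficients (constraints ignored)
    dof = max(y.size - A.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    try:
        cov = sigma2 * np.linalg.inv(A.T @ A)
        coef_sd = np.sqrt(np.clip(np.diag(cov)[:n_met], 0.0, None))
    except np.linalg.LinAlgError:
        coef_sd = np.full(n_met, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        percent_sd = 100.0 * coef_sd / c_met
    percent_sd = np.where(c_met > 0, percent_sd, np.inf)

    included = percent_sd < sd_cutoff
    total_cr = float(c_met[basis.names.index("Cr")] + c_met[basis.names.index("PCr")])
    valid = total_cr > 0
    ill = basis.gram_condition() > condition_limit

    return SpectrumFit(
        names=list(basis.names),
        coefficients=c_met,
        percent_sd=percent_sd,
        included=included,
        residual_norm=residual_norm,
        baseline_coefficients=coef[n_met:],
        total_creatine=total_cr,
        valid=valid,
        ill_conditioned=ill,
        sample_id=spectrum.sample_id,
        region=spectrum.region,
        te_ms=spectrum.te_ms,
    )


def ratios_table(fits: list[SpectrumFit], groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy table of creatine-normalized ratios across fits.

    One row per included metabolite per fit, plus one composite
    ``Cho+GPC+PCh`` row per fit (sum of the three coefficients over total
    creatine).  ``groups`` optionally maps sample id to group name.
    """
    groups = groups or {}
    rows = []
    for fit in fits:
        if not fit.valid:
            continue
        for name, c, psd, inc in zip(fit.names, fit.coefficients, fit.percent_sd, fit.included):
            if name in ("Cr", "PCr"):
                continue
            rows.append(
                dict(
                    sample=fit.sample_id,
                    group=groups.get(fit.sample_id, ""),
                    region=fit.region,
                    te_ms=fit.te_ms,
                    metabolite=name,
                    ratio=float(c / fit.total_creatine),
                    percent_sd=float(psd),
                    included=bool(inc),
                )
            )
        rows.append(
            dict(
                sample=fit.sample_id,
                group=groups.get(fit.sample_id, ""),
                region=fit.region,
                te_ms=fit.te_ms,
                metabolite="Cho+GPC+PCh",
                ratio=fit.choline_pool_ratio(),
                percent_sd=float("nan"),
                included=True,
            )
        )
    return pd.DataFrame(rows)
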