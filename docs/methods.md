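# Methods

## Scope and design

`mparamap` implements the quantitative computation behind a multiparametric
MRI + ex vivo MRS characterization of a rat glioblastoma model: pixelwise
relaxometry (T₂, T₂*, T₁), magnetization-transfer-ratio (MTR) mapping,
diffusion-tensor estimation with MD/FA, ROI statistics and tumor
volumetry, linear-combination metabolite quantification, and the group
statistics that compare tumor/ipsilateral against contralateral regions in
tumor-bearing and sham animals. Since no acquired data accompany such
desk-scale studies, a first-class synthetic-phantom module provides every
input with known ground truth; the package's validation strategy is
round-trip closure: *simulate with parameter θ, fit, recover θ*, exactly on
noiseless input.

## Phantom generator

The default phantom emulates the parametric acquisition geometry of a 7 T
rodent protocol: 64×64 pixels per slice at 0.2734 mm in-plane, five slices
of 1.5 mm, a disc-shaped tumor in one hemisphere and a mirrored
contralateral disc (equal size; region masks are disjoint by
construction). Each region carries T₂, T₂*, T₁ (ms), MTR (%), MD (µm²/s),
FA, an S₀ scale, and metabolite ratios relative to total creatine. The
built-in reference values (`phantom.c6_study_regions`) are group means for
an advanced-stage C6 glioma model and its sham counterpart, e.g. tumor
T₂ = 66.52 ms, MTR = 15.15 %, MD = 1064 µm²/s versus contralateral
51.26 ms, 30.56 %, 816 µm²/s.

Forward models are the textbook signal equations (mono-exponential decay,
saturation recovery, MT attenuation, mono-exponential tensor attenuation).
Acquisition grids follow the protocol's stated counts and ranges; where
only endpoints are published the spacing is a design choice: 75 echoes
evenly spaced 12–900 ms and 20 echoes evenly spaced 2.73–83.86 ms (even
spacing matches multi-echo hardware convention), and TRs
{125, 250, 500, 1000, 1500, 2500, 4000, 6000} ms (log-ish spacing for
conditioning across the stated 125–6000 ms range). The seven diffusion
directions are the three axes, three face diagonals and the body diagonal,
normalized — any non-degenerate 7-direction set is valid and the scheme is
an input. Nominal b-values (0, 300, 1400 s/mm²) are used as-is; gradient
timings (δ = 4 ms, Δ = 20 ms) are carried as metadata only.

The per-pixel tensor is constructed from (MD, FA) as an axially symmetric
prolate tensor: with r = λ∥/λ⊥, FA = (r−1)/√(r²+2), inverted in closed
form as r = (1 + FA·√(3−2FA²))/(1−FA²), then rotated to the region's
principal axis. Image noise is Rician — M = √((S+n₁)² + n₂²) with
n ~ N(0, σ²) — reflecting magnitude reconstruction; spectra receive
additive Gaussian noise (phased 1D spectra). All stochastic output is
bit-reproducible under the spec's seed.

The per-animal sampler (`phantom.simulate_study_values`) draws region
values as Normal(group mean, SEM·√n) with n = 10 tumor-bearing and 4 sham
animals, so each simulated cell's sample mean has the reported standard
error. The PCr/Cr split is 0.5/0.5 by default; only their sum is
identified by the creatine normalization.

What the phantom does **not** model: Bloch-equation/pulse-sequence
physics, partial volume, motion, B₀/B₁ inhomogeneity, slice profiles,
k-space reconstruction, J-modulation or T₂ weighting of the spectral basis
(TE 36 vs 144 ms is metadata only). Passing round-trip tests therefore
demonstrates correctness of the estimators under the stated signal models,
not robustness to acquisition artifacts present in real data.

## Relaxometry

`S(TE) = S₀·e^(−TE/T)` and `S(TR) = S₀·(1−e^(−TR/T₁))` are fitted per
pixel by bounded trust-region nonlinear least squares. Initialization is
analytic: log-linear regression on the positive samples for the decay
models; S₀ ← max(S) and the TR nearest 63.2 % recovery for T₁. Bounds
encode physical plausibility at 7 T — T₂ ∈ [1, 2000] ms,
T₂* ∈ [0.5, 500] ms, T₁ ∈ [50, 10000] ms; degenerate inputs (constant
signal) land on a bound rather than erroring, and pixels with fewer than
two usable points carry the NaN sentinel and are counted, not raised. No
constant-offset term is fitted (the signal equations are used literally)
and no Rician noise-floor correction is applied. The latter is a known
limitation: with echoes extending to ~13×T₂, the late echoes sit on the
noise floor σ√(π/2) and bias fitted T₂ upward by ~3 % at σ = S₀/50; the
test suite asserts this bias is positive and below 5 % rather than
pretending it is absent. Background masking (when no mask is given)
excludes pixels whose mean signal is below 5 % of the series' robust
maximum.

## MTR

`MTR% = 100·(S₀ − S_MT)/S₀`. Noise-driven negative values are retained by
default so ROI means stay unbiased; a `clip` option restricts to
[0, 100] %. Pixels with S₀ = 0 inside the mask become sentinels with a
logged count.

## Diffusion

The log-linear design has columns (−b·gₓ², −b·g_y², −b·g_z², −2b·gₓg_y,
−2b·gₓg_z, −2b·g_yg_z, 1); one OLS solve per pixel estimates the six
tensor elements and ln S₀ from all 15 volumes (the b = 0 row enters
through the intercept). Weighted least squares and positivity constraints
are deliberately omitted (ordinary LS is the transparent baseline; the
estimator is exact on noiseless data). Non-positive diffusion-weighted
samples are dropped per pixel (minimum 7 usable rows, else sentinel);
non-positive b = 0 pixels are unfittable. Eigenvalues are sorted
descending and clamped at zero before FA, with a per-map clamp count —
this prevents FA > 1 artifacts at the cost of a small bias in heavily
clipped pixels. Tensors are held in mm²/s; MD maps are reported in µm²/s.
Under Rician noise the eigenvalue-sorting bias inflates FA; the suite
asserts this direction explicitly.

## ROI statistics and volumetry

Per-animal region summaries pool pixels across all selected slices before
averaging (not a mean of per-slice means — the two differ whenever slice
areas differ, and the pooled convention is asserted by test). Tumor volume
is (Σ slice areas)·ST; areas are pixel counts × pixel area, so a
rasterized ~10-pixel-radius disc reproduces the analytic πr² volume to
within ~2 % pixel-quantization error.

## MRS quantification

Basis spectra are sums of Lorentzian lines at standard literature shifts
(NAA 2.01; Cr 3.03/3.93; PCr 3.03/3.94; Cho 3.19; GPC 3.21; PCh 3.22;
mI 3.52/3.61; Tau 3.25/3.42; Ala 1.47 doublet; Lac 1.31 doublet + 4.10
ppm), default width 1.5 Hz at 500.13 MHz, each normalized to unit
integrated area on a shared grid (0.5–4.5 ppm, 8192 points) so
coefficients are directly comparable. The fit solves a bounded linear
least-squares problem: metabolite coefficients ≥ 0, plus an unconstrained
Legendre baseline (default order 2) standing in for broad
lipid/macromolecule contributions; order −1 disables the baseline and
order 0 is used for exact-recovery checks. The %SD per metabolite is
100·sd(c)/c with sd from the residual-variance estimate times the inverted
normal matrix — a linear-model analogue of the Cramér–Rao-style SD that
dedicated linear-combination packages report, not a clone of any of them.
Metabolites at %SD ≥ 20 are excluded from the final ratios; zero total
creatine invalidates the fit. The Cho/GPC/PCh members lie 0.01–0.03 ppm
apart: at the default 1.5 Hz width they are resolved, but the fit flags
the basis ill-conditioned when the choline-pool Gram condition number
exceeds a configurable limit, and the composite Cho+GPC+PCh sum is always
reported (the sum stays well-conditioned under overlap).

## Group statistics

The emulated design is 10 GBM vs 4 sham animals × 2 regions. Per
parameter: Shapiro–Wilk normality; a two-way (group × region) ANOVA over
the four cells using Type II sums of squares (appropriate for the
unbalanced design; Type III available via argument); Tukey HSD over the
four cell means (family-wise adjusted); and a within-group paired t-test
with Holm–Šidák step-down adjustment — adjᵢ = 1−(1−pᵢ)^(m−i) over the
ascending-sorted family, monotonicity enforced — across whatever parameter
family is passed in one call. Significance is α = 0.05. Boxplot summaries
use linear-interpolation quartiles (the common default; conventions
differ) and 1.5×IQR whiskers.

Two statistical behaviors worth stating plainly. First, because the sham
ipsilateral and contralateral reference means differ slightly, the paired
sham comparison is a *near*-null: its rejection rate is ~7 % rather than
exactly α, which is the honest behavior of a paired test under a small
true shift. The reproducibility check for the study's qualitative pattern
(tumor different from every other region, sham regions not different)
therefore uses the Tukey family at α = 0.05, where the pattern reproduces
in ≥ 95 % of simulated studies. Second, under a true null the ANOVA group
effect's type-I error is calibrated at the nominal 5 % (Monte-Carlo,
seeded, 1000 studies).

## Problem sizes and numerics

Default test/validation sizes: the full 64×64×5 phantom (≈1560 pixels per
ROI) for round trips; reduced 20–32 px grids for the end-to-end pipeline
tests; 200 simulated studies for the pattern check and 1000 for type-I
calibration; 50 noisy spectra for the MRS Monte-Carlo (σ = 1 in basis
units, peak SNR ≈ 150, typical of ex vivo HRMAS). Nonlinear fits run at
xtol = ftol = gtol = 1e−14 so noiseless round trips close to ≤1e−6
relative; tie-breaks and degenerate inputs (constant signal, zero
spectrum, all-zero tensor) resolve to bounds, invalid flags, or zero maps
as described above rather than exceptions.

## Known limitations

- No Rician-bias handling anywhere in fitting (documented bias above).
- Mono-exponential relaxometry and single-tensor diffusion only; no
  multi-compartment, stretched-exponential, or kurtosis models.
- The spectral basis is synthetic (Lorentzian singlets/doublets), not a
  measured metabolite database; quantification is validated against its
  own forward model, not against acquired spectra.
- Region ANOVA treats cells as independent; the within-animal pairing is
  carried by the paired t-test, not by a repeated-measures model.
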