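# Methods

This note documents the models, estimators, and design choices behind
`cmscortex`, and what the synthetic-data experiments do and do not establish.

## Acquisition model

All d-MRI computations assume the ex-vivo multi-shell protocol: 14 shell
b-values (0, 0.5, 1.0, …, 4.5, 5.0, 6.0, 7.0, 8.0 ms/μm²) with one fixed set
of 12 gradient directions shared by every shell, 250 μm isotropic voxels,
Δ/δ = 15/5 ms. The direction set itself is not part of the published
acquisition table, so the package ships a frozen 12-direction
electrostatic-repulsion scheme (antipodally symmetrized Coulomb energy
minimized from a fixed start; minimum pairwise angle 38.1°). Any b-table in
s/mm² is auto-detected (`max(b) ≥ 100`) and converted to the canonical
ms/μm². All b=0 frames are averaged into a single effective measurement
before fitting; this is order-independent and strictly reduces noise.

## Diffusion tensor (MD, FA)

Weighted linear least squares on the log-signal with square-root weights
equal to the (first observed, then predicted) signal and one refinement
pass. MD = (λ₁+λ₂+λ₃)/3; FA is the standard normalized eigenvalue-dispersion
form, clamped to [0, 1], with FA := 0 when MD < 1e-6 μm²/ms to avoid 0/0.
Negative eigenvalues are allowed but flagged. Axial/radial diffusivities are
computed internally but not reported. By default the pipeline's MD/FA come
from the joint kurtosis fit (b ≤ 4.5 ms/μm²); `fit_dti` with its own
`b_max` (default 1.0 ms/μm²) is available for a pure-DTI analysis.

## Kurtosis tensor (MK, AK, RK, MKT, W_L, W_T)

Signal model (MD²-normalized convention):
`ln S = ln S0 − b·D(n) + (b²/6)·MD²·Ŵ(n)`, with
`K_app(n) = MD²·Ŵ(n)/D(n)²`. The fit uses the shells with b ≤ 4.5 ms/μm²: a
log-linear solve in the variables (ln S0, D, U = MD²·W) — in which the model
is exactly linear — followed by Levenberg–Marquardt on the signal domain.
No positivity or 0 ≤ K ≤ 3 constraints are imposed (plain NLLS, with a
convergence flag); optional clamping is left to downstream configuration.

**Identifiability with 12 directions.** The 15-component kurtosis tensor is
sampled through at most 12 independent directional evaluations, so a
3-dimensional null space of the design remains. Two measures keep this
deterministic and exact in the limits that matter:

1. the nonlinear refinement is parametrized inside the row space of the
   design (the null component cannot move during optimization), and
2. the null component is then fixed by minimizing the rotation-invariant
   anisotropy seminorm of W (the norm of the component orthogonal to the
   isotropic rank-4 tensor `sym(δ⊗δ)` under the multiplicity-weighted inner
   product).

Consequences: Gaussian ground truths give exactly W = 0; isotropic ground
truths are recovered exactly (the zero-anisotropy representative consistent
with the data is unique); a generic anisotropic W is recovered only up to
the unidentifiable subspace, and refitting a fit's own forward signal
reproduces the fit to machine precision. The diffusion tensor itself is
fully identifiable (6 ≤ 12). Scalar contractions of a generic W (including
MKT) inherit a small representative-dependence; with ≥ 15 well-spread
directions the design has full rank and the convention becomes inert.

Metrics: MK is the spherical mean of K_app on a Gauss–Legendre × uniform
azimuth product rule (32 × 64; exact far beyond the degree-4 integrands, and
the smooth K_app ratio converges spectrally); AK is K_app along the
principal diffusion axis; RK the azimuthal mean of K_app in the
perpendicular plane (64-point trapezoid, exact for the degree-4
trigonometric polynomial part). In the eigenframe of D:
MKT = (1/5)[W′₁₁₁₁+W′₂₂₂₂+W′₃₃₃₃+2(W′₁₁₂₂+W′₁₁₃₃+W′₂₂₃₃)], W_L = W′₁₁₁₁,
W_T = (3/8)[W′₂₂₂₂+W′₃₃₃₃+2W′₂₂₃₃]. Eigenvalues are sorted descending; at a
degenerate leading pair (λ₁−λ₂ < 1e-9) the axis with the larger |z|
component is taken, and every eigenvector's sign is fixed so its
largest-magnitude entry is positive.

**Two-site mixture check.** A non-exchanging isotropic mixture
f·e^{−bD₁} + (1−f)·e^{−bD₂} has cumulant-expansion kurtosis
K = 3·Var(D)/E[D]²; for f = 0.5, D = (0.5, 1.5) μm²/ms this is 0.75. The
package validates the fit chain on signals generated from this cumulant
pair (MD = 1, K = 0.75), which the fit recovers to ~1e-9. Fitting the *raw*
bi-exponential over the full b ≤ 4.5 range instead gives MK ≈ 0.48: the
mixture's fourth cumulant is negative, so the truncated quadratic-in-b model
absorbs higher-order curvature and is biased below the b→0 kurtosis. A unit
test pins this qualitative behavior (0 < MK < 0.75).

## Two-compartment neurite-density model (Neu, D_L, D_eff)

`S(b,g) = S0·[ν·∫f(n)e^{−b·D_L·(g·n)²}dn + (1−ν)·e^{−b·D_eff}]`: a stick
intra-neurite compartment (zero transverse diffusivity) with longitudinal
diffusivity D_L, dispersed by an ODF f expanded in even real spherical
harmonics (order 4 by default, 15 coefficients, l=0 fixed by normalization;
order 2/0 fallbacks for reduced protocols or isotropic phantoms), and an
isotropic Gaussian extra-neurite compartment with a *free* scalar D_eff — no
fixed-diffusivity (NODDI-style) constraint. The orientation integral uses
the Funk–Hecke theorem; the stick kernel's Legendre band factors
λ_l(u) = 2π∫e^{−ut²}P_l(t)dt come from 64-point Gauss–Legendre quadrature
(the isotropic limit reproduces the closed-form powder average
√(π/4bD_L)·erf(√(bD_L)) to 1e-15). "Neurite density" ν is the T2-weighted
signal fraction, not a volume fraction.

Fitting: Levenberg–Marquardt on the magnitude signal over all 14 shells,
analytic Jacobian, with bounds enforced by reparametrization
(ν = expit(x), diffusivities = 3·expit(x) μm²/ms — an ex-vivo ceiling — and
S0 = eˣ), multi-started from a 3×3×3 grid ν ∈ {0.2, 0.5, 0.8},
D_L ∈ {0.5, 1.0, 1.5}, D_eff ∈ {0.3, 0.7, 1.1} μm²/ms (2×2×2 in the
isotropic pipeline mode); the lowest-RSS start wins. ODF coefficients are
initialized isotropic and left unconstrained; no ODF non-negativity is
imposed. The noise model in the objective is Gaussian on magnitude data; an
optional expected-magnitude (Rician floor) variant exists but is off by
default. A fit is flagged non-identifiable when ν < 0.02 or ν > 0.98 or the
Jacobian is rank-deficient at the optimum.

Verified behavior: noiseless `fit(forward(θ)) = θ` to ≤ 2 % relative (in
practice ~1e-12) over a 100-point Latin hypercube of admissible truths
(ν ∈ [0.05, 0.95], D_L ∈ [0.5, 2], D_eff ∈ [0.2, 1.5], Watson κ ∈ [2, 10],
random orientation); at SNR 50 with Rician noise, 200 replicates keep the
median ν within ±0.05 and median D_eff within ±0.1 μm²/ms of truth (the
small upward ν bias is the familiar magnitude-noise floor effect).

## ROI aggregation and group inference

Parameter maps are aggregated per animal × ROI × metric as the mean over
valid (fitted, finite) voxels of each slice in the configured half-open
slice window — the slice is the replicate unit for d-MRI (the section plays
that role for histology). The replicate structure per animal is not part of
the published design, so it is configurable; the synthetic default is 3
slices.

Inference per metric × ROI: REML fit of
`value ~ group + (1 | animal)` via profiling the variance ratio θ = τ²/σ²
(the block structure of I + θZZᵀ is inverted in closed form, making the
profiled objective a fast scalar function optimized by bounded Brent to
1e-12). The overall group test is an F-test on the two group contrasts;
denominator df by the Satterthwaite method — per-contrast
df = 2v²/(∇vᵀA∇v) with A the inverse numeric REML information in (σ², τ²),
combined across the eigendirections of the contrast covariance. In balanced
designs this reproduces the one-way ANOVA on animal means exactly
(F to ~1e-9, df = N_animals − groups), and on unbalanced data it matches R's
lmerTest to ~1e-5 (F) and ~1e-2 % (df). When τ̂² hits the boundary (or each
animal has a single observation) the model degrades to a flagged
fixed-effects ANOVA. Type-I error over 2000 balanced null simulations is
≈ 0.05 (within [0.035, 0.065]).

Post hocs run only if the overall F is significant at α = 0.05: pairwise
contrasts with Satterthwaite-df t-tests, Benjamini–Hochberg adjustment
within the 3-contrast family of each metric × ROI (family definition
configurable).

**Group-mean CIs.** Reported group means carry *descriptive* 95 %
t-intervals computed from each group's animal-level means with the group's
own SD. A pooled-variance model-based interval has width determined by group
size alone and cannot display the between-group heterogeneity that is a
finding of interest in this paradigm (stress groups more dispersed); the
descriptive interval preserves it. Model-based estimates remain available on
the result object.

## Histology quantification

Density chain (identical for NF-H/axonal and MAP2/dendritic, which differ
only in their configuration profile): luminosity scaling divides channels by
the white reference (99th-percentile luminance of the brightest pixel
decile — the unstained background), stain intensity = 1 − scaled luminance
of the channel combination (equal weights by default), 1st–99th percentile
contrast stretch to [0, 1]; batch mode computes the white reference and
stretch globally so every image gets identical settings. Thresholding is at
30 % of the per-image post-enhancement signal range (the only reading of
"30 % relative to the signal level" well defined on normalized images; the
threshold is echoed in reports). Soma removal: 8-connected components are
hole-filled (nuclear counterstain), then components with eccentricity ≤ 0.85
and equivalent diameter 6–25 μm (and ≥ 20 px) are classified as cell bodies
and subtracted; the bounds are declared defaults spanning typical neuronal
soma sizes, all config-exposed. Density [%] = remaining foreground pixels /
total image pixels × 100. Pixel conservation (process + body ∩ foreground =
foreground) holds exactly by construction.

Cortical thickness is the Euclidean endpoint distance of annotation lines
(ImageJ-style CSV: image, roi, x1, y1, x2, y2) × μm/pixel, grouped per ROI
and montage; fewer than 3 montages × 5 lines per ROI warns (protocol
shortfall) without failing.

## Synthetic-data generators

All generators are pure functions of (spec, seed).

*d-MRI voxels*: noiseless signals from either forward model; Rician noise is
the magnitude of signal + complex Gaussian with per-channel SD S0/SNR
(SNR 50 at b=0 is the working regime).

*Cohort*: groups of 8 control / 7 anhedonic / 8 resilient animals (the
post-exclusion sizes), hierarchical draws — animal effect ~ N(0, between-SD),
replicate = group mean + animal effect + N(0, within-SD), with both SDs
multiplied by 1.5 in the stress groups (variance inflation). The default
effect template encodes only the qualitative finding structure: AC D_eff
0.60 (control) vs 0.48 μm²/ms (both stress groups, between/within SD 0.03);
MC FA higher in the resilient group; MC axonal density higher (8 → 10 %) and
cortical thickness lower (1800 → ~1650 μm) in stress groups; all other
cells flat or sub-threshold. Magnitudes are package choices — the source
figures print no numeric effect sizes — and are fully configurable. In map
mode the AC D_eff effect is planted at the signal level: per animal, 3
slices × 2 voxels simulated from the neurite forward model (ν = 0.4,
D_L = 1.2, isotropic ODF) at SNR 50, so the entire
fit → aggregate → LMM → FDR chain runs; 100 such runs take a few minutes,
which is why the per-animal volumes are miniatures. With these study
conditions the planted effect is detected (both control-vs-stress contrasts
FDR-significant) in ≈ 100 % of runs, and the mean stress-group CI is wider
than control's in > 90 % of runs.

*Micrographs*: white background, dark quasi-circular somata (default 10, 12–18
μm diameter, mutually non-overlapping), and long gently-curving thin strokes
(0.6–1.2 μm wide random walks) painted until the requested area fraction
(default 8 %) is reached; strokes keep a margin away from somata so the
planted inventory stays exact under connected-component analysis (non-overlap
bookkeeping by construction). Truth records the exact rendered pixel fractions.
The deliberately clean morphology means the recovery tests validate the
*chain logic* (enhancement, thresholding, shape filtering, bookkeeping), not
performance on real DAB tissue with touching structures, stain gradients, or
out-of-focus blur.

*Thickness montages*: a sinusoidal pial boundary (amplitude = undulation
fraction × thickness) with the white-matter boundary as its normal offset;
the five annotation lines per ROI run along the local pial normal with float
endpoints, so flat bands measure exactly and undulating bands stay within
the amplitude bound.

## Numerical choices and degenerate inputs

- SVD rank tolerance for the kurtosis design: 1e-10 relative (the null
  space is structural, singular values ~1e-15).
- Shell clustering tolerance 1e-6 ms/μm²; b=0 tolerance 1e-9.
- REML boundary: θ < 1e-7 → flagged fixed-effects degradation.
- Zero-range images skip enhancement with a warning and binarize to empty.
- Zero-length annotation lines are skipped with a warning.
- Voxels with any non-positive raw frame are excluded from tensor fits
  (checked before b=0 averaging); kurtosis fitting drops non-positive
  measurements and requires ≥ 22 usable ones per voxel.

## Known limitations

- With the 12-direction scheme, anisotropic kurtosis metrics (AK, RK, W_L,
  W_T) depend on the min-anisotropy null-space convention; they are exact
  only for isotropic/Gaussian ground truths. This mirrors a genuine limit of
  the acquisition, not of the implementation.
- The histology generators do not emulate realistic tissue texture; density
  recovery tolerances (±1.5 points) reflect clean-field conditions.
- The cohort emulation fixes effect magnitudes by choice; power numbers are
  statements about the synthetic conditions, not about the animal study.
- Exchange between compartments, ODF non-negativity constraints, and
  WMTI-style white-matter modelling are out of scope.
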