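# Methods

## The model

A multi-echo spin-echo (CPMG-type) acquisition samples the transverse decay
of brain water at 32 equally spaced echoes, TE = 10…320 ms, TR = 1000 ms. In
tissue the decay is multi-exponential: a short-T2 pool from water trapped in
myelin bilayers (T2 ≈ 10–40 ms), an intermediate intra/extracellular pool
(IEw, T2 ≈ 60–140 ms in the regions of interest), and a long-T2
fluid/CSF pool. The voxel signal is modeled as

    y_k = Σ_j x_j · A_k(T2_j, T1, α),    x_j ≥ 0,

where the dictionary column A(·, T2_j) is the EPG (extended phase graph)
echo train of a pure pool with time constant T2_j under refocusing flip
angle α. When α < 180°, part of the transverse magnetization is stored
longitudinally between pulses and recalled later as stimulated echoes; the
EPG recursion (relax τ → shift → rotate α → shift → relax τ per inter-echo
interval, with τ = ESP/2 and crusher-induced integer dephasing orders up to
the echo-train length) accounts for this exactly. At α = 180° every column
reduces to exp(−TE/T2).

Model conventions:

* T1 of all pools is fixed at 1000 ms (configurable). Over a 320 ms train
  the fit is insensitive to T1, so a single constant is adequate.
* Stored longitudinal states relax with T1 but do not regrow toward
  equilibrium during the train; the signal source is solely the excited
  magnetization. The isochromat (Bloch) oracle used in the tests integrates
  the same relaxation model spin by spin, so EPG and oracle are two
  independent implementations of one physical model (they agree to ~1e−15;
  the acceptance bound is 0.1%).
* Excitation is an ideal 90° on the refocusing axis (CPMG condition);
  B1 error is a single per-voxel scalar α, with no slice-profile modeling.

## Spectrum inversion

Each voxel's train is inverted on a 200-node logarithmic T2 grid over
[1, 3000] ms by non-negative least squares (scipy's NNLS), with a
minimum-curvature penalty:

    min_x ||A x − y||² + μ ||D₂ x||²,   x ≥ 0,

implemented by row augmentation of A with √μ·D₂. D₂ is the second-difference
operator along the (log-spaced) grid **with zero-padded (Dirichlet)
boundaries** (an n×n tridiagonal [1, −2, 1]). The boundary choice matters: with
interior-only rows, a linear ramp running into the grid edge has zero
curvature, and early-echo noise gets absorbed by huge-amplitude ramps at
sub-detectable T2 (a few ms) that destroy the compartment fractions.

μ is set by a discrepancy principle: the largest μ whose *data* misfit does
not exceed `misfit_inflation` (default χ = 1.02) times the unregularized
NNLS misfit, found by geometric bracketing and bisection on log μ (bracket
tolerance 10%; μ precision beyond that has no visible effect on the
spectrum). A floor of 1e−12·||y|| on the discrepancy target keeps noiseless
voxels (misfit at rounding level) well-posed. If bracketing fails within 60
iterations the fit falls back to μ = 0 with a logged warning.

### Flip-angle estimation

The refocusing angle is estimated per voxel by scanning the *unregularized*
NNLS misfit over a coarse angle grid (default 1° steps over [120°, 180°]),
refining the minimizer by quadratic interpolation through the best node and
its neighbors, then running the regularized fit at the refined angle.
Estimating the angle on the unregularized fit avoids regularization bias on
α and is cheaper. Ties (flat misfit, e.g. pure noise voxels) resolve to the
largest angle.

The angle scan runs on a reduced 40-node T2 grid whose shortest node is
0.8 × TE₁ (8 ms at the defaults). Grid nodes with T2 far below the first
echo time are invisible to the data but act as free absorbers that flatten
and bias the angle-misfit landscape: at SNR 200 the angle error spread
roughly halves (sd 1.9° → 1.2°) and multi-degree outliers disappear when
they are excluded from the *scan*. The final spectrum is always fitted on
the full 1–3000 ms grid.

### Known bias of the myelin fraction

The non-negativity constraint rectifies noise: a positive residual at the
first echoes can be absorbed by low-amplitude mass at sub-TE₁ grid nodes
(T2 ≈ 1–5 ms), while a negative residual cannot be compensated. This mass is
smooth (negligible curvature penalty) and genuinely reduces the misfit, so
minimum-curvature regularization cannot remove it at any weight — the
penalty budget is spent broadening the real peaks instead. The result is a
positive bias of a few percentage points in the myelin water fraction at
clinical SNR (the joint flip-angle fit absorbs part of it). The IEw
fraction and IEw weighted T2 — the quantitative readouts this pipeline is
built around — are unaffected; the myelin and CSF weighted-T2 maps are
produced but should be treated as unreliable (few echoes constrain T2 below
40 ms, and the train ends at 320 ms).

## Compartmentalization

Grid nodes are labeled myelin water (T2 < 40 ms), intra/extracellular water
(40 ms ≤ T2 ≤ 250 ms; both bounds inclusive — the default grid has no node
exactly on a bound, so this is a fixed convention) and CSF/free water
(T2 > 250 ms). Per pool the maps record the relative amplitude (fraction of
total spectral amplitude) and the amplitude-weighted mean T2, arithmetic in
linear ms by default; the geometric mean common elsewhere in the literature
is available via `t2_average="geometric"`. Out-of-mask and skipped voxels
are NaN in all maps. Each map set carries a JSON provenance sidecar (grid,
bounds, full configuration, noise-floor estimate).

## Volume pipeline

Stages, in order: (1) each echo volume is smoothed with a normalized 3-D
Gaussian kernel, sd 1.5 **voxels** (the protocol states the value without
units; voxels of the acquired grid is the recorded assumption,
configurable), reflect boundary, echo axis untouched; (2) the background
noise sd is estimated from out-of-mask voxels of the *unsmoothed* first echo
via the Rayleigh median (median = σ√(2 ln 2) — the median is robust to edge
voxels contaminated by partial tissue signal); voxels whose smoothed
first-echo magnitude falls below 5σ are skipped; (3) every remaining in-mask
voxel is fitted independently; (4) maps are assembled and written as float32
NIfTI-1 with the input affine. The pipeline is deterministic: identical
inputs and configuration give bit-identical maps, and voxel iteration order
does not influence any voxel's result (no state is shared between voxel
fits).

## Hyper-T2 segmentation and mismatch analysis

ROI T2 distributions are Gaussian kernel density estimates of the finite
IEw-T2 values, evaluated on a regular support over [40, 250] ms and
renormalized to unit integral. The default bandwidth is Silverman's rule
with a 5 ms floor. The floor is a robustness guard: when an ROI is nearly
homogeneous (phantom regions; its Silverman bandwidth then collapses well
below the ~2–5 ms voxelwise reproducibility of the fitted IEw T2), the
inside/outside density crossing degenerates to the edge of the narrow
sample's support rather than the balance point between the two populations.
Heterogeneous clinical-scale ROIs have Silverman bandwidths above the floor
and are unaffected. Bandwidth is configurable and recorded.

The segmentation threshold is the support point between the two modes where
the inside-GTV and outside-GTV densities cross (linear interpolation between
bracketing support points; with several crossings, the one nearest the
midpoint of the modes, with a warning). "Outside the GTV" defaults to all
brain-mask voxels with finite IEw T2 outside the GTV. Hyper-T2 voxels are
CTV voxels with IEw T2 *strictly greater* than the threshold; NaN is never
selected; volumes are converted to ml via the affine voxel size. The
mismatch report gives exclusive/overlap volumes and the Dice coefficient
against the FLAIR hyper-intensity mask. ROI distributions are additionally
summarized by the density mode and the adjusted Fisher–Pearson sample
skewness (affected regions show a mode shift toward higher T2 and positive
skew). A threshold fixed on one time point can be re-applied to later maps
by passing it explicitly.

## Synthetic phantom

The phantom generates what the analysis assumes and nothing more:

* **Geometry** — a centered ellipsoid "brain" (semi-axes 0.45 of each
  dimension) of white matter in a 24×24×12 volume of 2.5 mm isotropic
  voxels; a spherical lesion (radius 4 voxels); a FLAIR-positive mask = the
  concentric lesion core (radius 2.5), which also serves as the GTV; a CTV =
  GTV dilated by 4 voxels; a contralateral ROI mirrored across x. The shell
  of lesion outside the FLAIR core is the built-in "mismatch".
* **Tissue models** — white matter 12%/80%/8% at 20/80/1000 ms; lesion
  6%/86%/8% at 20/**110**/1000 ms, i.e. a +30 ms IEw elevation placing the
  lesion peak inside the 70–140 ms range where such alterations are
  observed.
* **Flip-angle field** — linear 180° → 160° along x, exercising per-voxel
  angle estimation.
* **Noise** — Rician: each magnitude is replaced by √((s+g₁)² + g₂²) with
  g ~ N(0, σ²) and σ = (tissue first-echo amplitude)/SNR, default SNR 200.
  TR-driven T1 saturation is folded into proton density (TR is fixed
  in-protocol).

What the phantom does *not* emulate: anatomy and partial-volume mixtures of
different tissue types, spatially correlated noise, within-region biological
T2 dispersion, B0/B1 structure beyond the linear ramp, or FLAIR physics
(FLAIR positivity is a mask, which is also how the analysis consumes it).
Passing tests therefore demonstrate correctness of the estimator and the
segmentation logic under the model's own assumptions, not robustness to
every property of in vivo data.

## Problem sizes and numerical defaults

The default phantom (≈2600 brain voxels) runs the full pipeline in about two
minutes on one CPU at ≈40 ms per voxel (61-angle scan on the reduced grid,
one full-grid NNLS, and ≈14 augmented solves for the μ search). Monte Carlo
studies use 100–500 voxels per condition. The detection-limit study
(scripts/acceptance.py) uses 200 baseline + 6×200 lesion voxels at SNR 100
with true flip 160° (the far end of the phantom's flip ramp, so stimulated-
echo correction is active), classifying on the baseline's 95th percentile
(5% false-positive rate) and reporting the smallest elevation reaching 90%
sensitivity.

## Degenerate inputs and tie-breaks

All-zero voxels fit to a zero spectrum (not an error) and are NaN in maps;
NaN magnitudes are an input error; equal-misfit flip angles resolve to the
largest; a zero-amplitude pool has weighted T2 NaN; nodes exactly on 40 or
250 ms belong to IEw; identical inside/outside distributions raise a
no-unique-intersection error rather than guessing.
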