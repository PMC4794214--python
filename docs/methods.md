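# Methods

## Overview

This package asks what a sparse-coding account of binocular vision predicts
about disparity detectors.  It learns complex-cell-like models from binocular
image patches with Independent Subspace Analysis (ISA) and then measures each
model's disparity selectivity the way a physiologist would: probe with
binocular sine gratings whose interocular phase difference encodes disparity,
reduce the responses to a disparity tuning curve, and summarise that curve
with the Disparity Discrimination Index (DDI) and a tuning-symmetry class.

## Stimulus ensemble (synthetic stereo pairs)

The analysis runs entirely on synthetic imagery so that every stage is
reproducible from a seed:

* **Luminance structure.** Each scene is Gaussian noise shaped to an
  amplitude spectrum proportional to `f^-1`, the classic naturalistic
  power-law, rescaled to mean luminance 0.5 and RMS contrast 0.1 (arbitrary
  linear units).  Default size 512 x 512 px; the pixel scale metadata is
  1 arcmin/px.
* **Disparity.** The right eye's image is the left eye's warped horizontally
  by a smooth random disparity field: Gaussian noise smoothed with a
  Gaussian kernel (correlation length 40 px) and scaled to a standard
  deviation of 2 px, so disparities are concentrated near zero as they are
  around fixation.  Vertical disparity is zero by construction.  Warping
  uses cubic interpolation and the warp margin is cropped before patch
  sampling so edge artefacts never reach the statistics.
* **Sensor noise.** Independent additive Gaussian noise per eye with sigma
  equal to 1% of the RMS contrast — enough to keep the patch ensemble full
  rank, small enough to leave the spectra untouched.

What this ensemble does *not* emulate: occlusions and disparity
discontinuities, monocularly visible regions, luminance nonstationarity,
chromatic structure, and the heavy-tailed scene statistics of real
photographs.  Passing the downstream tests therefore shows that the method
behaves correctly on a near-zero-disparity naturalistic ensemble, not that
the learned population matches what real photographs would give.

A second generator draws patch sets from the ISA generative model itself
(orthonormal components, sources isotropic within a subspace, exponential
radial distribution, hence sparse subspace norms).  It exists to benchmark
the optimiser against a known answer; recovery is scored as the mean
principal-angle cosine between matched learned and true subspaces
(Hungarian matching on projector overlaps), which is 1.0 at exact recovery
and about `sqrt(d/M)` at chance.

## Patch pipeline

50,000 binocular patches of 25 x 25 px per eye are cut at corresponding
image coordinates (the full-scale configuration uses 500,000).  Per eye,
each patch is centred on its own mean and scaled to unit norm; the
concatenated 1250-vector is then renormalised, leaving each half at norm
`1/sqrt(2)`.  This removes local luminance and contrast, mimicking retinal
gain control; rows whose per-eye norm underflows (blank patches) are dropped
and counted.  PCA whitening retains k dimensions with unit output variance.
k defaults to the number of learned components (2 x subspaces) because the
orthonormal component matrix must be square in whitened space; it is a
config knob since a different low-variance cutoff is defensible.

## Independent Subspace Analysis

The model is an orthonormal matrix `W` in whitened space whose rows are
grouped into fixed consecutive subspaces of two.  The per-patch objective is
`sum_s G(u_s)` with `u_s` the squared subspace response norm and
`G(u) = -sqrt(u + eps)`, `eps = 1e-4` smoothing the square root at zero.
Responses are isotropic (Gaussian-profile) within a subspace; the square
root makes subspace norms sparse across subspaces.  Because `W z` preserves
norms, the total energy `sum_s u_s` is fixed, and maximising the objective
concentrates energy in few subspaces per patch.

Optimisation is full-batch gradient ascent with symmetric
re-orthogonalisation `W <- (W W^T)^(-1/2) W` after every step and a
backtracking step size (halved on failure, grown 1.2x on success), so the
objective trace is non-decreasing by construction.  Convergence: objective
change below 1e-7 for 5 consecutive accepted steps, capped at 500
iterations.

The likelihood surface has local optima in which subspaces stay entangled.
Three mechanisms address this, all deterministic given the seed:

1. **Multi-start:** several random orthonormal inits (default 5) are burned
   in for 150 iterations and the best objective is pursued to convergence.
2. **Row-swap polish:** exchanging one component between two subspaces only
   re-bins already-computed responses, so all `O(J^2)` candidate swaps are
   scored incrementally and applied greedily while they help.
3. **Merge-and-resplit polish:** two subspaces can jointly span the right
   4-dimensional space yet split it along the wrong planes, which no row
   swap repairs.  Candidate pairs are ranked by the correlation of their
   response energies (independent subspaces have uncorrelated energies) and
   each candidate span is re-split by a small recursive ISA fit on a
   deterministic row subsample (cap 20,000 rows).

On ground-truth data (4 subspaces x 2 subunits, 50,000 patches) this
schedule recovers the true subspaces essentially exactly (mean matched
cosine > 0.99 across seeds).  The scaled-down pipeline run uses a lighter
budget (2 restarts, 1 resplit round) because the population statistics it
feeds are insensitive to the residual local optima.

## Complex-cell models and probing

Each subspace yields one complex-cell model with two subunit filters mapped
back to pixel space through the whitening transform (`v = forward^T w`, so
pixel-space and whitened-space responses agree exactly).  Two combination
rules are evaluated: **energy** (sum of squared subunit responses, the
binocular energy model's pooling) and **max-pooling** (maximum absolute
subunit response).  The energy rule is invariant to rotations of the filter
pair within its subspace; max-pooling is not.

Probe gratings are seeded at each model's mean fitted Gabor frequency and
circular-mean orientation (doubled-angle averaging, mod pi) and then
refined over a coarse grid around that seed so the model's peak map
response is maximised — the probe a physiologist would settle on by
hand-mapping the cell before running the disparity series.  Gabor fits are
bounded nonlinear least squares initialised from the discrete Fourier peak
and the centroid of the squared field, with up to 5 restarts and an early
exit once the fit explains 95% of the field's energy.  A half whose norm is
below 10% of its subunit's dominant half is treated as monocular and
excluded from the means; models with no usable half are excluded from
probing and logged.  The refinement step can be disabled
(`probe_mode="gabor_mean"`), which matters mainly for borderline mixture
models whose preferred grating is poorly predicted by the subunit fits.

Phase-phase maps sample both eyes' grating phases on a uniform 100-point
grid over [-pi, pi) (duplicate endpoint excluded).  Every stimulus pair goes
through the same per-eye normalisation as the training patches; because that
normalisation acts per eye, the map factorises through per-eye response
banks, and contrast drops out of the responses entirely.  Bar-shift maps use
an anti-aliased bright bar of width half the probe wavelength spanning the
whole patch along its orientation, shifted over +-12.5 px in steps of
0.5 px (half-pixel steps need the sub-pixel sampling the area-sampled
edges provide; bars are bright-on-zero by default, and the sign of the bar
amplitude selects the opposite polarity).

## Disparity metrics

The tuning curve averages the phase-phase map over constant-disparity
diagonals (disparity = right phase - left phase, circular; every cell
contributes once).  Averaging over the phase-sum direction marginalises out
absolute phase, so a phase-specific simple-cell-like model averages toward a
flat curve and scores low — the metric rewards exactly the phase invariance
an ideal detector needs.

The curve is summarised by its first circular Fourier harmonic
`r(d) = a sin(d + phi0) + c`, which on the uniform grid is the closed-form
least-squares sine fit — through the diagonal means and, equivalently,
through every map cell, since the regressors depend on disparity alone.
Then

    DDI = (Rmax - Rmin) / ((Rmax - Rmin) + 2 * RMS_error)

with the extrema taken from the fitted curve on the grid.  The residual
pools the curve's lack of fit *and* the within-diagonal variation of the
raw map over all `S^2` cells (`RMS_error = sqrt(SSE_total / (S^2 - 3))`).
The second term is essential: for any energy-rule model the diagonal means
are themselves an exact first harmonic in disparity (squares of responses
linear in the grating quadratures average to constant plus first harmonic),
so a curve-only residual would score every energy model 1.0.  Charging the
phase-dependent variation as error is what lets the index separate
phase-invariant disparity detectors (small within-diagonal spread, DDI near
1) from phase-specific or monocular models — the proportion of response
variation explained by disparity.  A numerically flat fitted curve (range
below 1e-9 of the offset) scores 0 rather than chasing a 0/0 limit — this
is what makes exactly-monocular fixtures score 0.

**Response phase and symmetry.** The reported response phase is the peak
location of the fitted curve, `psi = wrap(pi/2 - phi0)`: an even-symmetric
curve peaking at zero disparity reads psi = 0 (Tuned Excitatory), a trough
at zero reads psi = pi (Tuned Inhibitory), and odd-symmetric curves read
+-pi/2 (Near/Far).  Class bins are quarter-circle sectors at +-pi/4
boundaries; models with DDI below 0.6 are left unclassified.  The sign
convention — positive psi (peak at positive right-minus-left disparity)
labelled NEAR — is a package convention, exposed as a flag-level decision,
since nothing in the probing geometry ties the sign to crossed versus
uncrossed disparity.

Population summaries report DDI percentiles, maxima, threshold exceedance
fractions, and label proportions among tuned models with bootstrap 95%
confidence intervals (resampling models with replacement; default 200
resamples, configurable).  The energy versus max-pooling comparison uses
the two-sample Kolmogorov-Smirnov distance restricted to models with
DDI < 0.5 in both rules.

## Pipeline and reproducibility

Stages (simulate, patches, isa, probe, metrics) each persist one artifact in
the run directory and are skipped when it exists, so deleting a downstream
artifact and rerunning reproduces it bit-identically from upstream state.
All randomness derives from the master seed through stable per-stage
SHA-256 hashes, and a rerun with the same config yields a byte-identical
summary JSON.

Problem sizes used throughout the analysis and tests — 20 pairs at
512 x 512, 50,000 patches, 50 subspaces — are the package's scaled-down
study conditions; they keep a full run in the ten-minute range on one core
while leaving every population-level effect visible.  The full-scale
defaults (139 pairs, 500,000 patches, 200 subspaces) are retained in
`RunConfig` for runs against photographic data.

## Known limitations

* Subunits are linear with square or absolute-value nonlinearities; no
  half-wave rectification, and exactly two subunits per model.
* The DDI is phase-based: models that signal disparity through mixtures of
  position, frequency or orientation offsets are under-scored.
* The symmetry classes quantise a continuous phase; the +-pi/4 bin
  boundaries are a convention.
* The synthetic ensemble's disparity distribution is a modelling choice
  (smooth, sd 2 px), not a measurement of natural scenes.
* Because the right eye is an exact warp of the left plus 1% noise, nearly
  every learned component is binocular: the large low-DDI population that
  dominates analyses of photographic stereo data (monocular and unmatched
  structure from occlusions, vergence error and depth discontinuities) is
  almost empty here.  The DDI distribution is correspondingly compressed
  into the middle of the range, population statistics restricted to
  DDI < 0.5 rest on very few models, and a small number of odd-symmetric
  (Near/Far) position-disparity detectors survive the 0.6 threshold that
  photographic data suppress.
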