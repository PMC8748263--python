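# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic data does and does not emulate, and the
known limitations.

## Surface model

Analyses run on a left–right symmetric triangulated surface with one-to-one
vertex correspondence between hemispheres, the convention of symmetric
cortical templates (~2 mm inter-vertex spacing, ~32k vertices per
hemisphere). For desk-scale simulation the package stands in a regular
hexagonal lattice duplicated into two mirrored "hemispheres"
(`build_hex_mesh`): a lattice with *k* rings has `1 + 3k(k+1)` vertices,
interior vertices have the regular 6-neighbor triangulation, and the
homotopic pairing is the identity map across the hemisphere offset, with
`pair(v)`'s coordinates equal to `v`'s with the x-axis negated. Vertex
indexing is 0-based everywhere.

Neighborhoods are graph k-rings: all vertices within *k* edge steps
(breadth-first over triangle edges), center included. On the regular 2 mm
lattice the 4-ring holds exactly 61 vertices (≈ a 16 mm metric radius); a
metric-radius variant would differ slightly on irregular meshes and is not
implemented. Boundary vertices of the flat synthetic lattice keep their
truncated neighborhoods (closed cortical surfaces have no boundary, so this
only affects the stand-in mesh); the KCC denominator always uses the actual
neighborhood size.

The group analysis mask includes every vertex whose series has nonzero
temporal variance in every scan, "nonzero" meaning above numerical rounding
relative to the series mean (`var > (1e-8·(1+|mean|))²`), so flat-but-
inexact series are excluded.

## Synthetic cohort and BOLD generator

The cohort emulates a small longitudinal aging study: 24 subjects, baseline
ages uniform on 58–77 y, 8/24 male, five annual visits, two scans per
visit, 150 volumes at TR = 2 s. Education is uniform on 10–20 y (rounded);
baseline calendar time is uniform on 2012–2017, and the cohort covariate is
the decimal number of years between birth date and 1970-01-01, derived as
(baseline calendar year − 1970) − baseline age, hence constant within
subject and consistent with age across visits.

Each scan is a sum over the three slow bands of band-limited Gaussian
components plus white measurement noise and a constant positive offset
(default 10,000, the global-intensity scale). Per band:

1. unit-variance ideal-band-limited Gaussian noise per vertex, scaled to an
   amplitude `base·(1 + slope·(age − 58))·exp(b_i + covariate shifts)`;
   defaults base = 40/60/30 intensity units for slow-5/4/3 (≈0.3–0.6% of
   the offset, a realistic BOLD fluctuation scale), slope 0, subject
   intercept SD 0.1 on the log scale;
2. homotopic coupling: the right-hemisphere component is
   `w_h·(left mirror) + sqrt(1 − w_h²)·independent` (variance-preserving);
   default `w_h = 0.3`, optionally drifting with age per band;
3. local coupling: relaxed 1-ring averaging
   `(1 − w_s)·own + w_s·neighbor-mean`, default `w_s = 0.5`, optionally
   drifting with age per band; components are re-standardized afterwards so
   coupling drift never changes amplitude;
4. white measurement noise (default SD 10) and the offset.

The three aging pathways — amplitude (ALFF), local coupling (ReHo),
homotopic coupling (VMHC) — are separately switchable per band, and every
injected quantity (slopes, subject intercepts, dead vertices) is recorded
in a ground-truth ledger.

Two generator subtleties matter for pathway separability:

* **Retained-grid band structure.** The band components are constructed on
  the retained time grid (volumes after the 5 dropped equilibration
  volumes); the leading 5 volumes are the series' cyclic continuation.
  Ideal-filtering the full 150-sample series instead and truncating it
  would smear each band's age-trending content into neighboring bands
  (rectangular-window leakage), contaminating the "coupling drift in
  slow-4 only" condition.
* **Noise-free full-aging preset.** Broadband measurement noise dilutes
  band-filtered correlations, so an amplitude trend changes band SNR and
  thereby leaks a connectivity trend into every band. The
  `full_aging_signal_spec` preset therefore sets measurement noise to 0;
  the general-purpose default keeps noise SD 10.

At 145 retained volumes, slow-5 spans only ~3 DFT bins (frequency
resolution 1/290 Hz); scans can be lengthened where tests need spectral
resolution. What the generator does **not** emulate: hemodynamic response
shape, head motion, physiological (cardiac/respiratory) noise, spatial
inhomogeneity, vertex-wise effect topography. Passing recovery tests
therefore show that the *analysis* recovers the *modeled* structure; they
are not evidence about artifact robustness on real scanner data.

## Preprocessing

In-scope signal-level steps, fixed order: drop the first 5 volumes →
normalize the grand (4D) mean to 10,000 → remove per-vertex linear and
quadratic temporal trends. Detrending projects each series onto centered
{t, t²} and subtracts the projection, preserving the temporal mean: the
global-mean normalization is only meaningful on positive-mean data, and
ALFF excludes the 0 Hz bin regardless. Trend removal is per vertex
(standard practice). Volumetric stages (despiking, slice timing, motion
correction, ICA denoising, surface reconstruction, resampling) are out of
scope — the pipeline consumes surface-sampled series directly, and real
data preprocessed elsewhere can enter through the same `BoldScan`
container.

## Metrics

Band membership of a DFT bin is half-open `[f_low, f_high)` so the three
printed band ranges (which share the 0.03 and 0.08 Hz edges) partition the
spectrum without double counting. ReHo and VMHC are computed on ideal
(brick-wall DFT) band-filtered series; ALFF is computed from the detrended
series' amplitude spectrum restricted to the band's bins, which is
equivalent under the ideal filter (asserted by a test). ALFF uses the
*mean* one-sided amplitude `(2/T)·|DFT_k|` over in-band bins rather than
the sum, making values comparable across bands of different widths; a sum
variant is a keyword away. The 0 Hz bin and (for even T) the Nyquist bin
are never included.

ReHo is Kendall's W with average ranks on ties and no tie-correction term
in the denominator (ties have measure zero for the continuous synthetic
data; a warning is logged when a constant series makes them real), clipped
to [0, 1]. VMHC clips correlations at |r| = 1 − 1e−6 before `atanh` so
identical pairs stay finite; zero-variance members yield 0 with a warning.
Global summaries are the mean and the SD (denominator n − 1) of each raw
map over the masked vertices; a visit's two scans are averaged
arithmetically. No spatial smoothing is applied anywhere, consistent with
the global focus of the analysis. Whether the global "variability" should
be the over-vertex SD of the raw map (implemented) or a different variance
decomposition is an open interpretation documented here once.

## Aging-curve model

For one outcome (metric × band × statistic), the model is a Gaussian
additive mixed model: intercept, penalized cubic B-spline smooth of age,
linear fixed effects of sex (0/1), cohort and education, and a subject
random intercept. The spline basis uses 5 knots total — boundary knots at
the observed age range, 3 interior knots at age quantiles (basis dimension
7); "5 knots" is read as the total knot count, configurable if a user
prefers 5 interior knots. The penalty is the second-order difference
penalty on spline coefficients.

Fitting uses the standard mixed-model representation: the penalty's null
space contributes an explicit unpenalized linear age term (the constant is
the intercept), and the penalized range space is whitened to i.i.d.
coefficients with prior variance `σ_s²` and residualized against {1, age},
so at `λ = σ_ε²/σ_s² → ∞` the smooth collapses exactly to a straight line
and edf → 1; at `λ → 0` edf approaches the basis dimension. The two
variance ratios (smooth, subject intercept) are estimated by REML on the
profiled criterion `(n−p)·log(yᵀPy) + log|V₀| + log|XᵀV₀⁻¹X|`, optimized
on the log scale by Nelder–Mead started from the best point of a fixed
5×5 grid (a second deterministic restart from the origin guards against a
bad grid start); exactly-collinear or perfectly-fit degenerate inputs
short-circuit to the unpenalized limit. Smoothness edf is the trace of the
smooth's slice of the influence matrix (linear term + whitened wiggle
columns). Covariate p-values are Wald t-tests with the REML covariance and
n − total edf residual degrees of freedom.

The smooth's p-value is the standard Wald-type approximation: the fitted
smooth values are tested with a rank-truncated pseudo-inverse of their
posterior covariance at rank `max(1, round(edf))`, referred to
`F(rank, n − total edf)`. This is approximate by construction; the package
claims calibration, not exactness, and the test suite verifies by
simulation that the null rejection rate at α = 0.05 lies in [0.01, 0.10].
A manual cross-check harness (`scripts/crosscheck_gamm.py` +
`scripts/crosscheck_mgcv.R`) fits a shared synthetic dataset with
`mgcv::gamm`; the fitted curves agree to well under 5% RMS of the outcome
SD, with matching variance components and covariate tests.

Prediction curves are population-level: covariates at their sample means
(sex at the male proportion), random intercept excluded, pointwise 95% CI
as fit ± 1.96·SE from the coefficient posterior covariance. Grids far
outside the observed age range trigger an extrapolation warning (basis
evaluation clamps to the fitted range).

Cohort (birth year) is strongly collinear with baseline age by
construction; the longitudinal design identifies the age effect through
within-subject change, but cohort/age standard errors are accordingly
wide in a 24-subject cohort — visible in the recovery studies as
high-variance (though unbiased) slope estimates.

## Problem sizes and reproducibility

Simulation studies run at desk scale, chosen as the smallest sizes that
leave the Monte-Carlo error well inside each check's tolerance: the
synthetic mesh uses 5–9 rings (91–271 vertices per hemisphere; every
4-ring property is checked on interior vertices with complete
neighborhoods), cohorts are the full 24 × 5 × 2 design, recovery studies
use 25–200 replicate datasets. All randomness flows through
`numpy.random.SeedSequence` from explicit seeds; rerunning any pipeline
configuration reproduces its tables byte-for-byte.

## Known limitations

* The smooth p-value approximation is anti-conservative in small samples
  (observed null rejection ≈ 0.04–0.07 at nominal 0.05).
* The generator's Gaussian band-limited noise model is an explicit modeling
  choice, not an inference about any real cohort's noise structure.
* Graph-step neighborhoods approximate metric (16 mm) neighborhoods only on
  near-regular meshes.
* Global summaries cannot localize effects; a spatially heterogeneous
  aging effect can be invisible globally (and vice versa for nonlinear
  transformations of heterogeneous change).
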