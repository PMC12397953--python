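# Methods

This note documents the models and numerical choices behind `bplast`:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Data model

A recording is a set of trajectories, one per (individual, observation
day), sampled at a nominal 5 Hz (0.2 s).  Units are fixed at ingest: cm
and seconds.  Coordinates are treated as a continuous image-style plane
with the origin as recorded; no axis flipping.  `fill_gaps` first
materializes missing rows on the nominal grid, then bridges dropout runs
of at most `max_gap_frames` (default 5 frames = 1 s) by linear
interpolation between the flanking valid frames.  Longer gaps stay
invalid — downstream metrics split across them rather than inventing
movement — and nothing is extrapolated past the first/last valid frame.
Containment QC flags frames more than `tol_cm` (default 0.5 cm) outside
the tank polygon as invalid and snaps sub-tolerance excursions
(tracking jitter at the wall) onto the boundary; interior points are
never moved.

The default synthetic arena is an equilateral triangle of side 60 cm.
The real rearing tanks are triangular in planform but their published
description gives only the water depth (~7 cm); the 60 cm side is a
plausible stand-in, not an assertion about the real geometry, and any
convex polygon can be supplied as YAML.

## Basic metrics and CoV

Step length is the Euclidean displacement between consecutive valid
frames exactly one sampling interval apart.  The turning angle at frame
t rotates the previous movement vector onto the current one
(counterclockwise positive, wrapped to (−π, π], exact reversals map to
+π) and is *undefined* — not zero — whenever either movement vector has
zero length: a motionless animal has no bearing.  Wall distance is the
minimum distance to any boundary segment (via the polygon exterior, so
vertices and edges are handled uniformly).

Single-trait plasticity is the coefficient of variation sd/mean within
an interval.  Two conventions needed fixing where common usage is
ambiguous:

* **Turning angle sign.** Signed turns average to ≈0, making sd/mean
  ill-posed, so the CoV (and the wavelet channel) uses |turn| by
  default — variability of turning *intensity*.  `abs_turn=False`
  restores the signed convention.
* **Standard deviation.** Sample (n−1) sd by default; the population
  estimator is available via `ddof=0`.  At 18,000 frames per hour the
  difference is negligible.

Intervals with fewer than 50% of their nominal frame count, or with
non-positive mean, yield missing values rather than numbers.  Interval
indices are 1-based and aligned to observation-day starts; a complete
8 h/day × 28 day individual has exactly 224 hourly intervals of 18,000
frames.

## Wavelet feature space

Each metric series is z-scored with statistics from the individual's
whole observation period (one scope for all days, so a day of unusual
behavior stands out rather than being normalized away), then convolved
with 25 complex Morlet wavelets whose centre frequencies are log-spaced
from 0.01 Hz to the 2.5 Hz Nyquist limit — constant frequency ratio
250^(1/24) ≈ 1.26, covering rhythms from sub-second turns to ~100 s
excursion cycles.

The transform uses the analytic Morlet kernel in the frequency domain,
ψ̂(sω) = 2·exp(−(sω − ω₀)²/2) on positive frequencies with scale
s = ω₀/(2πf) (the unpaired Nyquist bin gets weight 1, not 2).  With
this scaling a unit-amplitude sinusoid at a channel's centre frequency
yields a peak amplitude of ~1 in that channel regardless of frequency,
which is the per-frequency normalization the downstream density
estimate needs; only relative amplitudes matter after that.  The
nondimensional frequency ω₀ defaults to 5, the conventional
time/frequency trade-off; it is config-exposed.

One observation day is one convolution segment — the 16 h overnight gap
makes cross-day convolution meaningless — with reflection padding at
segment edges.  Frames where any underlying metric is undefined are
zero-filled for the convolution and dropped from the output rows, so
the feature matrix has one 75-dimensional row (3 metrics × 25
frequencies, metric-major) per fully valid frame, with an alignment
index back to (individual, day, time).

## Behavioral space and clustering

UMAP (n_neighbors=50, min_dist=0.1, fixed seed, single-threaded for
reproducibility) is fit on a uniform 1/500 subsample of the pooled
feature rows; fitting a neighborhood embedding on a month of 5 Hz
tracking (10⁸ rows at full scale) is both infeasible and unnecessary,
as the subsample preserves the density structure.  All rows are then
re-embedded by inverse-square-distance weighted k-nearest-neighbor
interpolation (k=5) against the fit subsample in feature space — the
template re-embedding standard in the behavioral-mapping literature.
This is deterministic, exactly reproduces the fit sample's coordinates,
agrees between batched and whole-matrix calls, and embeds ~10⁶ rows per
minute on one core.

The embedded points are histogrammed on a 512×512 grid over the 5%-
padded bounding box and smoothed with an isotropic Gaussian.  Cluster
cores are the local maxima of the smoothed density; a watershed
transform on the *inverse* density assigns every grid cell to a basin.
The number of basins is controlled through the smoothing bandwidth:
larger σ merges modes, so σ is found by log-space bisection for exactly
k basins; because the basin count is not strictly monotone in σ, the
smallest bandwidth giving ≥ k basins is used as a fallback and surplus
basins are merged smallest-area-first into the neighbor behind their
densest shared ridge, then labels are renumbered 1..k.  Every frame
gets the label of its containing grid cell (points outside the box —
possible only when transferring a model to new data — snap to the
nearest border cell and are logged).

The k-means alternative clusters the raw 75-dim rows (labels 1..k);
above 200k rows the mini-batch variant keeps month-scale inputs
tractable on one core.

## Entropy and arcs

Within each interval, the occupancy distribution over the k clusters
gives Shannon entropy H = −Σ pᵢ ln pᵢ with 0·ln 0 := 0.  Natural log is
the default (ln 20 ≈ 2.996 nats at uniform occupancy of 20 clusters);
base-2 and normalized (H/ln k) variants are options.  Entropy is
permutation-invariant in the labels, and merging clusters can only
lower it, so comparisons are only meaningful at fixed k.

Arc models are linear mixed models fit by maximum likelihood (so that
AIC/BIC compare the two mean structures): response ~ z (+ z²) + mother
+ tank position + tank system, with per-individual random intercepts
and slopes (linear) or intercepts, slopes and quadratic terms
(quadratic), unstructured random-effect covariance.  The time covariate
z is the observation hour centered at its mean and scaled by its sd —
raw hours up to 224 make the quadratic random-effect scale pathological.
Daily-interval responses use the middle observation hour of each day so
both interval scales share a time axis.  Headline selection is by AIC
with BIC always reported; disagreement is flagged, never hidden.  Fits
that do not converge cleanly are returned with `converged=False` rather
than silently.

The peak hour is the vertex −β₁/(2β₂), mapped back to raw hours, and is
reported only when β₂ < 0.  Its CI is a nonparametric bootstrap over
individuals (cluster bootstrap, preserving within-individual
dependence), default 500 resamples (the pipeline uses 200): each
resample refits the population quadratic by OLS and records its vertex;
the percentile interval of those vertices is the CI.  Refitting the
full mixed model per resample would cost ~1–2 s each; resampling whole
individuals already absorbs the grouping structure, and the OLS vertex
of a resample targets the same population quantity.  Resamples with
non-negative curvature carry no interior peak and are excluded (their
count is logged).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with exact ground truth at every stage:

* **Movement modes.** Five latent modes (freeze/hover, slow
  wall-following, cruising, erratic turning, darting) differing in all
  three observable channels: per-frame step length ~ Gamma(shape,
  scale), heading increment ~ von Mises(0, κ), and a wall-attraction
  weight in [0, 1] steering the heading toward the nearest wall
  (thigmotaxis).  Mode separation in all channels is deliberate — it
  makes the clustering stage testable.
* **Diversity schedule.** At observation hour t the hour's
  mode-preference weights are drawn from Dirichlet(α(t)/M·1) with
  α(t) = exp(a₀ + a₁t + a₂t²); within the hour a sticky Markov chain
  (stay-probability 0.95) with stationary distribution equal to the
  drawn weights selects the per-frame mode.  a₂ < 0 programs an
  inverted-U diversity arc with peak at −a₁/(2a₂); defaults (a₀=−0.717,
  a₁=0.0448, a₂=−2×10⁻⁴) put the peak at hour 112 — mid-study — with
  total concentration rising from ~0.5 to 6 and expected weight entropy
  from ~0.5 to ~1.25 nats (closed form: E[H] = ψ(α+1) − ψ(α/M+1)).
* **Between-individual variation.** Per-individual (a₀, a₁, a₂) are
  drawn around the cohort values with sds (0.3, 0.002, 5×10⁻⁶): real
  heterogeneity in level and peak timing (individual peak-hour sd ≈
  6 h) that stays modest relative to the ±10 h tolerance the end-to-end
  validation tests — a validation cohort whose ground-truth population
  peak drifted by more than the tolerance would not test the pipeline.
* **Integration.** Positions advance sequentially (numba-compiled):
  wall steering, turn noise, gamma step, reflection off any crossed
  wall.  Reflection keeps fish inside while approximately preserving
  the step-length distribution; steps that interact with a wall are
  shortened slightly (a few percent for wall-hugging modes), which the
  tests account for by checking speed fidelity on wall-free steps.
* **Covariates and seeds.** Mother (3 levels), tank position (2) and
  tank system (4) are assigned round-robin such that no covariate is a
  function of another (a collinear assignment makes the mixed-model
  design singular).  Per-individual seeds fan out deterministically
  from the master seed via `numpy.random.SeedSequence`.

**Scaled presets.** The full design (45 individuals × 28 days × 8 h/day
at 5 Hz ≈ 1.8×10⁸ frames) is available but not what the tests run.  The
"desk" preset keeps the 8 × 28 = 224 hourly-interval structure and
shrinks each "hour" bin to 75 s (12 individuals × 10 min/day ≈ 10⁶
frames), which one core processes end-to-end in under a minute.  What
scaling down costs: per-interval entropy estimates are noisier (375
frames per bin), and the slowest wavelets (periods up to 100 s) smear
information across the shortened bins, so measured entropy
rank-correlates with the true schedule at ~0.6–0.85 at desk scale
versus essentially monotone agreement at full scale.  Passing tests at
desk scale therefore demonstrate correct mechanics and recoverability
of the programmed arc, not the signal-to-noise of a real month-long
recording.

What the generator does **not** emulate: biomechanically realistic fish
locomotion (no inertia, body posture, or burst-glide kinetics), social
or environmental context, vertical movement, tracking artifacts
(identity switches, jitter, dropouts — gaps must be injected manually
to exercise QC), and any direct coupling between the diversity schedule
and metric *means* (only mode composition changes over development).

## Reproducibility and orchestration

`run_all` executes io → metrics/CoV → wavelets → clustering → entropy →
arcs, writing per-stage tables, and is bit-reproducible given (config,
seed): stage seeds derive from the master seed by hashing, UMAP runs
single-threaded under its fixed seed, and provenance (config, per-stage
config hashes, package version, timings, QC counts) lands in
`provenance.json`.  `resume` re-runs from a named stage after verifying
that the config hashes of all upstream stages match the stored run;
entropy/arcs resume from the persisted CSVs, while earlier stages
recompute (the 75-dim feature matrix — ~300 MB per desk cohort — is
deliberately not persisted).  Memory stays bounded: features are
float32 and the largest transient is the feature matrix plus one
chunk of kNN scores.

## Known limitations

* The watershed basin count is controlled indirectly through the
  smoothing bandwidth; for pathological densities the bisection falls
  back to merging, and which basins merge depends on the density at
  ridge cells.
* kNN re-embedding places points inside the convex hull of their
  templates; genuinely novel behavior (far from every template) is
  pulled toward the nearest templates rather than forming new
  structure.
* MixedLM variance components frequently sit on the boundary for
  near-constant responses; fits are flagged rather than retried with
  alternative optimizers.
* CoV of the turning angle measures |turn| variability; a circular
  statistic might be preferable for strongly directional swimmers.
* The entropy–concentration mapping is concave, so a quadratic fit to
  entropy under a log-quadratic concentration schedule recovers the
  peak location well (the schedule is symmetric about its vertex) but
  the fitted curvature is not the schedule's a₂.
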