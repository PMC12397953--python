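# bplast — developmental arcs of behavioral plasticity from 2-D tracks

`bplast` quantifies how *behaviorally flexible* an individually tracked
animal is at each point of its development, and how that flexibility
changes over weeks of continuous high-frequency tracking.  It was built
for month-long, 5 Hz overhead recordings of individually housed fish in
triangular tanks, but any long 2-D trajectory sampled on a regular grid
fits the data model.

## What it computes

Starting from timestamped x-y tracks (one CSV row per video frame), the
pipeline derives, per individual:

1. **Basic movement metrics** at native 0.2 s resolution: step length
   (cm/frame), signed turning angle (rad), and distance to the nearest
   tank wall (cm).
2. **Single-trait plasticity** as the coefficient of variation
   CoV = σ/μ of each metric within hour-length (or day-length)
   intervals — 8 h/day × 28 days gives 224 hourly CoV values per metric.
3. **A behavioral phenotype space**: each (z-scored) metric timeseries is
   convolved with 25 complex Morlet wavelets log-spaced over
   0.01–2.5 Hz; the per-frequency amplitudes give every frame a
   75-dimensional feature vector capturing both instantaneous behavior
   and its temporal-autocorrelation structure.
4. **Cluster-delineated repertoire**: UMAP embeds the feature space in
   2-D (fit on a 1/500 subsample, all frames re-embedded), a
   Gaussian-smoothed data density is segmented by a watershed transform
   on its inverse into exactly *k* clusters (default 20); a k-means
   alternative clusters the raw 75-dim space directly.
5. **Behavioral entropy**: within each interval, the occupancy
   distribution p over the k clusters gives Shannon entropy
   H = −Σᵢ pᵢ ln pᵢ (nats), a whole-repertoire plasticity measure
   bounded by ln k.
6. **Developmental arcs**: linear and quadratic mixed models of entropy
   (and each CoV) over observation hours — fixed effects of time (and
   time²) plus mother identity, tank position and tank system; random
   intercepts/slopes(/quadratic terms) per individual — are fit by ML
   and compared by AIC/BIC.  A negative quadratic coefficient with an
   interior vertex −β₁/(2β₂) is an inverted-U arc; the vertex is the
   hour of peak plasticity, with a bootstrap-over-individuals CI.

A fully specified synthetic-cohort generator (`bplast.synthetic_data`)
produces 5 Hz trajectories from a regime-switching correlated random
walk inside the tank polygon whose latent-mode diversity follows a
programmable Dirichlet schedule α(t) = exp(a₀ + a₁t + a₂t²) — so every
stage of the pipeline can be validated against exact ground truth
(per-frame modes, per-hour occupancy entropy, programmed peak hour
−a₁/(2a₂)).

## Worked example

Simulate a scaled-down cohort (12 individuals × 28 days × 10 min/day,
keeping the 8 × 28 = 224 hourly-interval structure) with an inverted-U
diversity schedule peaking at observation hour 112, then run the full
pipeline:

```python
import bplast as bp
from bplast.pipeline import PipelineConfig, run_all

cfg = bp.desk_preset(master_seed=1)          # 12 fish x 28 days x 10 min/day
trajs, truth = bp.make_cohort(cfg)

pcfg = PipelineConfig(
    out_dir="results/demo",
    tank=cfg.tank,
    seconds_per_hour=cfg.seconds_per_hour,
    hours_per_day=cfg.hours_per_day,
    k=20,
    seed=1,
)
bundle = run_all(pcfg, trajectories=trajs)

arc = bundle["arcs"]["entropy"]
print(f"programmed peak hour : {cfg.programmed_peak_hour:.0f}")
print(f"model chosen by AIC  : {arc['selection']['winner_aic']}"
      f"  (dAIC = {arc['selection']['delta_aic']:.1f})")
print(f"estimated peak hour  : {arc['peak']['peak_hour']:.1f}"
      f"  (95% CI {arc['peak']['ci_low']:.1f}-{arc['peak']['ci_high']:.1f})")
```

printed:

```
programmed peak hour : 112
model chosen by AIC  : quadratic  (dAIC = 394.1)
estimated peak hour  : 116.9  (95% CI 113.9-119.4)
```

The quadratic (inverted-U) arc is selected decisively and the vertex
lands within a few hours of the programmed peak.  `bundle["arcs"]` holds
the same comparison for the three CoV responses; `run_all` also writes
`cov.csv`, `clusters.csv`, `entropy.csv`, `arcs.json` and a
`provenance.json` (config, per-stage hashes, seeds, timings) to the
output directory.

The same steps are available from the shell:

```bash
bplast simulate --out tracks.csv --truth truth.csv --preset desk --seed 1
bplast run --in tracks.csv --out results/demo --k 20 --seconds-per-hour 75 --seed 1
```

## Layout

| module | role |
|---|---|
| `bplast.io_tracks` | track CSV reading/writing, gap filling, tank polygon, containment QC |
| `bplast.metrics` | step/turn/wall metrics, interval binning, CoV |
| `bplast.wavelets` | frequency ladder, Morlet spectrograms, 75-dim feature matrix |
| `bplast.behavior_space` | UMAP embedding, density, watershed clustering, k-means |
| `bplast.entropy_arcs` | occupancy, Shannon entropy, mixed-model arcs, peak CI |
| `bplast.synthetic_data` | regime-switching cohort simulator with ground truth |
| `bplast.pipeline` | orchestration, provenance, resume; `bplast` CLI in `bplast.cli` |

See `docs/methods.md` for the modelling details, parameter defaults, and
known limitations.
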