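# Methods

## The model

Crawling *Drosophila* larvae alternate between two behavioural modes: an
**active crawling** phase, in which the animal advances with strong
directional persistence, and a **reorientation** phase, in which it stays
in place, sweeps its head, and exits in a new direction.  `bprw` models a
trajectory as a *bimodal persistent random walk* over a sequence of
smoothed points.  Each point is a reorientation event with probability
*f* (the reorientation frequency), independently of history — only the
mean frequency is part of the phenotype, so no run-length correlation is
imposed.  Every point is reached by an arrival step of Weibull(k, λ)
length; the heading increment before the step is N(0, σ_crawl), except
when leaving a reorientation event, where it is N(0, σ_reorient) with
σ_reorient ≫ σ_crawl.  A point is displacement-free *during* its dwell,
which is Gamma-distributed per phase (Gamma models accommodate the
long-tailed dwell distributions seen in data).  The six phenotype
parameters are therefore

| parameter | units | meaning |
|---|---|---|
| `reorientation_frequency` | – | fraction of smoothed points that are reorientation events |
| `crawl_time_gamma` (shape, scale) | s | dwell per active-crawling point |
| `reorient_time_gamma` (shape, scale) | s | dwell per reorientation point |
| `step_weibull` (k, λ) | mm | step length between consecutive crawl points |
| `crawl_angle_sigma` | rad | Gaussian width of within-crawl turning angles |
| `reorient_angle_sigma` | rad | Gaussian width of the turn across a reorientation event |

The crawl-phase step and angle parameters jointly determine a persistence
length l_p = −⟨ℓ⟩ / ln⟨cos θ⟩; for Gaussian turns ⟨cos θ⟩ = e^(−σ²/2),
so a fixed step b gives exactly l_p = 2b/σ².

## Analysis pipeline

1. **Smoothing** (`smoothing`).  Raw centroid samples (fixed interval,
   default dt = 2 s) are collapsed by a greedy walk: a run absorbs
   consecutive samples while their distance to the run's *first* member
   stays ≤ the threshold (boundary ties merge), the run is replaced by its
   m-weighted centroid, and the first sample beyond the threshold anchors
   the next run.  The pass is applied with thresholds a·r for a = 0.1,
   0.2, …, 1.0 (r is the resolution limit, nominally the larva's width in
   the image; the escalation yields the finest possible smoothing), and
   then iterated at threshold r to a fixed point, which makes the output
   well-defined and idempotent — at the fixed point all consecutive
   smoothed points are > r apart.  `m` counts raw samples per smoothed
   point and is conserved across passes (points inherit and sum their
   members' m), so m·dt is the dwell time at the point.
2. **Rest filter** (`detection`).  Points dwelling strictly longer than
   `rest_threshold` (default 14 s) are excluded from all statistics; this
   targets rare, barely-moving (injured) animals.  The filter runs before
   outlier detection so pathological resting cannot inflate the m
   statistics that detection relies on.  Exclusions interior to a track
   split the crawl sequence, so no step or angle is fabricated across an
   excluded gap.  Note an interaction worth knowing: if a population's
   genuine reorientation dwells approach the threshold, the filter
   censors them; set `rest_threshold = inf` for data known to contain no
   resting pathology (the synthetic closed-loop study does exactly this,
   since its reorientation dwell mean of 20 s exceeds 14 s by design).
3. **Reorientation detection** (`detection`).  Per track, the m values of
   the retained points are screened with the iterative modified Thompson
   tau test (τ = t·(n−1)/(√n·√(n−2+t²)), t the two-tailed Student-t
   quantile at α = 0.05, df = n−2, recomputed as values are removed; ties
   on the maximum deviation break to the first index).  The screen is
   two-sided, but only flagged points with m *above* the post-removal mean
   are labeled REORIENT — reorientations are the largest m values, and a
   low-side outlier is not an event.  Tracks with fewer than 3 usable
   points are labeled all-CRAWL and flagged.
4. **Phenotype fits** (`phase_stats`).  Step lengths are measured within
   uninterrupted crawl segments only; dwells per phase are pooled and
   fitted by Gamma MLE (location pinned at 0); steps by Weibull MLE.  The
   within-crawl angle sigma is fitted with the mean pinned at zero
   (crawling is unbiased absent taxis), i.e. σ = √⟨θ²⟩.  The turn across a
   reorientation event is the signed angle between the displacement into
   the event and the displacement out of it; because these samples are
   few, an iterative two-sided Grubbs screen (α = 0.05) removes individual
   outliers before σ is taken as the sample SD of the survivors.
   Model comparison (`select_best`) fits Weibull, normal, Gamma,
   lognormal, exponential and Cauchy candidates by maximum likelihood and
   ranks them by AIC (families differ in parameter count).  Population
   quantities (frequency, agilities = inverse mean dwell per phase) are
   computed per track first, then reported as mean ± SEM across tracks.
5. **Persistence length** (`persistence`).  Experimental crawl segments
   are too short for a direct estimate, so crawl-only tracks are simulated
   from the fitted step/angle distributions (default 10³ tracks × 10³
   steps; the acceptance study uses 200 × 500, which already determines
   l_p to a few percent) and ⟨R²⟩ versus contour length L is fitted with
   the worm-like-chain relation ⟨R²⟩ = 2l_pL − 2l_p²(1 − e^(−L/l_p)).
   Every track prefix contributes an (L, R²) pair; pairs are pooled into
   20 logarithmic bins between the 5th and 95th percentile of L and the
   fit is least squares on the bin means in linear ⟨R²⟩ space, balancing
   the ballistic (⟨R²⟩ → L²) and diffusive (⟨R²⟩ → 2l_pL) regimes.  A
   fitted l_p beyond the sampled contour range is flagged as a lower
   bound (near-ballistic ensembles constrain it only from below).
6. **MSD** (`msd`).  Time-and-ensemble averaged with overlapping windows
   (the standard construction, and the one that uses short tracks best).
   The σ band of a strain's MSD comes from repeated matched simulations:
   populations with as many tracks as the experiment are simulated and
   the band is the per-lag mean ± 1 SD across the *population-level*
   MSDs.  The log-log slope over a lag window gives the scaling exponent.

## The synthetic generator and what passing tests mean

The simulator (`simulator`) is first-class: it generates event-level
tracks from a phenotype and *renders* them to raw camera frames so the
entire analysis pipeline can be exercised closed-loop.  Rendering choices,
and their rationale:

- **Frame counts** per event are `floor(dwell/dt)` plus a Bernoulli draw
  on the fractional part (stochastic rounding), so the expected rendered
  duration equals the drawn dwell exactly; deterministic rounding with
  sub-frame drops would bias both the recovered frequency and the crawl
  dwell mean at dwell means of a few frames.  Events rendering to zero
  frames are dropped with a warning.
- **Crawl frames** interpolate linearly along the final stretch of the
  arrival step, capped at `crawl_span_frac · r` (default 0.5·r).  A
  smoothed point *is* sub-resolution travel, so its rendered footprint
  must stay below r; spreading frames over the whole step would make
  smoothing split one event into several.
- **Reorientation frames** sit at the event position plus isotropic
  Gaussian jitter of SD 0.2·r (head sweeping moves the tracked centroid);
  keeping the jitter well inside the merge radius lets the episode smooth
  back into a single high-m point.
- **Render resolution.**  The closed-loop studies use r = 0.015 mm, set
  so that the probability of an inter-event gap falling below the merge
  radius is ≈1% (P(step ≤ 1.5r) under Weibull(1.5, 0.5 mm)).  At coarser
  r, neighbouring events fuse during smoothing and the fused points
  masquerade as reorientations.

Reference study conditions for the closed loop: 25 tracks × 30 simulated
minutes at f = 0.10, crawl dwell Gamma(16, 0.25 s) (mean 4 s, CV 0.25 —
peristaltic progression is regular, so the crawl dwell is narrow),
reorientation dwell Gamma(4, 5 s) (mean 20 s, CV 0.5 — pause durations
are broad and long-tailed), steps Weibull(1.5, 0.5 mm), σ_crawl = 0.3,
σ_reorient = 1.2 rad.

What the generator does *not* emulate: coupling between speed and step
length (real smoothed steps and dwells are negatively correlated because
both derive from one continuous motion), run-length correlations in the
phase sequence, taxis or arena boundaries, larva–larva interactions, and
genuinely still "resting" pathology.  Passing the closed loop therefore
shows the pipeline inverts its own generative model at realistic sizes —
it does not certify accuracy on real video, where segmentation noise and
the above correlations enter.

## Numerical choices

- Distance comparisons merge on ≤ (ties merge); argmax ties in the tau
  and Grubbs screens break to the first index.
- Sampling regularity tolerance on input tables: |Δt − dt| ≤ 10⁻⁶·dt.
- Parameter JSON round-trips losslessly (shortest-repr floats).
- Gamma/Weibull/lognormal/exponential fits pin location at 0; standard
  errors come from the finite-difference observed information.
- Degenerate inputs (constant samples, absent phases, < 5 reorientation
  turns) flag the corresponding phenotype field as `None` with a warning
  instead of aborting the pipeline; such parameter sets cannot be
  simulated from.
- All stochastic stages accept a single master seed; populations spawn
  per-track child generators deterministically, so a seed reproduces a
  population bit-for-bit.

## Known limitations

- The Bernoulli phase model cannot express bursty reorientation
  statistics; only the mean frequency is matched.
- Recovered Gamma *shapes* for dwell distributions are biased by the
  dt-quantisation of dwell times (means are unbiased); comparisons
  between strains should use the means (equivalently the agilities).
- The rest filter and slow-reorienting phenotypes interact (see above);
  the 14 s default presumes the empirical situation where crawl dwells
  sit well below it.
- The worm-like-chain estimator assumes an unbounded homogeneous walk;
  it is not meant for taxis or wall-following data.
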