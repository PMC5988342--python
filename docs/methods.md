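# Methods

This note documents the models, estimators and numerical conventions used in
`attnspace`, the assumptions behind the synthetic-population generator, and
the design choices made where more than one reasonable option existed.

## 1. The analysis pipeline

### Attentional gain factors

For each cell and each attention task, the gain factor is the slope of an
unweighted least-squares regression constrained through the origin,

    b = Σᵢ xᵢ yᵢ / Σᵢ xᵢ²,   i = 1..3,

where `x` are passive-task condition means and `y` attention-task condition
means for the three stimuli shared by the two tasks.  The underlying model
is that attention rescales a cell's passive tuning multiplicatively
(response gain).  Four gains exist per cell: each attention task is
referenced against each passive baseline (passive-shape for the shape decode
space, passive-location for the location space).

The *shared* stimuli are matched as full stimuli, not as marginal labels:
the passive-shape task shows the eight shapes at one location — the best
location, which is also one of the three active locations — so the shape-
decode gain uses attention trials at that matched location; symmetrically
the location-decode gain uses attention trials carrying the best (matched)
shape.  Condition means, not single trials, enter the regression.

Cells whose matched passive vector is all zero have no identifiable gain and
are excluded with a logged count.  Since firing rates are non-negative, the
estimator cannot produce negative gains.

Estimator properties verified by the suite: exact recovery on noiseless
data; scale equivariance; mean bias under Poisson noise below 2% at base
rates ≥ 10 spikes/s with 12 repetitions (the small negative bias that does
exist is regression attenuation from noise in the passive regressor).

### Interpolation along the stimulus ring

The attention-task locations generally fall between the eight passive grid
angles (matched in eccentricity).  Passive responses at the active angles
are estimated with a cubic spline with **periodic** boundary conditions —
the only boundary choice respecting the circular domain — after
canonicalizing angles to [0°, 360°).  Negative spline overshoot is clamped
to zero because rates are non-negative.  With the default design (active
angles at best-grid-angle ± 120°, grid spacing 45°) each cell's three
interpolation shifts are {0°, 15°, 15°}, mean 10°; the nearest-grid shift
can never exceed half the grid spacing (22.5°).  A smooth cosine-like
tuning curve sampled at 8 knots is recovered to about 0.05% of its range
(worst case ~1% of the peak near zeros of the curve).

### Population matrices and correlation distances

A population response vector holds the mean rates of all retained cells to
one stimulus.  For an attention condition, each cell's row is its eight
passive means times its scalar gain; the passive condition uses the means
unscaled.  For the location space only cells inside the area's eccentricity
band (inclusive endpoints) are kept, and all stimuli are treated as lying
at the retained population's mean eccentricity.

Distance between stimuli is `d = 1 − r` with `r` the Pearson correlation
across cells between two population vectors (correlations between condition
vectors over the population — not between neurons).  The matrix is
symmetric and hollow with entries in [0, 2] and 28 unique distances for 8
stimuli.  Correlation distance is not a metric; the triangle inequality is
neither assumed nor asserted.  Cells with a constant row (zero variance
across all eight stimuli) carry no discriminative signal, break Pearson
correlation, and are dropped with a warning.  A direct consequence used as
a test invariant: a gain that is *common to all cells* cancels exactly, so
uniform gains leave the distance matrix unchanged; only gain
*heterogeneity* across cells can change the geometry.

The standard error reported with a mean distance is computed over the 28
unique distances.

### Classical MDS

Torgerson scaling: square the distances, double-center
`B = −½ J D∘D J`, eigendecompose, and scale eigenvectors by the square
roots of the top-k non-negative eigenvalues (k defaults to 2).  Correlation
distances are generally non-Euclidean, so negative eigenvalues occur; they
are excluded from both coordinates and the variance normalization
(positive-spectrum convention) and logged when their mass exceeds 5% of the
positive spectrum.  Reflection indeterminacy is fixed deterministically by
flipping each eigenvector so its largest-magnitude component is positive.
For any Euclidean input the embedding reproduces the distances to 1e-8;
scikit-bio's principal-coordinates analysis serves as an independent oracle
in the tests.

### Procrustes alignment and stress

Two configurations are compared after removing the linear indeterminacy of
MDS with the least-squares Procrustes transform: translation, orthogonal
rotation (reflections permitted), and optionally a uniform scale.  The
residual mismatch is the stress

    stress = Σ_{i<j} (d¹ᵢⱼ − d²ᵢⱼ)² / Σ_{i<j} (d¹ᵢⱼ − ⟨d¹⟩)²,

with `d¹`, `d²` the within-configuration Euclidean distances and the
denominator taken from the **first-named** configuration — stress is
deliberately asymmetric, and the pipeline always passes the first task of a
pair (or the MDS map, when comparing against physical locations) as
configuration 1.  Summation is over unique pairs; summing ordered pairs
scales numerator and denominator equally.  The Procrustes objective is the
summed squared coordinate difference, with stress then evaluated on the
aligned pair; these two criteria are closely related but not identical, and
the convention here is documented rather than resolved.  Scaling is turned
*off* when the purpose is to compare hull sizes (magnification), and *on*
when the purpose is to isolate warp.

Convex-hull summaries report the polygon area of the hull and the mean
distance of hull vertices from the configuration centroid.

### Shuffle-split bootstrap

The null hypothesis is that two attentional conditions' trials come from
one distribution.  Per iteration, trials are pooled **within each (cell,
stimulus) pair**, shuffled, and split back into two pseudo-conditions with
the original per-condition counts; the full pipeline — gain re-estimation,
matrix assembly, distances, MDS, full Procrustes — runs on each split and
the stress between the two results is recorded.  `p` is the fraction of
resampled stress values strictly greater than the observed one (no +1
smoothing; the minimum reportable p is 1/n_boot; ties count as
non-exceeding).  Default 10,000 iterations, reducible in config.

Two documented readings were considered and one rejected: a *global*
shuffle across stimuli would destroy stimulus identity and make stress
meaningless, so shuffling is within stimulus; and reusing point-estimate
gains inside iterations would make the resampled matrices independent of
the shuffle (the matrices are gain × passive-vector, so the shuffle reaches
the geometry only through the gains) — gains are therefore always
re-estimated per iteration.

For attention-vs-passive comparisons in the location space, the passive
trials were recorded at grid angles while the attention trials sit between
them; the passive side of the pool uses the trials at the grid angle
nearest each active angle, the same approximation the interpolation step
already makes.

Calibration, verified by the suite at 500 null sessions × 200 iterations:
empirical type-I error at the 0.05 threshold within [0.03, 0.07] and
Kolmogorov–Smirnov distance of the p-values from uniform below 0.1.

### Power analysis

A two-sided one-sample z-test on the n = 28 paired distance differences:
the minimal detectable effect is `δ = (z₁₋α/₂ + z_power)·sd/√n`, the
standard sample-size identity, which ignores the negligible far rejection
tail.  `power_of_effect` reports the exact two-tailed rejection probability
by default (equal to α at δ = 0) and the dominant-tail approximation on
request; the latter round-trips the closed form exactly.

### Rank tests

Group comparisons of distances use the two-sided Wilcoxon–Mann–Whitney
rank-sum test; paired gain comparisons use the Wilcoxon signed-rank test
with zero differences dropped (all-zero differences return p = 1 by
convention).  Both delegate to scipy and are verified against exhaustive
enumeration of labelings / sign patterns for all sample sizes up to 8.
No multiple-testing correction is applied across the comparison grid; the
reported p-values are uncorrected, as is conventional for this analysis.

## 2. The synthetic-population generator

The generator emulates the recording design: two areas (85 AIT-like and 53
LIP-like cells by default), 8 shapes, 8 locations equally spaced on an
iso-eccentric ring (AIT band 2–6°, LIP 7–12°; one eccentricity per cell,
uniform in the band), per-cell active subsets of 3 shapes (two strongest +
weakest, ties to the lowest index) × 3 locations (best grid angle ± 120°),
12 repetitions of each of the 9 sample conditions in each attention task
(216 non-catch matching trials per cell), 20% catch trials (generated,
flagged, excluded from analysis), and passive tasks with 4 (shape) and 12
(location) repetitions.

**Tuning model.**  A cell's mean rate to shape s at angle θ is
`f(s) · exp(κ(cos(θ − θ_pref) − 1))`: lognormal i.i.d. shape rates
`f(s) = base · exp(N(0, σ_shape))` (σ_shape = 0.8, base 20 spikes/s) times
a peak-normalized von Mises location profile.  Trial noise is Poisson on
spike counts in a fixed 500 ms window (rates = counts/window) — the
simplest count-noise model consistent with rate data; the window length is
a free parameter because sample-period boundaries are a recording-side
choice the analysis never sees.

**Attentional gains.**  A single attention trial has one firing rate, yet
each task carries two measurable gains (one per passive baseline), so four
independent per-cell gain distributions are not jointly realizable.  The
generator instead draws one *engagement* factor per task — lognormal per
(area, task), with passive-shape ≡ 1 and passive-location ≡ 1/ρ for a
per-cell lognormal offset ρ — and the four ground-truth gains are the
implied ratios: shape-decode gains equal the attention engagements,
location-decode gains equal engagement × ρ.  Default log-means (AIT: 1.15 /
1.08 with ρ ≈ 0.93; LIP: 1.35 / 1.30 with ρ ≈ 0.60) reproduce the
qualitative single-cell pattern the analysis expects: attention boosts
shape-decode responses in both areas (more strongly in LIP), while
location-decode gains sit slightly above 1 in AIT and clearly below 1 in
LIP.  Exact histograms are not reproduced.  A `shared_task_gains` switch
gives both attention tasks one engagement draw per cell, making their
trials exchangeable — the generator's exact null for bootstrap calibration.

**Warping mechanisms** (off by default, per area):
`gain_heterogeneity` multiplies each attention condition mean by a
per-(cell, stimulus) lognormal jitter of log-sd `warp_magnitude`, drawn
once per task; `tuning_shift` moves the preferred angle toward the attended
location by `warp_magnitude × 45°` during the location-attention task
(clamped at the target) and, during the shape-attention task, blends each
active shape's rate toward the cell's best shape with weight
`min(warp_magnitude, 1)`; `both` applies both.

**Spatial-tuning defaults and the between-area direction.**  AIT-like cells
get shallow location tuning (κ = 0.5) with preferred angles clustered
(von Mises concentration 2.5 around the contralateral center) — large,
foveally biased IT receptive fields tuned weakly to position — while
LIP-like cells get sharp tuning (κ = 3) tiling the ring uniformly.  Under
these defaults the LIP-like location maps match the physical stimulus ring
more closely (lower stress after full Procrustes) than the AIT-like maps in
≈95% of seeds, the directional pattern the generator is required to
exhibit.  The comparison statistic is the mean stress-vs-ring across the
three conditions of the location space.

**What the generator does not emulate.**  Spike timing, correlated trial
noise (noise correlations), adaptation or drift, behavioral errors and
reaction times, contrast manipulations, and cells lost part-way through a
session (every simulated cell completes all four tasks, so both decode
spaces use the same cells, unlike real recordings where the location
analyses retain fewer cells).  Shape tuning is i.i.d. across shapes, which
makes the simulated shape space nearly isotropic: 2-D MDS captures ~50-60%
of its variance, less than for real shape representations, whereas the
location space — genuinely low-dimensional by construction — exceeds 90%.
Passing tests therefore certify the *machinery* (estimators, geometry,
inference) and the qualitative between-area logic, not any quantitative
property of cortical data.

## 3. Detectability of warps through this pipeline

Because condition matrices are (scalar gain) × (passive 8-vector), the only
channel by which a between-condition difference reaches the geometry is the
cross-cell *pattern* of fitted gains.  A pure tuning shift alters each
cell's three matched responses in a correlated way that the through-origin
fit largely absorbs into its scalar slope (the fit is dominated by the
best-location/best-shape point), so pure shifts have limited
population-level detectability — measured rejection ≈ 0.3–0.5 even at 45°
shifts.  Per-stimulus gain heterogeneity, by contrast, decorrelates the
fitted gains of the two tasks across cells and is detected essentially
always at log-sd 0.5.  The directional scenario used in the verification
suite therefore warps the AIT-like area with `both` at magnitude 0.5
(rejection ≈ 0.98) while the unwarped LIP-like area stays at its nominal
acceptance rate (≈ 0.96).  This asymmetry — single-cell tuning changes that
barely move the population geometry versus gain heterogeneity that warps it
— is itself the dissociation between single-cell and population-level
attentional effects that motivates the analysis.

## 4. Problem sizes and defaults used in verification

Bootstrap calibration runs 500 null sessions of 20 cells × 200 resamples;
directional scenarios use 50 full-size sessions (85 + 53 cells) × 200
resamples; oracle checks use exhaustive enumeration up to n = 8 and ten
random instances per numerical core; the full-size headline session uses
1,000-iteration bootstraps.  The library default remains 10,000 iterations.
All randomness flows through explicit integer seeds; fixed seed and config
give byte-identical trial tables and reports (report numbers are kept at
full precision until JSON serialization).
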