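# attnspace

Population-level analysis of how endogenous attention reshapes neural
stimulus representation spaces, with a synthetic-population generator that
makes the whole pipeline testable end to end.

## The scientific problem

Single neurons in visual cortex are strongly modulated by attention, but a
*population* encodes a stimulus as a response vector — the ordered list of
firing rates of all recorded cells.  Whether attention merely rescales the
geometry of those vectors (a linear magnification) or *warps* it
(non-uniform changes in the relative positions of stimuli) is a question
about representational geometry, not about single cells.  `attnspace`
implements the full analysis chain for delayed match-to-sample recordings
from a ventral-stream (AIT-like) and a dorsal-stream (LIP-like) area, with
two attention tasks (attend shape / attend location) and two passive tasks:

1. **Attentional gain factors.** For each cell, the slope of a regression
   through the origin of attention-task responses `y` on passive responses
   `x` to the same three stimuli: `b = Σxᵢyᵢ / Σxᵢ²`.  Four gains per cell
   (2 tasks × 2 decode spaces).  For the location space, passive responses
   at the attention-task angles are first estimated by periodic cubic-spline
   interpolation along the iso-eccentric stimulus ring.
2. **Population geometry.** Each cell's eight passive responses, scaled by
   its gain, give the attention-condition population matrix.  Stimulus
   dissimilarity is the correlation distance `d = 1 − r` (Pearson `r`
   between two population vectors), yielding an 8 × 8 matrix with
   `n(n−1)/2 = 28` unique distances; their mean measures how discriminable
   the stimuli are.
3. **Classical MDS.** Torgerson scaling (double-center `−½·J D² J`,
   eigendecompose, top-k non-negative modes) embeds each condition in 2-D.
4. **Procrustes + stress.** Conditions are aligned by the best-fitting
   translation, rotation/reflection and (optionally) uniform scale; the
   residual warp is the stress
   `Σᵢⱼ (d¹ᵢⱼ − d²ᵢⱼ)² / Σᵢⱼ (d¹ᵢⱼ − ⟨d¹⟩)²` over unique stimulus pairs.
5. **Shuffle-split bootstrap.** Trials of two conditions are pooled within
   each (cell, stimulus), shuffled, split back at the original counts, and
   the whole pipeline re-run per split; the p-value is the fraction of
   resampled stress values exceeding the observed one.
6. **Power analysis.** The minimal detectable effect of a two-sided
   one-sample z-test on the 28 paired distances:
   `δ = (z₁₋α/₂ + z_power) · sd / √n`.

Because the original recordings are not public, the `syndata` module
generates sessions with the emulated recording design (85/53 cells, 8 shapes, 8
iso-eccentric locations, per-cell active subsets of 3 shapes × 3 locations,
12 repetitions per sample condition, 20% catch trials, Poisson trial noise)
and known ground truth: von Mises location tuning, lognormal shape tuning,
per-cell attentional gains, and optional warping mechanisms (attention-
dependent tuning shifts, per-stimulus gain heterogeneity).

## Worked example

`examples/04_warp_stress_bootstrap.py` simulates a session in which
attention warps only the AIT-like area (tuning shifts plus per-stimulus
gain heterogeneity at magnitude 0.5) and tests both areas:

```
AIT: stress(shape-att vs location-att) = 0.8849, bootstrap p = 0.0000 -> warped
LIP: stress(shape-att vs location-att) = 0.0102, bootstrap p = 0.6355 -> not significantly warped
```

The AIT maps disagree far beyond what trial noise can produce (none of 2000
shuffle-split resamples reached the observed stress), while the unwarped
LIP maps differ only at noise level.  The other examples cover session
simulation (`01`), gain estimation against ground truth (`02`, median
relative error ≈ 0.05 under Poisson noise at 12 repetitions), distance
geometry and MDS (`03` — e.g. 2-D captures ~90% of variance in the LIP
location space), and the power analysis (`05`, standardized minimal effect
0.52945 at n = 28).

A thin CLI wraps the same library:

```bash
attnspace simulate --seed 1 --out session/
attnspace run --table session/trials.csv --out report.json
attnspace bootstrap --table session/trials.csv --area AIT --space shape \
    --pair shape_attention,location_attention --n-boot 10000 --seed 7
```

`report.json` contains, per area and decode space, the mean response
distances per task, pairwise percent changes with rank-sum p-values,
2-D embeddings with variance explained, convex-hull summaries, Procrustes
stress per task pair with bootstrap p-values, and (location space) the
stress between each MDS map and the physical stimulus ring.

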