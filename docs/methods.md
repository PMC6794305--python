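# Methods

This note documents the models and procedures implemented in `emocert`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Band-wise decomposition and chimera synthesis

A band-limited signal `x(t)` restricted to 80–4400 Hz is split into `nb`
contiguous frequency bands (`nb ∈ {1, 2, 4, 8, 16, 32, 64}`). Within band
`k`, the analytic signal `z_k(t) = x_k(t) + i·H[x_k](t)` (Hilbert transform
`H`) factors the band into

* envelope `ENV_k(t) = |z_k(t)|` — slowly varying, non-negative;
* fine structure `FIS_k(t) = cos(arg z_k(t))` — a unit-amplitude carrier.

Since `|z| cos(arg z) = Re z = x_k`, the product `ENV_k · FIS_k` reconstructs
band `k` exactly. A chimera between sources A and B is
`Σ_k ENV_X[k] · FIS_Y[k]` with `(X, Y)` assigned by the carrier domain; it
carries one source's temporal-amplitude cues and the other's carrier cues.
At exact envelope zeros the phase is undefined; both components are defined
as 0 there, which keeps the product identity exact.

**Band spacing.** Edges are logarithmically spaced,
`edges[k] = 80 · 55^(k/nb)` Hz (55 = 4400/80), i.e. constant frequency
ratio — the conventional choice for cochlear-style chimera filterbanks over
a wide range.

**Filters.** All band filtering is zero-phase spectral windowing: each band
window is the difference of two monotone raised-cosine steps, one per edge,
and adjacent bands share the step at their common edge. Consequently the
band windows sum *exactly* to the 80–4400 Hz band-limit window (telescoping
sum), and self-chimera reconstruction is exact up to the RMS renormalization
— this is why IIR band-pass banks (whose squared-magnitude responses dip at
crossovers) were rejected: a Butterworth bank of order 4–8 leaves 2–5%
broadband reconstruction error at high band counts. Outer transitions have
half-width 2% of the edge frequency; inner crossovers use
`min(2% of edge, 1/8 of the narrower adjacent band width)` so that narrow
high-`nb` bands do not lose crossover power (white-noise energy ratio at
`nb = 64` is ≈ 0.94, within the 10% conservation tolerance).

**Normalization.** Chimera output is RMS-matched to the mean RMS of its two
sources, then peak-clipped to |x| ≤ 1 with a warning if matching overshoots.
Numerical tolerances are evaluated on the interior 80% of samples; the outer
10% on each side is excluded as edge-transient guard (the spectral filters
have no group delay, but circular-FFT edge effects and envelope onsets live
there).

## Sparse-sampling design

One fMRI volume (TA ≈ 1 s) is acquired per block, separated from the 3-s
stimulus by a ≈100 ms gap and followed by silence filling the block to
TR = 15 s. The finalized run is 74 blocks — 40 stimulus + 34 silent
(45.95% silent) — for 18 min 30 s. Stimulus blocks form 8 sets of 5
like-category presentations (the unit of analysis is the aggregation of
alike stimuli); silent gaps of 3–4 blocks surround the sets. Two runs per
subject use counterbalanced button maps (run 2 reverses run 1).

Design choices where the timing was underdetermined:

* 34 silent blocks cannot be split into 8 gaps of 3–4, so the schedule uses
  9 gaps (a leading gap plus one per set), 7×4 + 2×3, with the gap-of-3
  positions drawn from the seed.
* The nominal ≈10 s post-stimulus silence is approximate; the scheduler
  always closes each block exactly at TR. A protocol whose nominal segments
  overflow TR by more than 0.5 s (this happens for some gap-delay
  optimization trials at TR = 13 s) is flagged `silence_truncated` rather
  than rejected; only `stimulus + gap + TA > TR` is a hard error.
* The ≥ 2-minute separation rule applies between *sets* of the same
  category; within a set, same-category blocks are deliberately contiguous.
* The gap-delay / TR optimization sweep (gap 1–3.5 s, TR 10–13 s) is exposed
  only as a protocol grid generator; evaluating HRF robustness on real BOLD
  data is out of scope.

## 2IFC psychometrics

Each response (happy/sad) is scored against the label of the original
excerpt the stimulus derives from. Per-subject cell means are aggregated to
a group mean ± SD across subjects (a switch selects across-stimuli SD; the
dispersion unit is genuinely ambiguous in practice, and across-subjects is
the repeated-measures-consistent choice). Certainty classes: original →
*certain*; percent identification < 50 → *chance*; [50, 80) → *uncertain*;
altered stimuli ≥ 80 are flagged `certain_equivalent` — the class partition
must be total, but that region never occurs in the studied regime, so no
established name is invented for it.

The category-change summary is the mean absolute identification change over
consecutive ladder levels (original–8, 8–32, 32–64).

One-way repeated-measures ANOVA (levels within subject) uses the closed-form
F with the subject × level interaction as error term,
`df = (k−1), (k−1)(n−1)`; it is implemented directly for simulation speed
and cross-checked against `statsmodels` AnovaRM in the test suite. Follow-up
paired t-tests compare each altered level to the original, optionally
Bonferroni-corrected.

## Hemispheric laterality

Inputs are group t-maps already registered to a *symmetric* template
(registration itself is upstream and out of scope; the module validates the
space tag and an even left–right extent). The pipeline is:

1. **Sign restriction** — activation keeps `t > 0` (negatives zeroed),
   deactivation keeps `t < 0`. Activation + deactivation reconstruct the
   input exactly.
2. **Folding** — the volume is split at the midline and the right half is
   mirrored, so co-indexed voxels are left/right homologues. Default
   orientation is neurological (+x = right); a flag declares radiological
   data.
3. **Difference** — `R − L` on the restricted, folded maps. On activation
   maps this equals `|R| − |L|` (positive ⇒ right-lateralized activation);
   on deactivation maps a more-deactivated right hemisphere gives a
   *negative* value (negative ⇒ right-lateralized deactivation). The
   convention string is recorded on every laterality volume.

ROI statistics use probabilistic masks thresholded at 0.95; a summary with
fewer than 100 suprathreshold voxels is marked invalid (the boundary is
exact: 99 invalid, 100 valid). Leaning uses the mode's sign convention with
a 1e−9 zero tolerance. The sex contrast is the voxelwise
`mean |t_F| − mean |t_M|` with per-ROI two-sample t-tests on subject ROI
means.

## Modulation and weighted modulation

For a ROI trajectory `t = (t_org, t_8, t_32, t_64)`:

* percent change from original: `100 · |t_level − t_org| / |t_org|`;
* weighted modulation:
  `WM = mean_i(|Δt_i| · |Δpct_i|) / |t_org|`,
  with `Δt_i`, `Δpct_i` the consecutive-pair changes of the t-trajectory and
  the psychometric ladder.

The prose definition of the composite statistic admits several operation
orders; this package's reading was fixed by its invariants: WM is zero iff
either ladder is flat, invariant under rescaling the trajectory by any
`c > 0` and under flipping its sign, and undefined (flagged, never infinite)
when `t_org = 0`. An alternative order that divides by the mean `|Δt|` fails
the scale-invariance property and cannot separate a strongly modulated ROI
from a flat one, so it was rejected. All intermediates (`|Δt|` ladder,
`|Δpct|` ladder, normalizer) are exposed on the result object so alternative
compositions are one-liners. An independently coded straight-line oracle in
the tests pins the implemented reading to 1e−12 on 1000 random trajectories.

## Synthetic-data generator

The generator's defaults *are* the study conditions, not tuning knobs:

* **Audio** — 3-s, 44.1 kHz mono excerpts band-limited to 80–4400 Hz;
  happy = 8 notes/s C-major arpeggio with percussive envelopes, sad = slow
  sustained A-minor chord with a swell. These are schematic tempo/mode
  proxies: sufficient to exercise the signal path, with no claim of
  perceptual validity.
* **Psychometrics** — a 75-subject cohort responds to the 224-stimulus
  catalog with `P(correct)` from a logistic decline in `log2(nb)` anchored
  so the curve passes through the baseline at the original and through the
  value making the mean ladder change exactly 15.55 points (happy,
  95.55 → 48.90) and 12.00 points (sad, 95.00 → 59.00). The sad curve
  therefore ends above chance — consistent with sad identification declining
  less across decomposition. Slope `k = 1.1`/octave and midpoint `m = 3.5`
  octaves put the steepest decline near 8–16 bands.
* **Volumes** — 64 × 64 × 40 grids (voxel 2 × 2 × 3 mm; the grid is reduced
  from acquisition scale for desk-scale testing, metadata preserved) with
  N(0, 0.5) voxel noise. The synthetic atlas plants 6 mirror-symmetric
  ellipsoidal subdivisions per hemisphere (Te1.0/Te1.1/Te1.2 for Heschl's
  gyrus; LB/CM/SP for the amygdala), each ≥ 100 voxels at the 0.95
  threshold. Amygdala t-ladders rise with uncertainty and reverse to
  deactivation at the chance level (e.g. happy/right 1.0 → 2.8 → 3.6 → −1.4,
  placing the mean percent change from original in the ≈ 200% regime);
  Heschl's gyrus is flat (right 3.0, left 2.8); right−left differences are
  planted per subdivision, and an optional +0.8 female right-amygdala boost
  applies at the uncertain levels only. Every planted value is emitted in a
  ground-truth ledger so tests recover rather than re-derive it.

What the generator does **not** emulate: BOLD time series, HRF convolution,
scanner noise spectra, spatial autocorrelation of fMRI noise, inter-subject
anatomical variability, or real musical timbre. Passing recovery tests
therefore demonstrates correctness of the statistics on data satisfying the
model's assumptions, not robustness to real-data violations of them.

## Problem sizes and numerical choices

The test suite exercises full-scale signals (3 s at 44.1 kHz, up to 64
bands) in the acceptance path and shorter excerpts in property tests.
Recovery uses 100 generator seeds (laterality), one 75-subject cohort
(psychometrics) and 200 simulations (weighted-modulation ranking);
calibration uses 1000 null and 200 powered repeated-measures simulations at
16 subjects × 4 levels × 20 trials per cell. `scripts/acceptance.py` uses 50
laterality seeds and otherwise the same sizes. Tolerances follow the
invariants stated above: reconstruction < 2% relative RMSE on interior
samples, envelope-oracle correlation > 0.99, energy conservation within 10%,
psychometric recovery within 3 points per cell, laterality recovery within
3 SE, type-I error 0.05 ± 0.02.

## Known limitations

* Registration to the symmetric template, GLM fitting, motion correction and
  cluster correction are consumed upstream, never reimplemented.
* The weighted-modulation operation order is one defensible reading of an
  ambiguous verbal definition (see above); the exposed intermediates make
  alternatives trivial to compute.
* Certainty classes at ≥ 80% identification for altered stimuli have no
  established name and are flagged rather than classified.
* Cohort-specific inferential statistics on human data are not reproducible
  from synthetic data and are not claimed; only statistic definitions,
  their calibration and their behavior under planted effects are tested.
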