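# emocert

Analysis toolkit for studying the *threshold of emotion* in music: how the
certainty of a happy/sad percept degrades as an excerpt's fine structure and
envelope are progressively decomposed, and how amygdala and auditory-cortex
responses lateralize with that uncertainty.

The package is aimed at auditory/affective neuroscientists who need the
bespoke computations of such an experiment as tested, reusable code:

* **`emocert.chimera`** — band-wise Hilbert decomposition and auditory
  chimera synthesis. A band-limited signal is split into `nb` log-spaced
  bands (80–4400 Hz, `nb ∈ {2,…,64}`); per band the analytic signal gives the
  envelope `ENV_k = |z_k|` and fine structure `FIS_k = cos(arg z_k)`, and a
  chimera is `Σ_k ENV_X[k]·FIS_Y[k]` with the two components taken from
  different sources. Higher `nb` moves spectral detail from FIS into the
  envelopes, degrading emotional certainty.
* **`emocert.design`** — sparse-sampling fMRI protocol arithmetic and
  seeded block schedules (74 blocks/run: 40 stimulus + 34 silent at
  TR = 15 s), stimulus catalogs, BIDS-style events export.
* **`emocert.psychometrics`** — two-interval forced-choice identification
  tables, certainty classes (certain / uncertain < 80% / chance < 50%),
  category-change summaries, repeated-measures ANOVA.
* **`emocert.laterality`** — sign-restricted, hemisphere-folded `R − L`
  laterality maps of t-volumes in a symmetric grid, probabilistic-ROI
  extraction (0.95 threshold, ≥ 100 voxels), sex contrasts.
* **`emocert.modulation`** — the weighted-modulation statistic
  `WM = mean_i(|Δt_i|·|Δpct_i|) / |t_org|` coupling ROI t-value changes to
  psychophysical identification changes across the decomposition ladder.
* **`emocert.synthgen`** — synthetic excerpts, response tables, atlases and
  t-maps with planted ground truth, so the entire pipeline runs and is
  validated without any external data.

See `docs/methods.md` for the models, conventions and defaults in detail.

## Worked example

```python
import emocert as ec
from emocert import chimera as ch, design as dz, psychometrics as psy, \
    laterality as lat, modulation as mo
from emocert.synthgen import (SynthConfig, gen_excerpts, gen_responses,
                              gen_atlas, gen_tmaps, identification_probability)

cfg = SynthConfig(seed=42, n_subjects=75)

# chimera: happy fine structure carrying the sad excerpt's envelopes
happy, sad = gen_excerpts(cfg)
out = ch.synthesize_chimera(happy, sad, ch.ChimeraSpec("FIS", nb=8))
# -> chimera: label=happy, nb=8, duration=3.0 s, rms=0.221

# sparse-sampling protocol arithmetic
protocol = dz.build_protocol(15, 1, 3, 0.1, 10, 40, 34)
# -> 74 blocks, 45.95% silent, run time 1110 s

# psychometrics on a simulated 75-subject cohort, 224-stimulus catalog
table = psy.percent_identification(gen_responses(dz.enumerate_catalog(32, 6, 1), cfg))
change = psy.category_change(table)
# -> identification, happy: original=96.2  8=76.2  32=55.1  64=49.1
# -> mean category change: happy=15.69, sad=12.69

# hemispheric laterality of a synthetic t-map with planted R-L asymmetry
atlas = gen_atlas(cfg)
volumes, truth = gen_tmaps(cfg, atlas, levels=(32,), emotions=("happy",))
lmap = lat.laterality_map(volumes[("happy", 32)], "activation")
mask = next(m for m in atlas if m.name == "LB" and m.hemisphere == "left")
roi = lat.extract_roi(lmap, mask)
# -> LB laterality at 32 nb: mean=0.650 (planted 0.7), leaning=right, n=199

# weighted modulation ranks the rise-then-reverse amygdala above flat HG
pct = [identification_probability("happy", nb, cfg) for nb in psy.DEFAULT_LADDER]
amg = mo.ROITrajectory("AMG-LB", "right", "happy", cfg.amg_ladder[("happy", "right")])
hg = mo.ROITrajectory("HG-Te1.0", "right", "happy", (3.0, 3.0, 3.0, 3.0))
# -> weighted modulation: AMG=25.46, HG=0.00
```

Reading the numbers: the identification curve declines from near-ceiling at
the original excerpt toward chance at 64 bands, with a mean ladder change of
≈ 15.7 points for happy stimuli (the planted value is 15.55). The laterality
map recovers the planted right-minus-left amygdala difference of 0.7 within
sampling noise, leaning right. The weighted-modulation statistic is large
for the amygdala trajectory (which rises with uncertainty and reverses to
deactivation at chance) and exactly zero for the flat auditory-cortex
trajectory.

A `emocert` console script exposes the same operations from the shell, e.g.

```sh
emocert design protocol --tr 15 --stim 40 --silent 34
emocert chimera synth --nb 32 --carrier fis a.wav b.wav out.wav
emocert synthgen all --seed 42 --out fixtures/
```

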