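# stereorsa

Does what we *believe* about people shape what we *see* in their faces —
and does that shaping depend on live feedback from frontal cortex?
`stereorsa` implements, end to end, the analysis pipeline of a
backward-masking fMRI paradigm built around that question: subjects whose
stereotypes link men with anger and women with happiness show mouse
trajectories that drift toward the stereotype-congruent response, their
ventral-temporal multi-voxel patterns mirror those subjective biases when
faces are visible, and the biasing disappears under backward masking —
together with orbitofrontal–fusiform connectivity.

The package is aimed at cognitive-neuroimaging researchers who want a
tested, desk-scale implementation of this analysis family: mouse-tracking
deviation metrics, representational similarity analysis (RSA) with
covariate control, searchlight mapping with permutation inference, and
psychophysiological interaction (PPI) connectivity.  Because the original
behavioral and imaging data are not deposited, a first-class synthetic
generator plants every effect with known ground truth, so each stage is
verified by analytic identities and parameter recovery rather than by
eyeballing.

## The statistics at the core

- **Stereotype strength** from 4 × 30 descriptor ratings:
  `s = ([r(angry,male) + r(happy,female)] − [r(angry,female) + r(happy,male)]) / 2 ∈ [−2, 2]`.
- **Maximum deviation (MD)**: the signed perpendicular deviation of a
  mouse trajectory from the direct start→response line at its farthest
  point, positive toward the unchosen response; condition-wise
  `MD/max(MD)` values build a 4 × 4 **subjective dissimilarity matrix**
  (1 − Pearson r between category-similarity vectors).
- **Deviation model**: trial MD ~ gender × emotion × stereotype (GEE,
  exchangeable working correlation, sandwich SEs; gender/emotion coded
  ±0.5).
- **d′** = z(hits) − z(false alarms) with log-linear correction; chance
  band ±1.74.
- **Pattern estimation**: 2000 ms boxcars ⊛ gamma HRF
  (h(t) ∝ (t/pq)^p e^{p−t/q}), per-voxel OLS t maps, run-averaged and
  z-normalized.
- **RSA**: Spearman rank correlation between vectorized DMs, or rank
  regression of the neural DM on a subject's own subjective DM while
  controlling the group-average DM; Fisher-z group t tests.
- **Searchlight**: 123-voxel spheres (radius 3), local regression-RSA
  betas, 6-mm smoothing, sign-flip max-statistic permutation for
  family-wise error control.
- **PPI**: deconvolve the seed BOLD against the HRF, form
  seed × condition (masked = −1, unmasked = +1), reconvolve, fit
  [seed, condition, interaction]; the interaction beta per subject is
  correlated (one-tailed) with the subject's [unmasked − masked] RSA-beta
  difference.

See `docs/methods.md` for assumptions, parameter defaults and numerical
conventions.

## Worked example

Run the full synthetic-to-report pipeline (24 subjects, desk scale, about
half a minute on one CPU):

```bash
stereorsa run --seed 0 --out results/
```

which prints:

```
stereorsa pipeline summary
==========================
design: 140 faces, 280 mouse-tracking trials, 120 rating trials, 2000 ms trials
stereotype score: planted mean 0.614, recovered 0.645
gender x emotion B = -0.1531 (planted -0.1500) [recovered]
ROI RSA beta: unmasked 0.637 (p=0.0000), masked 0.007 (p=0.9294) [recovered]
searchlight: 647 significant voxels, 256 inside the planted region
PPI interaction beta 0.137 (p=0.0000) [recovered]
connectivity-representation link r = 0.594, one-tailed p = 0.0018 [recovered]
```

Reading the lines in order: the generator reproduced the printed design
constants (140 faces, 280 categorization trials, 120 rating trials,
2000 ms trials); the stereotype scores recovered the planted population
mean; the deviation GEE recovered the planted gender × emotion
coefficient −0.15 (stereotype-incongruent faces deviate more); regression
RSA found the planted subject-specific representational structure in the
unmasked arm (mean beta 0.64) and none in the masked arm (0.01), each
controlling the group-average DM; the searchlight localized the planted
signal sphere; the PPI interaction beta was positive (coupling stronger
unmasked); and subjects whose connectivity modulation was weaker also
showed less masking-induced representational loss (link r = 0.59).  A
machine-readable `results/results.json` carries every number printed and
more (simple slopes, d′ table, exclusion report, permutation threshold).

Module-level commands (`stereorsa simulate`, `stereorsa mousetrack`,
`stereorsa stereotype`, `stereorsa dprime`) expose the stages separately;
the same functionality is available as a library:

```python
from stereorsa import mousetracking as mt
from stereorsa.synthetic import GroundTruth, gen_trajectories

trials = gen_trajectories(subject_bias, GroundTruth(), seed=0)
metrics = mt.metrics_table(trials.t_ms, trials.xy,
                           trials.trials["response_side"].to_numpy())
dms, group_dm = mt.subject_dms(trials.trials.join(metrics))
```

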