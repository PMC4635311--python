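# cuefuse

Analysis pipeline for studying how the developing visual system combines
two depth cues — binocular disparity and relative motion — in behavior and
in fMRI activation patterns.

Adults fuse redundant depth cues into a single estimate whose variance is
lower than either cue alone; children appear to gain this ability only
around ages 10–11. Two signatures distinguish a *fusion* readout
(reliability-weighted averaging) from an *independence* readout (separate
per-cue channels, whose combined discriminability is the quadratic sum
√(S_D² + S_M²) and which ignores the relative sign of the cues):

1. **Conflict cost** — `index1 = S_DM − S_D−M`: fusion averages opposed cues
   toward zero, so sensitivity collapses under cue conflict; independence is
   unaffected.
2. **Beyond quadratic sum** — `index2 = S_DM − √(S_D² + S_M²)`: a fusion
   mechanism is handicapped in single-cue conditions (the flat cue dilutes
   the informative one), so its consistent-cue performance exceeds the
   quadratic-sum prediction built from those handicapped single-cue scores.

Both indices are identically zero for an independence observer and strictly
positive for a fusion observer. `cuefuse` implements the full chain on
synthetic data with known ground truth:

- **`observer_models`** — ideal observers in the 2-D disparity–motion depth
  space generating 2AFC sessions (90 trials/condition: 15 × 6 levels), with
  closed-form sensitivity predictions `1/σ` as oracles.
- **`psychometrics`** — trial-wise maximum-likelihood cumulative-Gaussian
  fits, the cohort exclusion rules (R² < 0.7, |bias| > 3 arcmin, > 5 SD
  index outliers), both integration indices, age-binned paired t tests, and
  constant/linear/exponential developmental-curve selection by AIC.
- **`synthetic_fmri`** — block-design BOLD simulator (TR 2 s, 8-volume
  blocks, 3 blocks per condition × depth per run, 6 runs, 16-s baselines)
  whose voxels encode disparity, motion, and optionally fused-depth
  channels.
- **`mvpa`** — the decoding pipeline: 400-voxel-style t-map selection,
  per-run z-scoring, 2-TR hemodynamic shift, 8-volume block patterns with
  mean-centering, linear SVM (C = 1) near/far classification with
  leave-one-run-out cross-validation, `d′ = 2·erfinv(2·accuracy − 1)`,
  1000-shuffle permutation nulls, and spherical-searchlight maps of both
  indices.
- **`pipeline`** / **`cli`** — one-command behavioral and fMRI analyses over
  seeded synthetic cohorts whose readout mechanism switches at 10.5 years.

## Worked example

The numbered drivers under `analysis/` run the two end-to-end analyses:

```bash
python analysis/01_simulate_cohort.py --seed 1      # 140 simulated children
python analysis/02_behavioral_analysis.py           # fits, exclusions, tests
python analysis/03_fmri_decoding.py                 # synthetic scans + SVM
python analysis/04_searchlight.py                   # planted-cluster mapping
```

A run of the behavioral analysis prints (seed 1):

```
included 103 of 140 subjects (37 excluded)

age-bin paired tests (both fusion criteria):
      bin       test  n  mean_diff         t            p
  6.0-8.5 criterion1 22  -0.025362 -0.086167 9.321502e-01
  6.0-8.5 criterion2 22   0.177271  0.892916 3.820205e-01
 8.5-10.5 criterion1 49  -0.175311 -1.427059 1.600360e-01
 8.5-10.5 criterion2 49  -0.302487 -2.284009 2.683575e-02
10.5-12.0 criterion1 32   1.983481 15.670445 2.787583e-16
10.5-12.0 criterion2 32   0.883176  6.453097 3.403379e-07

index1 age trend: best model = exponential, half-rise age = 11.055...
```

Read: only the oldest bin shows positive paired differences for both
criteria (sensitivities in normalized depth units⁻¹, where the
consistent-cue standard is 1.0 ≙ 8 arcmin ≙ 0.25°); the younger bins sit at
or below zero — the middle bin's criterion 2 even dips significantly
negative, a finite-sample quadratic-sum inflation that non-fusing cohorts
genuinely exhibit. The age trend of the conflict-cost index is best
described by an exponential whose transition midpoint falls beside the
10.5-year mechanism switch the cohort was generated with. The fMRI driver
prints the analogous decoding-level comparison (group difference in both
d′ indices between younger/fused-gain-0 and older/fused-gain-positive
subjects).

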