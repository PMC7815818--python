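# envtrack

Cortical tracking of the continuous-speech envelope, as a tested, reusable
pipeline:

- **envelope** — multiband stimulus model: a bank of 16 gammatone filters
  uniformly spaced on the ERB scale (250–8000 Hz, Slaney all-pole design),
  per-band Hilbert envelopes compressed with a 0.6 power law, resampled to the
  EEG clock (128 Hz) and differentiated into signed envelope *edges*.
- **preprocess** — zero-phase Butterworth band filtering (full 1–8 Hz, delta
  1–4 Hz, theta 4–8 Hz), epoching (−5 to 70 s around stimulus onset),
  common-average referencing, and pooled per-subject z-scoring. Minimal EDF
  and BrainVision readers convert recordings into the portable HDF5+JSON
  container.
- **trf** — forward temporal response functions: time-lagged design matrices
  (−100 to 450 ms), ridge regression with an unpenalized intercept,
  leave-one-track-out cross-validation with per-subject ridge-parameter
  selection, per-track/per-channel Pearson prediction accuracies ("cortical
  tracking metric" = grand mean), and permutation chance levels (97.5th
  percentile of the metric under derangement re-pairings of stimulus and EEG
  tracks).
- **groupstats** — EEG SNR proxy (post/pre-onset RMS ratio), rationalized
  arcsine (RAU) transform of comprehension scores, 2×2 mixed ANOVA with
  generalized eta squared, and cluster-based permutation comparison of TRF
  time courses using Wilcoxon rank-sum statistics.
- **synthdata** — speech-like stimuli (pink noise amplitude-modulated at a
  quasi-periodic syllable rate) and simulated EEG whose signal component is
  the lagged convolution of the envelope edges with a known ground-truth
  kernel (group-specific theta-band gain) plus 1/f noise — so every stage has
  a parameter-recovery test.
- **pipeline** — end-to-end orchestration with YAML config and a
  reproducibility manifest.

## Test

```sh
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, a property-based battery
(oracle equivalence, kernel recovery, chance-level and cluster-test
calibration, the theta/delta group dissociation) that takes several minutes.

## CLI

```sh
envtrack simulate --config sim.yaml --out simdir --seed 1
envtrack envelope --wav track.wav --fs-out 128 --bands 16 --flow 250 --fhigh 8000 --out track.env
envtrack preprocess --in sub01.h5 --band theta --out sub01.theta.h5
envtrack fit --eeg sub01.theta.h5 --env track00.env --env track01.env --env track02.env \
    --lags -100 450 --lambda auto --perms 1000 --seed 7 --out sub01.theta.trf
envtrack stats anova results.csv --band theta
envtrack stats cluster groupA/ groupB/ --electrode Fz --perms 1000 --seed 7
envtrack run --config study.yaml
```

A demo study config is in `examples/demo_study.yaml`.

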