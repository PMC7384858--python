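# mirrorpop

Population analyses of motor-cortical activity across action **execution**,
**observation**, and **withholding (NoGo)**, packaged as a tested, seeded,
end-to-end pipeline:

- soft-normalized, multi-event-aligned population rate tensors
  (10 ms bins, 50 ms Gaussian kernel, Go/HPR/DO stitching, range or absmax
  soft-normalization with a +5 spikes/s constant);
- single-neuron mirror-neuron classification (2-way EPOCH × GRASP ANOVA
  with post-hoc comparisons; F-F/F-S/S-F/S-S categories);
- cross-condition epoch correlations with shuffle nulls and cross-temporal
  correlation matrices (50 ms unsmoothed bins);
- **PCA subspace alignment**: alignment index of target activity in a
  reference subspace, random-orthonormal (Haar) null distributions
  (10,000 draws), and paired cross-grasp bootstraps (1000 draws, 50%
  neuron subsamples);
- pseudo-population decoding with a maximum-correlation-coefficient
  classifier, resampled 10-fold cross-validation, label-permutation nulls,
  and a ≥5-consecutive-bin cluster rule;
- EMG conditioning, baseline-referenced trial distances, iterative
  contaminated-trial exclusion, and EMG median splits;
- a synthetic-session generator with recorded ground truth (planted
  subspace angles via arccos(√ρ), condition gains, lognormal event times,
  inhomogeneous-Poisson spiking, execution-locked EMG bursts, injectable
  contamination) used for parameter-recovery and calibration tests.

## Quick start

```sh
# write a synthetic session (HDF5) plus its ground-truth JSON
mirrorpop simulate --seed 1 --out scratch/session.h5

# run every stage on a synthetic session
mirrorpop run-all --seed 1 --out scratch/run1

# or stage by stage / on an existing session file
mirrorpop subspace --session scratch/session.h5 --out scratch/sub1
```

`run-all` writes, per stage: `events.csv`, `behaviour.csv`,
`classification.csv`, `epoch_correlations.csv`, `subspace.json`,
`trajectories.csv`, `decoding_accuracy.csv`, `decoding.json`,
`exclusion_report.json`, and a `manifest.json` of SHA-256 content hashes.
Identical config + seed ⇒ identical manifests. Stage parameters live in a
single YAML config (see `mirrorpop.cli.DEFAULT_CONFIG` for defaults, which
match the reference analysis parameters).

Library use mirrors the CLI:

```python
from mirrorpop import synthetic_data as sd, preprocess as pp, subspace as ss

cfg = sd.GroundTruthConfig(n_neurons=40, trials_per_condition=20)
bundle, truth = sd.generate_session(cfg, seed=1)
tensors = pp.population_rates(bundle)          # (condition, grasp) -> RateTensor
suite = ss.condition_projection_suite(tensors) # Fig. 7/9-style analyses
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (alignment-index
identities and brute-force equality, cos²θ recovery under Poisson noise,
Haar-null calibration, M1-like/F5-like population signatures, decoder
calibration, EMG-exclusion sensitivity/specificity, ANOVA type-I
calibration). The full suite runs in ~6 minutes on one CPU.

## Layout

```
src/mirrorpop/
  dataio.py          session data model, HDF5/CSV I/O, deposit adapter
  synthetic_data.py  seeded generator with recorded ground truth
  preprocess.py      binning, smoothing, alignment, normalization, behaviour
  emg.py             envelopes, distances, iterative exclusion, median split
  units.py           ANOVA task modulation, mirror-neuron categories
  correlation.py     epoch correlations, shuffle nulls, cross-temporal matrix
  subspace.py        PCA fitting, alignment index, Haar nulls, bootstraps
  decoding.py        pseudo-populations, max-correlation decoder, clusters
  cli.py             click pipeline (simulate ... run-all)
  plotting.py        diagnostic figures
```

Large/binary outputs belong under `scratch/` (ignored).
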