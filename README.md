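# eegscreen

A tested pipeline for three-class dementia screening (healthy controls vs.
mild cognitive impairment vs. Alzheimer's disease) from resting-state EEG.
It covers the full analysis chain:

1. **synthetic** — three-group EEG cohort generator (narrowband oscillators
   per frequency band + band-limited 1/f background noise, per-subject
   parameter jitter), so every downstream stage is testable without real
   recordings.
2. **preprocessing** — zero-phase 1–70 Hz Hamming-window FIR band-pass,
   50 Hz Butterworth notch, segmentation into non-overlapping 5-s epochs.
3. **spectral** — normalized PSD (Welch) and relative power in six bands,
   median frequency, individual alpha frequency (4–15 Hz), spectral entropy.
4. **nonlinear** — Lempel–Ziv complexity, central tendency measure, sample
   entropy, fuzzy entropy, auto-mutual information (numba-accelerated), plus
   Kruskal–Wallis grid selection of their parameters.
5. **selection** — fast correlation-based filter: symmetrical-uncertainty
   relevance ranking and redundancy pruning over MDL-discretized features.
6. **classify** — LDA/QDA (Gaussian discriminants) and a one-hidden-layer
   sigmoid MLP with weight decay, including leave-one-subject-out
   hyperparameter tuning with restart averaging.
7. **evaluate** — trial-majority-vote subject diagnosis, 3×3 confusion
   matrices, Cohen's kappa, overall accuracy, and one-vs-all
   Se/Sp/Acc/PPV/NPV blocks.
8. **pipeline / cli** — end-to-end orchestration from one seeded config.

Features are computed per epoch and channel and averaged over channels; one
row per 5-s trial with 14 named feature columns.

## CLI

Each stage is exposed as a subcommand of `eegscreen`:

```sh
eegscreen simulate --config cohort.yaml --out data/ --seed 7
eegscreen preprocess --in raw/ --fs 200 --epoch 5 --out epoched/
eegscreen extract --in epoched/ --out features.csv
eegscreen select --features train.csv --out selection.json
eegscreen train --features train.csv --selection selection.json --model mlp --out model.json
eegscreen predict --model model.json --features test.csv --out trials.csv
eegscreen evaluate --trials trials.csv --out report.json
eegscreen run --config run.yaml --out results/
```

Cohorts are stored as one `channels × samples` CSV matrix per trial plus a
`manifest.csv`; models and selection results serialize to JSON. A minimal
`run.yaml`:

```yaml
cohort:
  n_subjects_per_group: 37
  n_channels: 19
n_train_per_group: 20
models: [LDA, QDA, MLP]
mlp:
  tune: true
  n_restarts: 30
seed: 7
```

## Notes

- The tolerance `r` of SampEn/FuzzyEn is specified as a multiple of the
  per-epoch, per-channel standard deviation; CTM's radius is applied to
  z-scored epochs by default.
- Subject-level splits are stratified by group and seeded; feature
  selection, standardization statistics and hyperparameter tuning only ever
  see training rows.
- Epochs on which sample entropy is undefined (no template matches) are
  excluded from that feature's channel average with a warning.
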