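# eegtopo

Classification of two-class multichannel EEG via topographic RGB image
sequences and a hybrid CNN-LSTM, with classical baselines, a tenfold
cross-validation harness, and channelwise group statistics.

The pipeline:

1. **signal_prep** — channel pruning (e.g. the four ocular channels),
   segmentation into 1.4 s trials, 400 ms sliding windows with 200 ms step
   (6 per trial), and zero-phase Butterworth decomposition into theta
   (4–7 Hz), alpha (8–13 Hz), and beta (14–30 Hz) bands.
2. **features** — per window, channel, and band: **fuzzy entropy**
   (m = 2, n = 2, r = 0.25·SD; exponential membership of pairwise Chebyshev
   distances between baseline-removed embeddings) or **FFT band amplitude**
   (hand-built radix-2 decimation-in-frequency butterfly for power-of-two
   lengths, direct DFT otherwise; mean in-band |X(k)|).
3. **topomap** — azimuthal equidistant projection of 3-D electrode
   positions (apex tangent point), Clough-Tocher interpolation onto a
   32×32 mesh per band, and stacking as RGB (theta→R, alpha→G, beta→B)
   with per-band min-max normalization fitted on the training split.
4. **classify** — a NumPy implementation of a time-distributed VGG-style
   CNN (configs A–D: stacks of 3×3/stride-1/pad-1 convs + 2×2 max pools +
   FC-512) feeding a 128-unit LSTM and a softmax head; Adam
   (lr 1e-3, β = 0.9/0.999), batch 32, dropout 0.5; tenfold CV with an
   8:1:1 train/validation/test split per fold; SVM / KNN / logistic
   regression baselines on flattened feature frames.
5. **groupstats** — channelwise two-sided Welch t-maps with
   Benjamini-Hochberg FDR and Bonferroni correction, plus a Pearson helper.
6. **synth_eeg** — a deterministic synthetic cohort generator
   (band-limited oscillations + pink noise; class-1 recordings receive
   frontally weighted broadband noise and a theta amplitude factor) so the
   whole chain is testable without clinical data.
7. **cli_io** — delimited-matrix + JSON-sidecar and minimal EDF recording
   I/O, cohort manifests, JSON pipeline configs, and the CLI.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (literal fuzzy-entropy double loop,
O(N²) DFT, closed-form Welch t, hand LSTM step), property tests
(hypothesis), and `tests/test_acceptance.py` with one test per acceptance
criterion. The synthetic-recovery criterion trains the full config-C
network on two 800-trial cohorts (effect and null) and takes ~12 minutes
on one CPU; the rest of the suite finishes in under a minute.

## CLI

```sh
eegtopo simulate --out cohort/ --subjects 10 --trials 20 --complexity-effect 0.8 --seed 1
eegtopo features --input cohort/ --feature fuzzyen --out feats.npz
eegtopo images   --input cohort/ --feature fuzzyen --out images.npz
eegtopo crossval --input cohort/ --model C --feature fuzzyen --out results/
eegtopo baselines --input cohort/ --method svm --feature fuzzyen --out results/
eegtopo stats    --input cohort/ --feature fuzzyen --out results/
eegtopo run      --config pipeline.json
```

All stages are deterministic given the config seed. `run` executes the
configured pipeline end to end and writes `metrics.json` (per-fold and
summary accuracies, baselines, stat map) and `comparison.tsv` (method ×
feature accuracy table) under the output directory.

A pipeline config is JSON mirroring the defaults, e.g.:

```json
{
  "synth": {"n_subjects_per_class": 10, "trials_per_subject": 20,
             "complexity_effect": 0.8},
  "feature": "fuzzyen",
  "model": "C",
  "train": {"epochs": 2, "seed": 0},
  "baselines": ["svm", "knn", "logreg"],
  "cv_k": 10,
  "output_dir": "out",
  "seed": 0
}
```

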