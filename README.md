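# conveegnn

Predicting memory performance from single-trial EEG.

In subsequent-memory experiments, a participant hears a cue, then a word, and
is later tested on which words they remember.  The EEG around word
presentation differs systematically between subsequently remembered and
subsequently forgotten words (the *subsequent memory effect*): remembered
words show more negative-going pre-stimulus and more positive-going
during-stimulus ERPs over frontal sites.  This package implements
**ConvEEGNN**, a small convolutional neural network that predicts
remembered-vs-forgotten from a single trial's EEG matrix, together with the
full surrounding study: a ground-truth-labeled EEG simulator, the
preprocessing chain, leave-pair-out cross-validation with exact binomial
significance, six comparison classifiers, and channel weight-map analysis.

## Model

A trial is a matrix `I ∈ R^(N_ch × T)` (30 channels × 75 decimated samples
for the full −0.1–2.9 s window).  The network has five layers:

* `L_c` — spatial convolution: `N_c` maps, each map `m` applying one kernel
  `k_m ∈ R^(N_ch)` across all channels at each time step,
  `x1_m(s) = f(b_m + k_m · I(:,s))`;
* `L_cs` — temporal convolution + subsampling: per map, a shared kernel of
  length `K_m = T / P_m` over non-overlapping blocks, giving `P_m` features;
* `L_h` — 10 fully connected logistic units;
* `L_out` — 2 logistic outputs, one per class.

`f(u) = 1.7159 tanh(2u/3)`; training is per-sample stochastic gradient
descent on the squared error with early stopping on a stratified validation
split.  See [docs/methods.md](docs/methods.md) for the complete description,
parameter-count formulas, and design rationale.

## Quick start

Simulate one participant (100 trials, ±2 µV frontal effects in calibrated
noise) and cross-validate the network against the LDA baseline.  The network
run trains one model per leave-pair-out fold and takes roughly two minutes on
one CPU:

```python
import conveegnn as c

ep = c.simulate_epochs(c.SimConfig(n_trials=100, seed=0))
net = c.cross_validate(ep, "conveegnn", window="entire", seed=0)
lda = c.cross_validate(ep, "lda", window="entire", seed=0)
print(f"ConvEEGNN: {net.accuracy:.3f} (p = {net.p_value:.3g})")
print(f"LDA:       {lda.accuracy:.3f}")
```

Output:

```
ConvEEGNN: 0.660 (p = 0.000895)
LDA:       0.600
```

Both classifiers are significantly above chance, with the network ahead of
LDA on the same folds.

The same workflow is available from the command line, including continuous
sessions with blinks, drift, and the full preprocessing chain:

```sh
conveegnn simulate --out session/ --seed 1
conveegnn preprocess --in session/ --out epochs.npz
conveegnn evaluate --epochs epochs.npz --model conveegnn --window entire \
    --seed 0 --report report.csv
conveegnn run --out results/        # full multi-participant experiment
```

## Reproduction

The headline quantities (forward/gradient verification errors, calibrated
and null cross-validation accuracies per window, channel-recovery fraction,
grand-average effect sizes) are reproduced by:

```sh
python scripts/acceptance.py --seed 0 --out results.json
```

All randomness derives from `--seed`.

## Layout

* `src/conveegnn/synthetic.py` — labeled EEG session/epoch simulator
* `src/conveegnn/preprocessing.py` — re-reference, band-pass, EOG
  regression, segmentation, baseline, rejection, model-input preparation
* `src/conveegnn/network.py` — the convolutional network, analytic
  gradients, SGD training
* `src/conveegnn/baselines.py` — LDA, dense ANNs, SVM, CSP/SVM+LDA fusion,
  wavelet+SVM
* `src/conveegnn/evaluation.py` — leave-pair-out CV, binomial significance,
  participant selection
* `src/conveegnn/channels.py` — weight-map channel analysis, grand-average
  effect report
* `src/conveegnn/io.py`, `src/conveegnn/cli.py` — EDF/BrainVision/NPZ I/O,
  run configuration, command-line surface
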