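# bioharkit

Human activity recognition from synchronized wearable bio-signals — ECG,
EMG, and tri-axial accelerometer — for patient-monitoring research. The
package takes raw multichannel sensor logs with per-sample activity labels
and per-recording subject IDs, and answers: *which activity was the wearer
performing in each time window, and how well does a classifier trained on
some subjects generalize to unseen subjects?*

## Pipeline

1. **Conditioning** — zero-phase band-pass (ECG 0.5–40 Hz, EMG
   20–min(450, 0.45·f_s) Hz) and powerline notch (50/60 Hz, Q = 30) for the
   electrophysiological channels; a zero-phase Butterworth low-pass
   (magnitude `|X(f)| = 1/√(1 + (f/f_c)^{2N})`, order N = 4) for the
   accelerometer.
2. **Empirical mode decomposition** — each window's ECG/EMG is sifted into
   intrinsic mode functions with `x(t) = Σₙ IMFₙ(t) + r_N(t)` holding to
   machine precision; the Hilbert transform of each mode yields its
   amplitude envelope and instantaneous frequency.
3. **Muscle synergies** — multichannel EMG envelopes V (muscles × time)
   are factored as `V ≈ WH` by non-negative matrix factorization
   (Lee–Seung multiplicative updates, monotone Frobenius objective),
   giving muscle-weight vectors W and temporal activations H.
4. **Features** — per window: mean absolute value `MAV = (1/N) Σ|xᵢ|`,
   waveform length `WL = Σ|xᵢ₊₁ − xᵢ|`, Parseval-exact power-spectrum band
   fractions, spectral rolloff (smallest R with `Σ_{f≤R} P(f) ≥ k·Σ P(f)`,
   k = 0.85), spectral flux `SFₙ = Σ_f (Pₙ(f) − Pₙ₋₁(f))²`, plus
   EMD-envelope and synergy-activation summaries.
5. **Reduction** — Fisher LDA: directions maximizing
   `Q(w) = wᵀS_b w / wᵀS_w w`, eigenvectors of `S_w⁻¹S_b`, at most C−1
   components.
6. **Classification** — a deep belief network: stacked RBMs
   (Gaussian-visible first layer) pretrained with CD-1, fine-tuned with a
   softmax head by momentum SGD.
7. **Evaluation** — subject-wise k-fold cross-validation (no subject ever
   spans the train/test divide of a fold), per-fold confusion matrices,
   accuracy / precision / recall / F1 with fold-mean aggregation, and
   one-vs-rest ROC/AUC pooled over all folds' test predictions.

A seeded synthetic-cohort generator (ECG pulse trains, synergy-modulated
EMG noise, class-dependent accelerometer oscillations, per-subject random
effects) provides ground-truth data for every test; readers for
mHealth-style whitespace/comma column logs let the same pipeline run on
real recordings.

## Worked example

Simulate the default cohort (10 subjects × 6 activities × 20 s at 100 Hz),
then run the full pipeline under subject-wise 5-fold cross-validation. The
config raises the accelerometer cutoff to 5 Hz so the gait-band
oscillations survive filtering:

```sh
bioharkit simulate --out data/ --seed 7
printf 'io:\n  sampling_rate_hz: 100.0\nfilters:\n  acc:\n    cutoff: 5.0\n' > cfg.yaml
bioharkit evaluate --config cfg.yaml --in data/ --seed 7 --out report.json
bioharkit report --in report.json
```

which prints:

```
config hash : 1c4c6b80af128f40
folds       : 5
mean acc    : 0.9738
pooled acc  : 0.9738
macro acc   : 0.9738
mean P / R  : 0.9781 / 0.9738
AUC per cls : 0: 1.000, 1: 1.000, 2: 1.000, 3: 1.000, 4: 0.997, 5: 0.999
```

`mean acc` is the arithmetic average of per-fold accuracies; `pooled acc`
weights every test window equally across folds; `macro acc` averages the
row-normalized pooled-confusion diagonal (the three coincide here because
folds and classes are balanced). The per-class AUCs come from one-vs-rest
ROC curves over all held-out predictions: classes 4 and 5 (the two most
vigorous activity profiles) overlap slightly in their oscillation
amplitudes once per-subject ±15% amplitude effects are applied, hence the
only sub-1.000 values. `report.json` holds the full per-fold confusion
matrices and metrics. The same steps work from Python via
`bioharkit.pipeline.evaluate_recordings`; `bioharkit train` / `predict`
persist and reuse a fitted model.

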