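# Methods

`bioharkit` implements an activity-recognition pipeline for synchronized
wearable bio-signals (ECG, EMG, tri-axial accelerometer): signal
conditioning, empirical mode decomposition with Hilbert analysis,
muscle-synergy factorization, hand-crafted multidomain features, Fisher LDA
reduction, a deep belief network classifier, and subject-wise k-fold
cross-validation. This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic test bed does
and does not demonstrate.

## Windowing

Recordings are segmented into fixed windows of `window_length_s` (default
5 s) with `overlap_fraction` (default 0.5) overlap; the stride is
`L·(1−overlap)` samples, floored, and a trailing partial window is
discarded. Five seconds covers at least two cardiac cycles at resting heart
rate and is standard practice in human activity recognition. A window
inherits the majority label of its samples; the purity threshold defaults
to 1.0, i.e. mixed-label windows at activity transitions are discarded
rather than given a noisy label. Ties break toward the smaller label value
so resolution is deterministic. A `drop_labels` list allows discarding an
unlabeled/null class (as in mHealth-style logs, where label 0 is a null
class).

## Signal conditioning

All filters are zero-phase so that window features are not time-shifted
relative to the labels.

* **ECG / EMG**: order-4 Butterworth band-pass applied forward–backward
  (`sosfiltfilt`), defaults 0.5–40 Hz (ECG) and 20–min(450, 0.45·fs) Hz
  (EMG) — conventional clinical bands — followed by an IIR powerline notch
  (default 50 Hz, switchable to 60 Hz, quality factor 30). The ideal
  brick-wall band-pass and ideal notch are unrealizable (non-causal), so
  these IIR realizations stand in for them; forward–backward application
  squares the magnitude response, which only sharpens both. When the notch
  frequency does not fit below Nyquist (e.g. 50 Hz at a 100 Hz sampling
  rate) the notch is skipped with a warning — there is no powerline energy
  at Nyquist to remove in that case anyway.
* **Accelerometer**: a zero-phase low-pass with the exact order-N
  Butterworth magnitude `1/√(1+(f/f_c)^{2N})`, applied by multiplying the
  real FFT of the (mirror-extended) signal. A forward–backward IIR pass
  would square the magnitude and move the −3 dB point off the cutoff; the
  frequency-domain realization keeps DC gain exactly 1, gain 1/√2 at the
  cutoff, and the analytic −20N dB/decade roll-off, with no phase
  distortion. The default cutoff is 0.3 Hz with order 4; note that 0.3 Hz
  removes nearly all voluntary-movement dynamics, so the synthetic
  evaluation configuration (`synthetic_pipeline_config`) raises it to 5 Hz,
  which preserves gait-band oscillations. Both are config-exposed
  (`filters.acc.cutoff`, `filters.acc.order`).

## Empirical mode decomposition

Plain (non-ensemble) EMD by iterative sifting: cubic-spline envelopes
through the local maxima and minima, with the outermost two extrema
mirrored across each boundary (the standard treatment of edge effects);
the envelope mean is subtracted until the Cauchy criterion
`Σ(h_prev−h)²/Σh_prev²` falls below `sd_threshold` (default 0.2, the
customary convention) or 50 sift iterations are reached. Extraction stops
when the residue is monotonic, has fewer than two maxima or two minima, or
`max_imfs` is reached (default 10 as a runtime bound; 5 inside the feature
pipeline — bio-signal windows at these lengths rarely produce more
informative modes). The residue is always recomputed as `input − Σ IMFs`,
so the reconstruction identity holds to machine precision by construction.
Any global DC offset left in a sifted component (possible when it has very
few extrema) is transferred to the residue, since a mode is oscillatory by
definition; this keeps every IMF zero-mean without extra sifting.
Because maxima and minima are treated symmetrically, the decomposition is
odd: negating the input negates every IMF.

Hilbert analysis of a component takes the analytic-signal magnitude as the
amplitude envelope and the central-difference derivative of the unwrapped
phase (one-sided at the endpoints, so outputs keep full length) as
instantaneous frequency, clipped to [0, Nyquist]. The EMD feature block
emits mean and standard deviation of envelope and instantaneous frequency
for the first `emd.n_imf_features` IMFs (default 3); missing modes
contribute zeros so the feature schema is fixed.

## Muscle-synergy factorization

Multichannel EMG is rectified and smoothed (zero-phase Butterworth
low-pass, 4 Hz, order 4) into activation envelopes — synergy analysis
conventionally factorizes envelopes, not raw interference EMG. The
envelope matrix V (muscles × time) is factored as V ≈ WH by Lee–Seung
multiplicative updates for the Frobenius loss, which decrease the
objective monotonically. Initialization is uniform random scaled by
`√(mean(V)/k)`, seeded; because multiplicative updates find only local
minima, the best of `n_restarts` (default 3) independently initialized
runs is kept — without restarts, factor recovery on exactly factorizable
problems occasionally stalls near 0.90 mean matched cosine instead of
>0.99. After fitting, W columns are normalized to unit Euclidean norm with
the scale absorbed into H, leaving the product unchanged. Reconstruction
quality is summarized as VAF = 1 − ‖V−WH‖²/‖V‖². `select_rank` returns the
smallest k reaching a VAF threshold (default 0.90, k_max 5). Per-window
synergy features are the mean and peak of each activation row, rows sorted
by descending mean to fix the permutation ambiguity. Synergy features
require at least two EMG channels and are skipped otherwise.

## Feature block

Per window, in fixed role order (ECG, EMG, shared synergy block, ACC):

* ECG/EMG channels: mean absolute value, waveform length, band-power
  fractions (ECG: 0.5–4 / 4–8 / 8–15 / 15–25 Hz; EMG: four equal bands up
  to Nyquist), EMD envelope/frequency moments.
* Accelerometer axes: MAV, the slow-band fractions, spectral rolloff
  (default threshold 0.85), and spectral flux statistics.

The power spectrum is a rectangular one-sided periodogram normalized so
total power equals the time-domain energy Σx² (Parseval exactly); no taper
is applied, keeping band powers interpretable as exact energy fractions
(a taper would trade that identity for less leakage, and the features here
compare like against like across windows). Spectral flux is computed as
printed power differences squared between consecutive sub-segments: each
window is split into 4 equal parts and the mean and max flux across the 3
consecutive pairs are emitted. An optional `flux_normalize` switch divides
each sub-spectrum by its total power first (off by default — fidelity to
the raw definition first). Wavelet-domain features are deliberately
absent: no defining formula accompanies the claim, so nothing principled
could be frozen into the default schema.

## LDA

Fisher discriminant directions are eigenvectors of `S_w⁻¹ S_b` in
decreasing eigenvalue order, computed via the symmetric-definite
generalized eigenproblem. `S_w` is shrunk as `S_w + λ·tr(S_w)/d·I`
(λ = 1e−4, config-exposed) so the inverse exists even when features
outnumber windows. Features are standardized with training-fold statistics
before LDA because the block mixes units (volts, hertz, dimensionless
fractions). `n_components` defaults to C−1, the rank bound of `S_b`;
requests beyond it are clamped with a warning. Zero-variance columns are
dropped with a warning and the same selection is replayed at transform
time.

## DBN classifier

Stacked RBMs: the first layer has Gaussian visible units over the
standardized (LDA-reduced, re-standardized) inputs, deeper layers are
Bernoulli over the previous layer's activation probabilities. Pretraining
is CD-1 (30 epochs, lr 0.05, batch 32). Fine-tuning backpropagates softmax
cross-entropy through the sigmoid stack with momentum SGD: lr 0.05,
momentum 0.9, 100 epochs, batch 32. Plain small-step SGD (lr 0.01, no
momentum) was tried first and provably stalls on the initial
cross-entropy plateau of a sigmoid stack — chance-level accuracy even on
linearly separable data — hence the momentum recipe. Early stopping
restores the best parameters after 10 epochs without improvement, but the
patience counter only becomes active once the loss has dropped at least 5%
below its starting value; otherwise the stopper fires during the plateau
that precedes the actual descent. Default hidden sizes are [64, 32]:
the post-LDA input is at most C−1 dimensional, so a small dense stack is
sufficient and trains in seconds on one CPU. All randomness flows from one
seed through named substreams, so runs are bit-reproducible. A
`classifier.backend = logistic` switch substitutes multinomial logistic
regression for ablation and debugging.

## Evaluation

Folds partition subjects (seeded permutation into k nearly equal groups,
default k = 5), never windows, so no individual contributes to both sides
of a fold. Feature extraction fits nothing and is shared across folds;
standardization, LDA, and the classifier are re-fit per fold on training
subjects only, and each fold's standardizer is retained in the report so
leakage can be audited by independent recomputation. Accuracy, per-class
one-vs-rest precision/recall/F1, and the confusion matrix are computed per
fold; overall numbers are arithmetic fold averages. Because the
sample-weighted pooled accuracy and the mean of the row-normalized pooled
confusion diagonal (macro accuracy) genuinely differ under class
imbalance, both are reported, clearly labeled. Classes with zero support
in a fold are excluded from that fold's macro averages and flagged. ROC
curves are per class one-vs-rest over the pooled test predictions of all
folds, with trapezoidal AUC; a fold whose training subjects miss a class
entirely is skipped with a warning and recorded.

## Synthetic cohort

The generator emulates the statistical structure the pipeline exploits,
not physiology:

* ECG: template pulses (sum of three Gaussians — a P-QRS-T caricature,
  cheap and peak-detectable) at intervals 60/bpm with optional
  multiplicative jitter, plus white noise (sd 0.02).
* EMG: two channels of band-limited noise amplitude-modulated by a known
  synergy structure `W₀·H-pattern` (periodic rectified-sine bursts), plus
  white noise (sd 0.02). The carrier band is 20–45 Hz: the conventional
  20–120 Hz EMG band is clipped below the 50 Hz Nyquist of the 100 Hz
  default rate.
* Accelerometer: constant gravity on the z axis, a class-dependent
  sinusoid per axis, Gaussian noise (sd 0.05).

Six activity classes span rest to vigorous locomotion (oscillation
0.2–3.2 Hz, amplitudes 0.02–2 g-units, heart rate 60–150 bpm, burst rates
0.4–3.2 Hz). Subjects carry random effects — amplitude scale ±15%,
frequency ±10% — drawn from subject-keyed substreams of one root seed, so
any component is reproducible in isolation. The default cohort is 10
subjects × 6 classes × 20 s per class at 100 Hz, chosen so the full
pipeline (including per-window EMD) evaluates in well under a minute on
one CPU; it yields 420 windows of 82 features under the default windowing.

What passing tests show: the pipeline is numerically correct
(reconstruction identities, oracle-matched operators, leakage-free fold
statistics) and can learn class structure that is expressed through the
feature set, with subject-held-out generalization under bounded subject
variability. What they do not show: performance on real recordings —
real EMG/ECG carry motion artifacts, electrode drift, inter-subject
variability far beyond ±15%, and label noise that the generator does not
emulate.

## Numerical details and degenerate inputs

* Constant or monotonic signals decompose to zero IMFs with the input as
  residue (not an error).
* `vaf` is undefined for an all-zero matrix (error); all-zero EMG windows
  yield zero synergy features.
* Rolloff of a zero-power spectrum is an error at the operator level; the
  feature builder substitutes 0 for silent channels so vectors stay
  finite.
* Standardization guards zero-variance columns by substituting unit
  scale; LDA drops such columns outright.
* The multiplicative-update monotonicity check tolerates 1e−10 relative
  floating-point wobble; the epsilon guard in the update denominators is
  1e−12.
* Mixed-label tie-breaks, fold assignment, NMF restarts, and all network
  initializations are functions of explicit seeds; reports are
  byte-reproducible for a fixed config and seed.

## Known limitations

* Single-channel EMG disables synergy features (factorizing one envelope
  is meaningless); the feature schema then simply lacks the synergy block.
* The EMD feature block uses only the first three modes; very-low-frequency
  structure ends up in the residue and is not vectorized.
* The ideal-magnitude FFT low-pass assumes the mirror extension suppresses
  circular wrap-around; for windows much shorter than one cutoff period
  edge effects can remain.
* No resampling or cross-device synchronization: all channels of a
  recording must share one sampling rate.
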