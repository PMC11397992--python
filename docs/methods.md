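# Methods

## Problem and data model

The package estimates a continuous wrist joint angle from multi-channel
surface-EMG envelopes.  The input contract mirrors the Ninapro-DB1
acquisition: EMG that has already been amplified, filtered and rectified
(non-negative envelopes) and a 22-sensor glove angle trace, both at
100 Hz.  One `SignalRecord` holds one subject/movement recording; the rest
plateaus between repetitions stay inside the record so that held-out
predictions form one unbroken curve with peaks (movements) and troughs
(rest).  Which glove sensor is "the" wrist angle, and which stimulus
labels denote the three wrist movements (WF, WUD, WECH), vary by dataset
export; both are explicit configuration, with documented defaults, rather
than trusted constants.

Angles are normalized to [0, 1] by an affine map whose min/max come from
the training half of the trace only, then clipped; all reported RMSE
values are therefore fractions of the movement's range.

## Windowing and features

Windows are interpreted in milliseconds: 100 ms windows with 10 ms overlap
are 10-sample windows advancing 9 samples at 100 Hz.  (The sample-count
reading — 100-sample windows — is also expressible through the config,
but the millisecond reading is the one consistent with window-length
sweeps in the 50–200 ms range.)  The sample after each window is its
target, so the pairing never reads beyond the next time step.  Features
are computed per channel and concatenated channel-major.  MAV and RMS are
the defaults; VAR uses the unbiased sample variance, and the spectral trio
MNP/MNF/MDF comes from a plain one-sided periodogram of the raw window
with the DC bin included in total power — rectified envelopes concentrate
power at DC, and excluding it would be a different (also defensible)
dialect.  MDF ties resolve to the lower frequency bin.

## Architectures

* **TCN** — one residual block per dilation (1, 2, 4), each block two
  causal dilated convolutions (kernel 15, 25 channels) each followed by a
  rectifier and optional dropout; the shortcut is the identity when widths
  match, otherwise a width-1 linear projection.  The block output is the
  activation path plus the shortcut.  Receptive field
  `1 + convs_per_block * (K-1) * sum(d)` = 197 windows at the defaults; the
  number of convolutions per block is a config knob because reasonable
  variants exist.
* **LSTM** — 5 layers of 50 units, standard gate equations, zero initial
  states at every subsequence start (no state carry-over between batches).
* **Hybrid** — the TCN output is concatenated per time step with the input
  features (pure splicing, no gating) and decoded by the LSTM stack; a
  linear head maps hidden states to one angle per window.  All paths are
  causal end to end, which the test suite verifies by perturbation.

Everything is pure NumPy with hand-derived backpropagation; gradients are
exact and are checked against central finite differences.  Weights use
fan-in-scaled uniform initialization from a seeded generator, so runs are
bit-reproducible.

## Training recipe

MSE loss, Adam (SGD available), batch size 32, 50 epochs, initial learning
rate 0.01 multiplied by 0.5 every 10 epochs.  Training consumes
chronological subsequences of 128 windows (a non-overlapping cover; the
final piece is taken flush with the end).  128 windows is shorter than the
197-window receptive field; a warning notes that early steps of each
subsequence see truncated history, and longer subsequences are one
parameter away.  Two numerical choices the recipe leaves open are made
explicitly and applied identically to all three models:

* **Feature standardization.** Inputs are z-scored with training-split
  statistics inside `fit` (test data reuses the stored transform).
  Envelope features have strongly channel-dependent scales, and without
  standardization the deep LSTM spends a third of the epoch budget
  escaping its initial plateau.
* **Gradient clipping.** Gradients are clipped to a global norm of 5
  before each update; at the initial learning rate an occasional large
  step can otherwise lock a run into a poor minimum.  The threshold binds
  rarely and both choices are parameters (`standardize`, `clip_norm`).

A non-finite loss aborts with the epoch and learning rate in the message
rather than training onwards.

## Evaluation protocol

Each subject/movement sequence splits 1:1 chronologically; models predict
the unbroken second half in one pass.  RMSE and R² are computed from that
trace; per-(subject, movement, model) rows aggregate into benchmark-style
tables with per-movement Average rows, per-model grand means, subject
spread, and percent change using the baseline model's mean as reference.
Both SD and SEM over subjects are reported because published "±" spreads
are often ambiguous between the two; no silent choice is made.  Model
comparison uses classic one-way ANOVA (significance at p < 0.05) on
per-subject means.  The package ships the published per-subject RMSE/R²
benchmark grids for the three decoders on the DB1 wrist task as data, so
the whole aggregation layer is auditable against printed values.

## Synthetic generator

The generator produces envelopes, not raw interference EMG: DB1-style
input is already rectified and low-pass at 100 Hz, so simulating 1–2 kHz
raw EMG would not match the pipeline's input contract.  The angle is a
train of raised-cosine bursts (smooth, C¹) peaking at 1, separated by rest
at 0, with the DB1 protocol timing as default (10 repetitions, 5 s
movement, 3 s rest).  Muscle activation is the angle advanced by the
electromechanical delay (default 75 ms, the middle of the physiological
50–100 ms band); channel `c` is `baseline + w_c * activation` under
multiplicative noise `|1 + eps|`, which keeps envelopes non-negative
without clipping bias and preserves the monotone weight→MAV relationship
that parameter-recovery tests rely on.  Channel weights default to
distinct values on [0.5, 2.0] so channels are informative but not
redundant; the noise level is a free knob (no published noise
characterization exists for these recordings), defaulting to 5 %.

What the generator emulates: repetition structure, activation lead,
channel coupling, rectified non-negativity, seeded reproducibility.  What
it does not: motor-unit biophysics, electrode shift, fatigue, non-periodic
volitional movement, inter-subject variability beyond the seed.  Passing
the synthetic-recovery tests therefore shows the pipeline is implemented
correctly and can recover a known envelope→angle mapping; it does not
certify accuracy on real recordings.

## Problem sizes used in the checks

The synthetic-recovery checks train all three models on cohorts of two
subjects (10 channels, 10 repetitions, ≈8 300 samples → ≈920 windows per
subject, half for training) for the full 50-epoch recipe, repeated for
three seeds — about a minute of CPU.  Unit tests use smaller records and
truncated training so the whole suite stays fast.

## Known limitations

* On the synthetic task the three architectures converge to held-out RMSE
  within about 0.01–0.03 of one another, and the lighter TCN-only model
  tends to edge out the hybrid.  The generator's envelope→angle map is a
  noisy affine relation with no long-range temporal structure, so the
  LSTM memory that distinguishes the hybrid has nothing to exploit and
  its extra depth is pure optimization cost at this training budget.  The
  published ordering (hybrid clearly best on real recordings) reflects
  structure that real sEMG has and this generator deliberately does not;
  the hybrid's advantage should not be expected to reproduce under these
  synthetic conditions, and the corresponding ordering check is allowed
  to fail rather than the conditions being tuned until it passes.
* The per-subsequence zero initial LSTM state means the first windows of
  each training subsequence are predicted from truncated history;
  predictions at evaluation time use the full unbroken sequence.
* The spectral features use a plain periodogram without tapering; for
  10-sample windows the frequency resolution (10 Hz bins) is coarse.
* Percent "reduction" follows the convention that the baseline model's
  mean is the reference denominator; published spreads quoted with "±"
  could not be reproduced as either SD or SEM across subjects and are
  not asserted anywhere.
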