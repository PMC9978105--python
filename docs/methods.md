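# Methods

## Problem

The N400 is a negative event-related potential (ERP) component peaking near
400 ms post-stimulus over centro-parietal electrodes, larger in amplitude for
one semantic condition of a word-pair judgment task than the other.  It is
*not strictly phase-locked*: its latency varies from trial to trial.
Arithmetic averaging of trials therefore blurs and flattens the component,
degrading exactly the feature a classifier needs.  This package implements an
alignment-aware alternative — single-subject short-distance ERP averaging
(SSE) built on Soft-DTW barycenters — together with a compact transformer
classifier and a subject-wise cross-validation harness, plus a synthetic
N400 generator so the whole pipeline is testable without access to a real
ERP corpus.

## Dynamic time warping and Soft-DTW

For series `x ∈ R^{p×n}`, `y ∈ R^{p×m}` and a pairwise cost
`Δ(x,y) = [δ(x_i, y_j)]`, classic DTW is the dynamic program

    r[i,j] = δ[i,j] + min(r[i,j-1], r[i-1,j], r[i-1,j-1]),

with the distance `r[n,m]`.  Soft-DTW replaces `min` with
`softmin_γ(a) = -γ log Σ exp(-a_k/γ)`, which equals
`-γ log Σ_{A} exp(-⟨A, Δ⟩/γ)` over the full monotone alignment set and makes
the discrepancy differentiable in `x`.  The gradient is computed by the
reverse dynamic program over `E = [∂r[n,m]/∂r[i,j]]`: starting from the
corner `e[n,m] = 1`, each entry combines its three successors with weights
`exp((r_succ − r[i,j] − δ_succ)/γ)`, and
`∇_x dtw_γ = (∂Δ/∂x)^T E`.

Numerical choices:

* The soft minimum is evaluated in stabilised log-space (subtract the
  minimum before exponentiating); the table boundary is `+∞` (`−∞` in the
  backward pass), so no corner special-casing is needed.  Values stay finite
  for γ down to 1e-3 with costs up to 1e6.
* `δ` defaults to the **squared** Euclidean distance.  Plain Euclidean is
  selectable, but squared costs are smooth everywhere, which the backward
  pass and the barycenter optimiser rely on; with plain Euclidean the cost
  gradient at coincident points is set to zero.
* `γ = 0` selects the exact-min branch and reproduces classic DTW
  bit-for-bit on the same cost matrix; the backward pass refuses `γ = 0`.
* Correctness is established against independent oracles rather than
  typography: brute-force enumeration of the alignment set for forward
  values, and central finite differences for gradients.

The distance between two *epochs* (trial matrices, samples × channels)
treats every channel column as an independent univariate series, computes
classic DTW per channel and sums — no multivariate joint warping.  The hot
loops (DTW tables, Soft-DTW forward/backward, the fused barycenter
objective) are numba-compiled.

## Soft-DTW barycenter

Given series `y_1..y_N` with lengths `m_i` and positive weights `λ_i`
summing to one, the barycenter of length `n` minimises

    F(x) = Σ_i (λ_i / m_i) · dtw_γ(x, y_i).

The objective is smooth for γ > 0 with exact gradients, so we use L-BFGS-B
(`scipy.optimize.minimize`) with `max_iter` 100 and relative-decrease
tolerance 1e-5 by default.  The optimiser's sufficient-decrease line search
makes the objective trace at accepted iterates monotone non-increasing,
which the tests assert.  Initialisation is the anchor trial itself when
called from the SSE pipeline (this keeps each output tied to its own trial,
preserving between-trial variability) and the arithmetic mean (linearly
resampled if lengths differ) otherwise.  Weights are uniform in the SSE
use-case.  Note `dtw_γ(y, y) < 0` is normal for γ > 0 — the soft minimum
lies below the hard minimum — so barycenter objectives can be negative.

On shifted copies of a unimodal bump the arithmetic mean provably flattens
the peak; the Soft-DTW barycenter re-aligns before averaging and keeps the
peak magnitude at or above the mean's.  This is the mechanism the SSE
method exploits.

## SSE averaging

Four steps, all confined to one `(subject, label)` group:

1. partition trials by subject and condition;
2. within each group, compute the symmetric matrix of summed per-channel
   DTW distances between all trial pairs (cached to disk per group — it is
   the pipeline's expensive stage and is computed once, before training);
3. for each anchor trial, select the `N` nearest trials (anchor included;
   distance ties break toward the lower trial index; groups smaller than
   `N` use the whole group);
4. for every channel independently, replace the anchor's channel with the
   Soft-DTW barycenter (γ default 1.0, uniform weights, init = anchor) of
   that channel across the similar group.

`N = 1` returns the input verbatim instead of running a one-series
barycenter: that is the exact identity, avoiding γ-induced drift.  The
output dataset has identical cardinality, shapes and metadata; nothing
crosses subjects, conditions or channels, so applying SSE to a full dataset
before subject-wise cross-validation leaks no information across folds.
Barycenters are recomputed per anchor rather than shared between
overlapping similar groups.

The published operating point on real N400 data is `N = 25`; the package
default matches.  The test suite uses smaller `N` at reduced epoch sizes.

## The classifier

The `ErpTransformerClassifier` is a deliberately small transformer encoder:

* sinusoidal positional encoding added to the `(seq_len, channels)` input,
  then dropout (p = 0.5);
* 3 identical encoder blocks.  Multi-head self-attention with 5 heads:
  three shared channel-to-channel input projections produce the Q/K/V
  bases, each head applies its own `(channels × head_dim)` maps with
  `head_dim` equal to the channel count (35 at full scale — heads are
  full-width, not a `dim/heads` split), scores are scaled by
  `num_heads^{-1/2}` (the conventional `head_dim^{-1/2}` is selectable),
  the concatenated head outputs are linearly projected back, then dropout,
  residual, LayerNorm; a two-layer ReLU feedforward (hidden 64 by default)
  with dropout, residual, LayerNorm closes the block.  The residual around
  the feedforward path is a design choice from the Transformer lineage.
* flatten to `seq_len × channels` features (8 960 at full scale) and a
  single linear map to 2 logits with softmax.

Training uses softmax cross-entropy with Adam at learning rate 5e-4, batch
size 256 capped at the training-set size, 100 epochs, all seeded.  The
frequency schedule `ω_k = 10000^{-2k/dim}`, the loss, the optimiser and
Glorot initialisation are standard choices where the architecture
description leaves them open.

The network is implemented directly in NumPy with hand-written
backpropagation for every layer; the full backward pass is verified against
central finite differences in the test suite, and reproducibility is
guaranteed by threading a single seeded generator through initialisation,
batch shuffling and dropout.

## Evaluation protocol

Subjects (never trials) are partitioned into `k = 5` folds differing by at
most one subject (contiguous sorted blocks by default; seeded shuffle
optional).  Each fold trains a fresh model on the remaining subjects and is
evaluated on the held-out subjects after *every* epoch, recording the four
confusion counts — true/false Related/Unrelated, with Related the positive
class.  Accuracy `(TR+TU)/total`, precision `TR/(TR+FR)` and recall
`TR/(TR+FU)` are averaged across folds per epoch; zero-denominator ratios
are reported as undefined (`None`), not zero.  The reported operating point
is the epoch with the highest mean accuracy.

## Synthetic data

The generator emulates the statistical structure the method assumes, per
trial: `topography ⊗ Gaussian-bump + white noise`, where the bump is
centred at 400 ms plus a per-trial latency jitter, scaled by the condition
amplitude and a per-subject gain.  Defaults (the package's study
conditions): Related amplitude −10 µV, Unrelated −4 µV (the amplitude gap
is three times the 2 µV per-sample noise sd), bump width 80 ms, latency
jitter sd 40 ms — comparable to the component width, so single-trial peaks
are visibly non-phase-locked — subject gain sd 0.15.  The epoch window is
`[0, 1 s)` post-stimulus with no pre-stimulus baseline: sample `s` sits at
`s/sfreq` seconds, so 400 ms is sample 102 at 256 Hz (0-based).  For the
full 35-channel montage the topography weights named 10-20 channels
(maximal at CPz/Pz, near-zero for EOG derivations); reduced montages get a
smooth index-space bump.  Reduced-scale configurations shrink `seq_len` and
set `sfreq = seq_len` to keep the 1-second window and the 400 ms centre.

What the generator does *not* model: overlapping early components
(P1/N1/P2), coloured (1/f) noise, eye-movement artifacts, electrode drift,
or realistic volume-conduction correlations between channels.  Passing
tests therefore demonstrate that the pipeline recovers a jittered,
condition-dependent component under controlled conditions — not performance
on real EEG.

## Problem sizes used in tests and the acceptance script

Dynamic-programming oracles run on hundreds of random short series (lengths
≤ 5), where the alignment set can be enumerated exhaustively.  The SSE
structural contracts run on 4 subjects × 30 trials/label with 64-sample,
8-channel epochs; the end-to-end classification check runs 5 subjects × 16
trials/label with 48-sample, 6-channel epochs, similar-group size 10, 60
training epochs at batch size 32, and 3 seeds, with the barycenter capped
at 12 L-BFGS iterations.  These sizes keep the full pipeline's quadratic dynamic programs
at desk scale while preserving every contract being tested; the published
full-scale configuration (256 × 35 epochs, N = 25, 100 epochs, 40 subjects)
is reachable through the same interfaces.

## Known limitations

* SSE averaging is transductive: each trial's output depends on the other
  trials of the same (subject, label) group in the dataset at hand.
* The barycenter is a local optimiser; different initialisations give
  different (valid) local minima.  Init = anchor is deliberate, not
  incidental.
* Per-channel warping ignores cross-channel covariance of the latency
  jitter (all channels of a trial jitter together in the generator, but
  each channel is re-aligned independently).
* The classifier flattens the encoder output, so its final layer is
  position-specific; it is not translation-invariant by construction.
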