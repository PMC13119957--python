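# Methods

## The problem

Wearable sensing systems record several modalities at once — inertial
motion (IMU), electrocardiography (ECG), electrodermal activity (EDA),
respiration (RESP), skin temperature (TEMP) — and routinely lose some of
them to poor skin contact, motion artifacts, battery management, or
hardware failure.  `modrepair` implements a self-supervised
*detect-and-repair* pipeline for this setting: it learns modality-robust
fused representations under simulated modality dropout, predicts at
inference time which modalities are actually present, and reconstructs
the missing streams from the remaining ones.

## Model

Each modality window `x(m)` (shape `T_w x C`, z-scored) is encoded by a
shallow 1-D CNN: three convolutions with kernel sizes (5, 3, 3) and
channel widths (64, 128, 128), stride 1, zero same-padding, each followed
by ReLU and batch normalization, then global average pooling over time to
an embedding `z(m)` of dimension D = 128.  Same-padding is our choice
(it preserves the time axis for pooling and removes minimum-length edge
cases); the global-average readout is the simplest one consistent with a
"shallow encoder".

Fusion is single-head additive attention restricted to the available
modalities: a shared scoring map `s(m) = w . tanh(W z(m) + b)` is
soft-maxed **over the present slots only**, so absent modalities receive
weight exactly zero and provably cannot influence the fused vector
`z_f = sum_m a_m V z(m)`.  A transformer-style fusion is deliberately out
of scope; the lightweight variant is the more dropout-robust choice.

Two heads operate on `z_f`:

* a **presence predictor** (2-layer MLP, logistic outputs) that performs
  multi-label detection of which modality slots carry a real signal, and
* a **masked decoder**: per modality a 2-layer MLP
  `(z_f ++ presence mask) -> 256 -> T_w * C`, emitting the full window.
  Reconstructions are produced for all modalities; the loss selects the
  dropped ones.  This is the smallest decoder satisfying the
  conditioning-on-`z_f`-and-mask requirement.

A projection head `D -> D -> 64` (ReLU between) feeds the contrastive
loss; its outputs are L2-normalized inside the loss, not in the head.

## Objectives

The hybrid objective is

```
L_total = lambda_rec * L_masked + lambda_con * L_contrastive
          + lambda_pres * L_presence
```

with defaults `lambda_rec = 1.0`, `lambda_con = 0.5`.

* `L_masked`: per dropped modality, the element-wise mean squared error of
  its reconstruction, averaged over the dropped set per window
  (`1/|Mdrop| * sum`), then over windows with at least one drop; an empty
  drop set contributes 0.  Per-element means keep `lambda_rec` scale-free
  across modalities with different `T_w * C`.
* `L_contrastive`: NT-Xent (temperature `tau = 0.5`) between projections
  of the same window seen through two different modalities, averaged over
  all unordered modality pairs, each pair evaluated on the windows where
  both members are present (pairs with fewer than two shared windows are
  skipped; the denominator counts only contributing pairs).  An optional
  BYOL-style momentum target encoder (`m = 0.996`) can supply the second
  view during unimodal pretraining; it is off by default.
* `L_presence`: mean binary cross-entropy of the presence probabilities
  against the true mask, over all `N x M` entries.  The presence head has
  to be trained by *something*; an auxiliary third term with a small
  weight (`lambda_pres = 0.1`) is the smallest addition that does it, and
  the detection ablates away cleanly by setting it to zero.

Numerical guards: 1e-12 added to L2 norms before normalization,
probabilities clipped to [1e-7, 1 - 1e-7] in the cross-entropy, and the
within-softmax max-shift for the attention and NT-Xent denominators.

## Dropout simulation

Dropout is applied per window and per modality, i.i.d. with marginal drop
probability `rate` (the 10% / 30% / 50% grid is the default evaluation
sweep); a guard resamples all-absent rows so at least one modality
survives (bias on the marginal < rate^M).  Fill policies for dropped
entries: `zeros` (training default), `gaussian-noise` (i.i.d. N(0,1),
matching the z-scored scale — the default for *presence-detection*
evaluation, because a zero-filled window is trivially recognizable while
noise emulates a corrupted-but-active sensor), and `last-window-hold`
(stale buffer).

## Training

Three phases, all Adam (lr 1e-3, library-default betas), batch 32,
seed 42:

1. **Unimodal SimCLR** on one designated modality (IMU-like by default).
   Augmentations are the minimal standard time-series pair — additive
   jitter N(0, 0.05) and per-window scaling U(0.9, 1.1).
2. **Masked multimodal pretraining**: encoders + fusion + decoder +
   presence head, masked loss (+ presence term), a fresh dropout mask per
   batch.
3. **Joint fine-tuning** with the full hybrid objective; dropout
   continues.  Ablations `masked_only` / `contrastive_only` zero
   `lambda_con` / `lambda_rec` respectively.

Per training step one encoder pass per modality (over the filled batch)
serves both heads: the repair path fuses with the true mask (absent
weight exactly 0), the detection path fuses blind (all slots assumed
present) so the presence head learns from exactly the input it will see
at inference, where the true mask is unknown.  In training mode the
batch-norm batch statistics therefore include filled placeholder rows;
at evaluation time running statistics make every forward pass per-sample
independent, so the zero-influence guarantee for absent modalities is
exact.

Epoch counts are configuration-driven; the shipped defaults (10/20/20)
suit desk-scale experiments and the tests use smaller counts (see
"Problem sizes" below).  No learning-rate schedule is used.

The network itself runs on a small tape-based reverse-mode autodiff
engine over numpy arrays (`modrepair.autodiff`), with fused primitives
for the 1-D convolution and batch normalization; gradients are verified
against finite differences and the convolution against
`scipy.signal.correlate` in the test suite.  Single-threaded runs with a
fixed seed are bit-reproducible.

## Synthetic data

No real dataset is required.  The generator emulates the one property the
method relies on — cross-modal redundancy: a hidden first-order Markov
chain over K discrete states (self-transition probability tuned to a
~30 s mean dwell at the configured rate, so 10 s windows are mostly
label-pure) produces a drive vector (0.5 s moving-average-smoothed
one-hot plus AR(1) fluctuation, coefficient 0.9, innovation sd 0.05) that
every modality reads out linearly through a K x C loading matrix.
Loadings place distinct state levels (`linspace(-1, 1, K)`) along a
random unit channel direction plus a small perturbation, so every
modality carries state contrast.  Modality-typical carriers are layered
on top: amplitude-modulated sinusoids (IMU ~1-3 Hz, RESP ~0.2-0.4 Hz),
an ECG-like spike train whose inter-pulse interval is
`1 s * (1 + 0.3 * drive_1)` (rate modulation, no waveform morphology),
and direct readout for EDA/TEMP.  Gaussian noise (sd 0.1 by default,
0.05 for TEMP) is added.  Per-subject RNG substreams derive from
`(seed, subject_index)`, so the dataset is a pure function of its config.

What this generator does *not* emulate: physiological waveform
morphology, sensor drift, bursty or structured failures, asynchronous
clocks, inter-subject amplitude idiosyncrasies beyond per-subject
normalization.  Passing tests on this data therefore demonstrate that the
architecture and objectives behave as designed under the stated
redundancy assumption — not that the pipeline reaches any particular
accuracy on real wearable recordings.

A consequence worth knowing: the carrier-free slow modalities (EDA,
TEMP) are the reconstructable ones.  The sinusoid and spike-train
carriers have random per-recording frequency/phase, which a time-pooled
fused embedding cannot recover, so reconstruction of IMU/ECG/RESP
converges to the conditional mean (RMSE ~1 on z-scored data).  This
mirrors the physiological reality that slow autonomic signals are
cross-predictable while the fine structure of motion or heartbeat timing
is not, and it is why reconstruction quality is reported for EDA and
TEMP.

## Evaluation protocol

Leave-one-subject-out splitting at the recording level (windows never
span subjects).  Downstream quality is measured with a multinomial
logistic probe (L2-regularized, seeded) on frozen fused embeddings.
Reconstruction error is RMSE in the z-scored domain, so zero-imputation
scores ~1.0 and per-channel-mean imputation ~1.0 — the baselines a useful
repair must beat.  Presence detection is scored as per-modality binary
accuracy / precision / recall / F1 at threshold 0.5 plus their
unweighted macro average (zero-denominator cases score 0).  Robustness
sweeps re-apply masks `n_repeats` times per rate (default 10) and report
mean +/- sd.  2-D latent projections use PCA (deterministic up to sign)
or seeded t-SNE.

## Problem sizes used by the shipped experiments

The tests and the acceptance script run the full pipeline on generated
data at desk scale, chosen to keep single-CPU runs comfortable: sampling
rate 10 Hz (a 10 s window is then 100 steps), 5 modalities, K = 3
states, 5 subjects, with 200-1250 windows and 3 + 3 epochs for phases
2-3 depending on the experiment; the training constants above (lr,
batch, tau, lambdas, momentum, seed 42) are never changed.  The
generator's own defaults (64 Hz, 600 s, 5 subjects) describe the
full-scale setting.

## Known limitations

* Linear-plus-carrier synthetic readouts are intentionally analyzable,
  not biophysical.
* The decoder reconstructs from a time-pooled embedding; within-window
  temporal detail that is uncorrelated across modalities is
  unrecoverable by design.
* Modalities must share window timing (synchronous sampling assumption);
  no asynchronous alignment is attempted.
* The engine is CPU-only and single-threaded-deterministic; it is meant
  for method study at desk scale, not large-scale training.
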