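# Methods

## Problem and model

The package decodes three lower-limb movements — standing up, sitting down,
and walking — from five channels of surface EMG (sEMG) recorded on one leg
(rectus femoris, vastus lateralis, tibialis anterior, biceps femoris,
lateral gastrocnemius) at 1500 Hz. The motivating use is a human–robot
interface for exoskeleton control, where the non-paretic leg's muscle
activity predicts intended movement before it unfolds mechanically.

Classification combines two feature streams per analysis window
`X ∈ ℝ^{C×W}` (C = 5 channels, W = 300 samples):

1. **Hand-crafted features** `F_td, F_fd`: per channel, MAV, SSI, WL, RMS,
   ZC, SSC, the six Yule–Walker AR(6) coefficients (time domain), and MNP,
   PKF, MDF from a one-sided rectangular-window periodogram (frequency
   domain). These are the standard myoelectric pattern-recognition
   statistics; their exact definitions and conventions are in
   `hcsnet/handcrafted.py`.
2. **Learned channel-synergy features** `F_learning = MCSNet(X)`: a shared
   per-channel LSTM over short input patches, a two-layer same-padded CNN
   along time (batch norm, ELU, average pooling), and a depthwise
   convolution across the channel axis that mixes per-muscle feature maps
   into synergy maps, followed by global average pooling.

The fused vector `F_fusion = [F_td | F_fd | F_learning]` is gated by a
channel-attention block,

    w = σ( MLP(AvgPool(F_fusion)) + MLP(MaxPool(F_fusion)) ),
    F = w ⊙ F_fusion,

with a single shared two-layer MLP (bottleneck = n_channels / reduction,
ELU inside) and pooling taken within *attention channels*: one group per
sEMG channel's time-domain block, one per frequency-domain block, and one
per learned feature map. Grouping is required to make the pooling
non-degenerate on a flat vector; a `flat_attention` mode (every element its
own channel) is available for comparison. The gating is a broadcast
element-wise product — the only shape-consistent reading of a channel
gate applied to a flat feature vector. Prediction is
`softmax(linear(F))` over the three classes, ties toward the lowest class
index.

## Training

Class-weighted categorical cross-entropy (weight = majority proportion /
class proportion, so the majority class has weight exactly 1), Adam with
its standard defaults (lr 1e-3, β = 0.9/0.999, ε = 1e-8), at most
`max_epochs` epochs with **validation stopping**: the returned weights are
those of the epoch with the lowest validation loss. An early-stop patience
(default 12 epochs without ≥ 1e-3 val-loss improvement) saves compute
without changing which weights are returned. Hand-crafted blocks enter the
graph as constants, z-scored with statistics fit on the training split only
(SSI and the AR coefficients differ by orders of magnitude; unnormalized
they would dominate the attention MLP). Gradients flow jointly through
MCSNet, the attention block, and the head. Everything is seeded and
CPU-deterministic: repeated runs reproduce the history and reports exactly.

The network is implemented on a small in-repo reverse-mode autodiff over
numpy (`autograd.py`, `nn.py`): elementwise ops, matmul, a fused LSTM
sequence op, per-tap GEMM 1-D convolution, batch norm, segment pooling for
the attention groups, and a fused weighted softmax cross-entropy. Gradient
correctness is verified against central finite differences in the test
suite.

### Network sizing

Defaults: patch length 10 (the LSTM sees 30 patches of 10 samples rather
than 300 raw samples — a standard input-embedding step that shortens the
recurrence 10× with no loss at these window lengths), LSTM hidden 16,
CNN filters 8 → 32 with kernel 15 and pool 2, depthwise multiplier 2,
dropout 0.25. `F_learning` is therefore 64-dimensional and the fused
vector is 60 + 15 + 64 = 139-dimensional. These sizes were chosen so that
the full two-protocol evaluation (15 network trainings) runs in minutes on
one CPU core; every size is config-exposed, and the closed-form parameter
count is tested against the built model.

## Preprocessing

Per trial: optional channel selection, 50 Hz IIR notch (2nd order, Q = 30),
10–450 Hz Butterworth bandpass (order 4), both applied forward–backward for
zero phase (the paper-standard frequencies; orders and zero-phase execution
are this package's choices, config-exposed). Then the first second of
movement after the 4 s cue is kept — intervals are half-open, 0-based,
sample = round(t·fs) — and cut into sliding windows (default 300 samples,
step 150), never straddling trial boundaries. Filter edge effects are
handled only by the forward–backward scheme's default padding; filter tests
exclude 100 ms at each edge.

## Synthetic data

No public recordings exist for this task, so `synthetic_data` generates
surrogate sessions with the statistical structure the features measure:

    s_c(t) = gain_c · env_c(t − jitter) · n_c(t)
             + noise_std · w_c(t) + mains · sin(2π·50·t + φ_c)

with `n_c` unit-RMS Gaussian noise bandpassed to 20–450 Hz (the amplitude-
modulated interference-pattern surrogate standard in EMG simulation),
white baseline noise (reference σ = 0.05 signal units), and nonzero mains
pickup (reference amplitude 0.05) so the notch filter is exercised.
Class-specific per-channel envelopes give distinct synergy patterns:
standing = ramp-hold on the knee extensors, sitting = reversed ramp on the
flexors, walking = ~1 Hz alternating raised-cosine bursts between the shank
antagonists. A session is 30 trials per subject (10 per class, 3 groups of
10; standing/walking shuffled over the first 20 trials, sitting last), each
trial 12 s with the movement cued at 4 s, at 1500 Hz. Inter-subject
variability is one dial: channel gains lognormal(σ = variability), onset
jitter N(0, (0.3·variability)² s²), noise and mains levels lognormal around
their references; variability 0 makes subjects identical, and the mean
pairwise distance between subjects' MAV profiles grows monotonically with
it (property-tested).

What the generator does **not** emulate: motor-unit action potentials and
firing statistics, electrode shift, fatigue-related spectral compression,
crosstalk structure, or paretic-limb signals. Passing tests therefore show
the pipeline recovers class structure of the amplitude/spectral kind the
features target — not performance on clinical recordings.

## Evaluation protocols

* **Within-subject**: per subject, stratified 70/30 trial split (21/9 of
  30); a 4-fold stratified CV structure over the 21 training trials
  provides validation folds, and the network's stopping set is the first
  fold; accuracy is reported on the held-out 30 %. Splits are at trial
  level so overlapping windows never leak across the boundary.
* **Cross-subject**: subjects split 7 train / 3 test, repeated 5 times with
  seeded resampling. By default the stopping set is carved (20 % of trials,
  trial-grouped, stratified) from the *training* subjects — the no-leakage
  variant; `paper_protocol=True` stops on the held-out subjects instead,
  reproducing the common-but-leaky literature design. Classical baselines
  (LDA, RBF-SVM with C = 1 and γ = 'scale', 5-NN, 100-tree RF — all
  config-exposed scikit-learn pipelines on standardized hand-crafted
  features) train on the union of fit and stopping windows, since they have
  no stopping step.

Accuracy is per window by default (`vote="trial"` adds majority voting).
Reports carry per-unit accuracies, confusion matrices, and all seeds, and
serialize to byte-stable JSON.

The sliding-window sweep re-windows the segments over a (length, step %)
grid and scores an RBF-SVM on hand-crafted features within subject. On the
default synthetic conditions, accuracy at length 300 matches or beats the
shorter windows; near the high-SNR ceiling adjacent cells can differ by
less than one window's worth of accuracy, so only the 300-vs-shorter
comparison is asserted.

## Numerical conventions

* AR(6): Yule–Walker on the demeaned window with biased (1/N)
  autocovariances, solved as stacked Toeplitz systems; zero-variance
  windows return all-zero coefficients by convention. Agreement with an
  independent implementation (statsmodels) is tested to 1e-9.
* Periodogram: one-sided, rectangular window, no detrending, density
  scaling; PKF/MDF ties break toward the lowest bin; the DC bin counts in
  total power; MDF is the smallest bin where cumulative power reaches half
  the total.
* ZC/SSC dead-band thresholds default to 0 (the literature rarely states
  them); both are configurable.
* The per-channel time-domain block is 12-dimensional (6 scalars + 6 AR
  coefficients). Because a 7-feature list containing a 6-vector cannot also
  be 7-dimensional, an `ar_scalar_mode` flag collapses AR to its first
  coefficient, reproducing the 7-per-channel layout quoted in parts of the
  literature; the default keeps all six.
* Default problem sizes for the shipped experiments: 10 subjects,
  variability 0.1, window 300/step 150, network training capped at 100
  epochs with patience 12 — the scale at which the full acceptance run
  completes in minutes on one CPU core while the protocols' contrasts are
  already stable.

## Known limitations

* Surrogate data only; the paper's own recordings are not deposited, so its
  headline accuracies are not reproduction targets here.
* MCSNet's published hyperparameters are not stated in the source
  literature; the architecture follows the three-stage description, sizes
  are this package's defaults.
* The channel-attention "channels" of a flat fused vector are not defined
  in the source description; the grouping above is a design choice.
* No onset detection, artifact rejection, or real-time streaming path.
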