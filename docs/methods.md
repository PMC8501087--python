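# Methods

This note documents the modelling choices behind `aideseg`: what the
procedure assumes, what the tunable parameters mean and why their defaults
are what they are, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The training procedure and its assumptions

The engine treats noisy-label segmentation as a label-*repair* problem
rather than a sample-rejection problem. Its working assumptions:

1. **Early learning.** An over-parameterized segmentation network trained by
   SGD on a mixture of correct and corrupted masks fits the consistent,
   image-supported structure before it memorizes per-sample label errors.
   Consequently, early in training, (a) per-sample loss ranks label quality
   (samples whose labels disagree with the image content have larger
   losses), and (b) the network's own predictions can be *better* than the
   worst labels. The test suite verifies this directly: on the synthetic
   noisy scenario the Spearman correlation across training samples between
   prediction-vs-noisy-label DSC (epoch 5 of a plain supervised run) and
   hidden noisy-vs-clean DSC is positive.
2. **Peer decorrelation.** Two networks with different initializations make
   partially independent errors, so letting each network rank the other's
   batch (small-loss filtering) and letting each correct only its *own*
   label copy limits self-confirmation and error accumulation.
3. **Anatomical regularity.** Images of the same region look roughly alike
   across subjects, so replacing a minority of worst-agreeing labels by
   model predictions is informative rather than circular — provided the
   replacement happens while assumption 1 holds (the warm-up window) or
   after the network has become reliable (the periodic late corrections).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `filter_fraction` | 0.5 | batch fraction treated as suspected-noisy each iteration; should roughly track the expected label-noise rate. An optional `filter_ramp` grows it from 0 co-teaching-style. |
| `correction_fraction` | 0.25 | fraction of *low-quality-flagged* samples whose labels are replaced per correction event (`floor(0.25 · n_low)` exactly). |
| `warmup_epochs` | 5 | corrections run every epoch while `epoch < warmup_epochs`. Must lie inside the early-learning window; see "Scale" below. |
| `correction_period` | 10 | after the warm-up, corrections run every 10 epochs (`epoch > warmup` and `(epoch − warmup) mod period = 0`; with `warmup = 0`, simply `epoch mod period = 0`). |
| `ramp_epochs` | 10 | linear 0→1 ramp on the consistency weight; the shape is the simplest monotone choice satisfying the schedule contract. |
| `k_views` | 4 | augmented views averaged into a pseudo-label; 4 covers the flip/rotation group cheaply. |
| `temperature` | 0.5 | two-class power sharpening `p^(1/T)/(p^(1/T)+(1−p)^(1/T))`; 0.5 squares the odds, T→0 gives hard labels, 1 is the identity. |
| `alpha`, `epsilon` | 1, 1.0 | cross-entropy weight and Dice smoothing constant of the segmentation loss. |
| `suspected_target` | `"stored"` | loss form for suspected samples, see below. |
| `base_channels` | 32 | first-level feature width of the U-Net (tests use 8 so the suite runs on one CPU); widths double per level, depth is fixed at 5 down / 4 up blocks. |
| optimizer | Adam, lr 1e-3 | a single configurable gradient-descent family; Adam converges within desk-scale epoch budgets without per-task tuning. |

### The suspected-sample loss

Two readings of "a weighted summation of the segmentation loss and
consistency loss" are implemented:

* `"stored"` (default): `L = L_seg(stored label) + λ(epoch) · L_cor(ŷ)` —
  the ramped hyper-parameter controls the *contribution of the consistency
  loss* while the (possibly noisy, but still informative) stored label keeps
  supervising.
* `"pseudo"`: `L = λ(epoch) · [L_seg(ŷ) + L_cor(ŷ)]` — the pseudo-label
  replaces the distrusted annotation outright.

The default is `"stored"`. In desk-scale experiments the `"pseudo"` form
removes the supervised signal from half of every batch and degenerates into
self-confirmation: the network trains toward its own sharpened predictions
and held-out accuracy falls below the plain baseline, while the `"stored"`
form combined with scheduled corrections exceeds it (both forms remain
selectable; the acceptance suite exercises the default).

### Scale and the warm-up window

At publication scale (hundreds of training images, GPU epochs) a network is
already competent after one epoch, so warm-up corrections from epoch 0 are
safe and the warm-up length is uncritical. At desk scale (tens of images)
the early-learning window is only a couple of epochs long; corrections
issued after it replace labels with predictions that are *worse* than the
labels, and the errors compound. The label-recovery experiment therefore
uses `warmup_epochs = 2` with the default period of 10. This is a property
of the scaled world, not of the algorithm; the package default stays 5.

## The synthetic world

`synthdata` generates what the method needs to be falsifiable without any
external dataset: bright elliptical/blobby foreground objects (intensity
0.75) on a darker background (0.25) with Gaussian noise (σ = 0.05) and a
few bright confounder blobs emulating distracting structures; optionally a
second modality as a monotone intensity remap with independent noise.
Label corruptions act on labels only — the clean truth record is immutable —
and severity is *calibrated*: the smallest severity whose mean
corrupted-vs-clean DSC falls to the requested level (fractional severities
round stochastically so the mean varies continuously).

The acceptance scenario is the stated high-noise regime scaled to one CPU:
32×32 phantoms, 10 trusted + 40 corrupted labels (80 % noise level),
calibrated to noisy-label DSC ≈ 0.6, three seeds. The corruption model is
`drop` (random chunks of the object deleted), chosen because it is
*systematically biased* — like the model-generated or carelessly drawn
annotations the method targets — whereas the unbiased `mixture` model
(random dilate/erode/shift) averages out under SGD and a plain supervised
baseline is already robust to it, so the comparison would not probe the
correction machinery. The generator's library defaults keep the stated
64×64, 20 + 80 world.

What the generator does **not** emulate: anatomical shape statistics,
scanner physics and artefacts, 3D continuity, class imbalance at clinical
severity, or correlated inter-rater disagreement. A green suite therefore
establishes that the algorithmic machinery behaves as specified and
recovers label quality in a controlled world — not clinical performance.

## Numerical conventions

* **Surfaces**: a boundary pixel is a foreground pixel with ≥ 1 background
  neighbour under 4-connectivity (8 configurable); the image border is not
  background. Surface distances use a Euclidean distance transform with the
  physical spacing (`sampling=`), which is exact for point-set nearest
  neighbours and verified against an all-pairs oracle to 1e-9 mm.
* **Empty masks**: DSC(∅, ∅) = 1 by convention (flagged in reports),
  DSC(∅, ·) = 0; surface distances and RAVD are undefined on the relevant
  empty mask and raise (reports carry NaN).
* **Thresholds**: all binarizations use `value ≥ t`; the consensus protocol
  evaluates t ∈ {0.1, …, 0.9} bit-reproducibly.
* **Logarithm clamp**: probabilities are clamped to `[1e-7, 1 − 1e-7]`
  *inside logarithms only*, realising `0·log 0 = 0` with a single code path
  and keeping the Dice term exact; the clamp zeroes the CE gradient outside
  the open interval.
* **Tie-breaks**: loss and DSC rankings break ties by ascending sample id;
  the largest-component filter keeps the component whose first pixel comes
  first in raster order; max-pooling takes the first maximum.
* **Rounding**: the suspected set has `round(fraction · batch)` members
  (half away from zero); correction events touch `floor(fraction ·
  eligible)` labels.
* **Determinism**: all randomness flows from named streams spawned off one
  seed (network A/B init, batch order, augmentation draws), so runs are
  byte-reproducible and the degenerate configuration (`filter_fraction = 0`,
  corrections off) reproduces an independently coded supervised loop
  bit-exactly. Batch norm uses batch statistics in training and running
  averages in evaluation; training batches of one are rejected (a trailing
  singleton is merged into the previous batch, and a single-sample dataset
  is duplicated within its batch).
* **3D inputs**: training and per-sample ranking operate slice-wise; for
  reported metrics, slices can be stacked into a volume with a slice
  spacing and evaluated volume-wise.

## Known limitations

* The numpy network is CPU-bound; publication-scale images (256² and up,
  hundreds of samples) need a GPU framework behind the same interfaces.
* Two peer networks only; the design does not extend to larger committees.
* Binary foreground/background tasks only; no multi-class head.
* The UDA path relies purely on label generation plus self-correction — no
  feature alignment — so very large domain gaps degrade the generated
  labels beyond what correction can repair.
* Pseudo-label averaging happens in probability space; logit-space
  averaging is untested.
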