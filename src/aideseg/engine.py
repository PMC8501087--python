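"""Cross-model self-correcting training engine.

Two networks are trained in parallel on the same data but with independent
copies of the (possibly noisy) labels. Three mechanisms cooperate:

* **Local label filtering** — each iteration, every network's batch is
  partitioned by its *peer's* per-sample segmentation losses: the
  ``filter_fraction`` with the largest losses are treated as
  suspected-noisy (small-loss criterion). Trusted samples contribute the
  plain segmentation loss against their stored label; suspected samples
  contribute a ramped combination of the segmentation loss against a
  sharpened pseudo-label (built from K augmented views of the image) and an
  MSE consistency loss against the same pseudo-label.
* **Global label correction** — at scheduled epochs the DSC between each
  network's post-processed hard prediction and its stored label is computed
  over the whole training set; a ``correction_fraction`` of the
  low-quality-flagged samples with the smallest DSCs have their stored label
  replaced by the prediction. High-quality labels are never touched.
* **Ramped consistency weight** — the suspected-sample loss is scaled by a
  weight rising linearly from 0 to 1 over ``ramp_epochs`` epochs.

The correction schedule follows the early-learning (memorization) pattern:
networks fit cleanly-labelled structure before memorizing noisy labels, so
corrections run every epoch during the warm-up window and every
``correction_period`` epochs thereafter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import keep_largest_component
from .losses import (LossParams, PseudoLabel, apply_transform,
                     consistency_loss_grad, invert_transform,
                     segmentation_loss, segmentation_loss_grad, sharpen)
from .metrics import dice_score
from .nn import ModelSpec, MultiStreamUNet, build_model, make_optimizer


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass
class AideConfig:
    """Every framework hyper-parameter in one place.

    ``filter_fraction`` is the batch fraction treated as suspected-noisy each
    iteration; ``correction_fraction`` the fraction of low-quality samples
    corrected per scheduled update. ``suspected_target`` selects the
    suspected-sample loss form: ``"stored"`` (default) keeps the
    segmentation loss against the stored label and ramps in the consistency
    term; ``"pseudo"`` replaces the target by the pseudo-label and ramps the
    whole suspected-sample loss.
    """

    filter_fraction: float = 0.5
    correction_fraction: float = 0.25
    warmup_epochs: int = 5
    correction_period: int = 10
    ramp_epochs: int = 10
    k_views: int = 4
    temperature: float = 0.5
    loss_params: LossParams = field(default_factory=LossParams)
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    enable_correction: bool = True
    postprocess_corrections: bool = True
    suspected_target: str = "stored"   # or "pseudo"
    filter_ramp: bool = False          # co-teaching-style warm ramp of the filter

    def __post_init__(self):
        for name in ("filter_fraction", "correction_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.correction_period < 1:
            raise ValueError("correction_period must be >= 1")
        if self.warmup_epochs < 0 or self.epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.k_views < 1:
            raise ValueError("k_views must be >= 1")
        if self.suspected_target not in ("pseudo", "stored"):
            raise ValueError("suspected_target must be 'pseudo' or 'stored'")


@dataclass(frozen=True)
class CorrectionRecord:
    epoch: int
    id: str
    dsc_before: float   # DSC(prediction, old stored label) — the ranking score
    dsc_after: float    # DSC(prediction, new stored label)


class LabelStore:
    """Mutable per-network copy of the training labels plus quality flags.

    High-quality-flagged labels are immutable; every replacement of a
    low-quality label is appended to the audit log.
    """

    def __init__(self, labels: np.ndarray, high_quality: np.ndarray,
                 ids: list[str] | None = None):
        labels = np.asarray(labels)
        if labels.ndim != 3:
            raise ValueError("labels must be (n, H, W)")
        self.labels = labels.astype(np.uint8).copy()
        self.high_quality = np.asarray(high_quality, dtype=bool).copy()
        if self.high_quality.shape != (len(self.labels),):
            raise ValueError("one quality flag per sample required")
        self.ids = list(ids) if ids is not None else [str(i) for i in
                                                      range(len(labels))]
        self.audit: list[CorrectionRecord] = []

    def __len__(self) -> int:
        return len(self.labels)

    def copy(self) -> "LabelStore":
        new = LabelStore(self.labels, self.high_quality, self.ids)
        new.audit = list(self.audit)
        return new

    def replace_label(self, index: int, new_label: np.ndarray, epoch: int,
                      dsc_before: float, dsc_after: float) -> None:
        if self.high_quality[index]:
            raise ValueError(
                f"label {self.ids[index]!r} is flagged high-quality and "
                "cannot be modified")
        self.labels[index] = np.asarray(new_label, dtype=np.uint8)
        self.audit.append(CorrectionRecord(epoch=epoch, id=self.ids[index],
                                           dsc_before=float(dsc_before),
                                           dsc_after=float(dsc_after)))


@dataclass(frozen=True)
class BatchPartition:
    clean_ids: tuple
    noisy_ids: tuple


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    ramp: float
    mean_loss: tuple[float, float]
    train_dsc_mean: tuple[float, float]
    train_dsc_std: tuple[float, float]
    n_corrected: tuple[int, int]


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        rows = []
        for r in self.records:
            rows.append({"epoch": r.epoch, "ramp": r.ramp,
                         "loss_a": r.mean_loss[0], "loss_b": r.mean_loss[1],
                         "train_dsc_a": r.train_dsc_mean[0],
                         "train_dsc_b": r.train_dsc_mean[1],
                         "train_dsc_std_a": r.train_dsc_std[0],
                         "train_dsc_std_b": r.train_dsc_std[1],
                         "corrected_a": r.n_corrected[0],
                         "corrected_b": r.n_corrected[1]})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrainingData:
    """Images and sample ids; labels live in :class:`LabelStore`."""

    images: np.ndarray          # (n, modalities, H, W) float32
    ids: tuple

    def __post_init__(self):
        img = np.asarray(self.images, dtype=np.float32)
        if img.ndim != 4:
            raise ValueError("images must be (n, modalities, H, W)")
        object.__setattr__(self, "images", img)
        object.__setattr__(self, "ids", tuple(self.ids))
        if len(self.ids) != len(img):
            raise ValueError("one id per image required")

    def __len__(self) -> int:
        return len(self.images)


# --------------------------------------------------------------------------
# scheduling primitives
# --------------------------------------------------------------------------

def derive_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Named random streams shared by the engine and the supervised baseline
    so degenerate configurations reproduce a plain run bit-exactly."""
    children = np.random.SeedSequence(seed).spawn(4)
    return {"net_a": np.random.default_rng(children[0]),
            "net_b": np.random.default_rng(children[1]),
            "order": np.random.default_rng(children[2]),
            "augment": np.random.default_rng(children[3])}


def epoch_batches(order: np.ndarray, batch_size: int) -> list[np.ndarray]:
    """Split a permutation into batches; a trailing single sample is merged
    into the previous batch (batch norm needs >= 2)."""
    chunks = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    if len(chunks) > 1 and len(chunks[-1]) < 2:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks.pop()
    return chunks


def partition_batch(peer_losses, filter_fraction: float,
                    ids=None) -> BatchPartition:
    """Split a batch into trusted and suspected-noisy samples.

    The suspected set is exactly the top ``round(filter_fraction * n)``
    samples by peer loss; ties are broken by ascending sample id.
    """
    if not 0.0 <= filter_fraction <= 1.0:
        raise ValueError(f"filter_fraction must lie in [0, 1], "
                         f"got {filter_fraction}")
    losses = np.asarray(peer_losses, dtype=float)
    if not np.isfinite(losses).all():
        raise ValueError("peer losses must be finite")
    n = len(losses)
    ids = list(range(n)) if ids is None else list(ids)
    n_noisy = int(math.floor(filter_fraction * n + 0.5))
    ranked = sorted(range(n), key=lambda i: (-losses[i], ids[i]))
    noisy = sorted(ranked[:n_noisy], key=lambda i: ids[i])
    clean = sorted(ranked[n_noisy:], key=lambda i: ids[i])
    return BatchPartition(clean_ids=tuple(ids[i] for i in clean),
                          noisy_ids=tuple(ids[i] for i in noisy))


def ramp_weight(epoch: int, ramp_epochs: int) -> float:
    """Linear 0 -> 1 ramp over the first ``ramp_epochs`` epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if ramp_epochs <= 0:
        return 1.0
    return min(1.0, epoch / ramp_epochs)


def should_correct(epoch: int, cfg: AideConfig) -> bool:
    """Correction schedule: every epoch below the warm-up count, then every
    ``correction_period`` epochs after the warm-up window."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    w, p = cfg.warmup_epochs, cfg.correction_period
    if w == 0:
        return epoch % p == 0
    if epoch < w:
        return True
    return epoch > w and (epoch - w) % p == 0


# --------------------------------------------------------------------------
# per-sample losses and pseudo-labels
# --------------------------------------------------------------------------

def per_sample_losses(prob_fg: np.ndarray, refs: np.ndarray,
                      params: LossParams) -> np.ndarray:
    return np.array([segmentation_loss(prob_fg[i], refs[i], params)
                     for i in range(len(prob_fg))])


def _batched_pseudo_labels(net: MultiStreamUNet, images: np.ndarray, k: int,
                           temperature: float, rng: np.random.Generator
                           ) -> list[PseudoLabel]:
    """Pseudo-labels for several images with one network forward.

    Draws the (rotation, flip) transforms in the same per-sample order as
    repeated calls to :func:`aideseg.losses.pseudo_label_from_augmentations`
    and is numerically equivalent up to float batching.
    """
    n = len(images)
    square = images.shape[-2] == images.shape[-1]
    rots = (0, 1, 2, 3) if square else (0, 2)
    transforms = []
    for _ in range(n):
        for _ in range(k):
            transforms.append((int(rng.choice(rots)), bool(rng.integers(0, 2))))
    views = np.stack([apply_transform(images[i], rot, flip)
                      for i, (rot, flip) in
                      zip(np.repeat(np.arange(n), k), transforms)])
    probs = net.forward(views, train=False)[:, 1]
    out = []
    for i in range(n):
        acc = None
        for j in range(k):
            rot, flip = transforms[i * k + j]
            fg = invert_transform(probs[i * k + j], rot, flip)
            acc = fg.astype(np.float64) if acc is None else acc + fg
        mean_fg = np.clip(acc / k, 0.0, 1.0)
        out.append(PseudoLabel(foreground=sharpen(mean_fg, temperature),
                               source_k=k, temperature=temperature))
    return out


def hard_prediction(prob_fg: np.ndarray, threshold: float = 0.5,
                    postprocess: bool = False,
                    connectivity: int = 4) -> np.ndarray:
    """Binarize a foreground-probability map, optionally keeping only the
    largest connected component."""
    hard = (np.asarray(prob_fg) >= threshold).astype(np.uint8)
    if postprocess:
        hard = keep_largest_component(hard, connectivity=connectivity)
    return hard


def predict_dataset(net: MultiStreamUNet, images: np.ndarray,
                    batch_size: int = 8) -> np.ndarray:
    """Evaluation-mode foreground probabilities for every image, (n, H, W)."""
    outs = []
    for i in range(0, len(images), batch_size):
        outs.append(net.forward(images[i:i + batch_size], train=False)[:, 1])
    return np.concatenate(outs, axis=0)


# --------------------------------------------------------------------------
# the training step
# --------------------------------------------------------------------------

def train_iteration(images: np.ndarray, idxs: np.ndarray,
                    nets: tuple[MultiStreamUNet, MultiStreamUNet],
                    stores: tuple[LabelStore, LabelStore],
                    optimizers, cfg: AideConfig, epoch: int,
                    rng_aug: np.random.Generator) -> dict:
    """One cross-model optimization step on one batch.

    Each network's batch is partitioned by the *peer's* per-sample
    segmentation losses; trusted samples regress their stored labels,
    suspected samples regress their pseudo-labels with the ramped
    consistency term. One optimizer step per network.
    """
    if len(idxs) < 2:
        raise ValueError("batch size must be >= 2")
    ramp = ramp_weight(epoch, cfg.ramp_epochs)
    ffrac = cfg.filter_fraction * (ramp if cfg.filter_ramp else 1.0)
    params = cfg.loss_params

    partitions = []
    if ffrac > 0.0:
        for x_i in (0, 1):
            peer = nets[1 - x_i]
            peer_store = stores[1 - x_i]
            p_peer = peer.forward(images, train=False)[:, 1]
            losses = per_sample_losses(p_peer, peer_store.labels[idxs], params)
            partitions.append(partition_batch(losses, ffrac, ids=list(idxs)))
    else:
        partitions = [BatchPartition(clean_ids=tuple(idxs), noisy_ids=())] * 2

    mean_losses = []
    for x_i in (0, 1):
        net, store, part = nets[x_i], stores[x_i], partitions[x_i]
        pos = {int(g): j for j, g in enumerate(idxs)}
        noisy = [int(i) for i in part.noisy_ids]
        pseudos = []
        if noisy:
            # pseudo-labels are gradient-free and must run before the
            # training-mode forward (layer caches are single-slot)
            pseudos = _batched_pseudo_labels(
                net, images[[pos[i] for i in noisy]], cfg.k_views,
                cfg.temperature, rng_aug)
        p = net.forward(images, train=True)
        pf = p[:, 1]
        grads = np.zeros_like(pf, dtype=np.float64)
        sample_losses = np.zeros(len(idxs))
        for gid in part.clean_ids:
            j = pos[int(gid)]
            l, g = segmentation_loss_grad(pf[j], store.labels[gid], params)
            grads[j] = g
            sample_losses[j] = l
        for pl, gid in zip(pseudos, noisy):
            j = pos[gid]
            l2, g2 = consistency_loss_grad(pf[j], pl)
            if cfg.suspected_target == "pseudo":
                # pseudo-label replaces the distrusted annotation entirely;
                # the whole suspected-sample loss is ramped
                l1, g1 = segmentation_loss_grad(pf[j], pl.foreground, params)
                grads[j] = ramp * (g1 + g2)
                sample_losses[j] = ramp * (l1 + l2)
            else:
                # stored (possibly noisy) label keeps supervising; only the
                # consistency term is ramped in
                l1, g1 = segmentation_loss_grad(pf[j], store.labels[gid],
                                                params)
                grads[j] = g1 + ramp * g2
                sample_losses[j] = l1 + ramp * l2
        if not np.isfinite(sample_losses).all():
            bad = [store.ids[g] for g, l in zip(idxs, sample_losses)
                   if not np.isfinite(l)]
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} for samples {bad}; "
                f"ramp={ramp}, lr={cfg.learning_rate}")
        dldp = np.zeros_like(p)
        dldp[:, 1] = (grads / len(idxs)).astype(p.dtype)
        net.backward(dldp)
        optimizers[x_i].step()
        mean_losses.append(float(sample_losses.mean()))
    return {"loss_a": mean_losses[0], "loss_b": mean_losses[1], "ramp": ramp}


# --------------------------------------------------------------------------
# global label correction
# --------------------------------------------------------------------------

def global_label_correction(net: MultiStreamUNet, store: LabelStore,
                            data: TrainingData, epoch: int, cfg: AideConfig,
                            predictions: np.ndarray | None = None) -> int:
    """Replace the worst-agreeing low-quality labels by the network's
    post-processed hard predictions.

    The DSC between the network's current hard prediction and each stored
    label is computed over the whole training set and ranked; exactly
    ``floor(correction_fraction * n_low_quality)`` low-quality-flagged
    samples with the smallest DSCs are replaced. Returns the number of
    replaced labels. Raises if called off-schedule.
    """
    if not should_correct(epoch, cfg):
        raise RuntimeError(f"global_label_correction called at epoch {epoch}, "
                           "which is not on the correction schedule")
    if predictions is None:
        predictions = predict_dataset(net, data.images, cfg.batch_size)
    hard = np.stack([hard_prediction(predictions[i], 0.5,
                                     cfg.postprocess_corrections)
                     for i in range(len(store))])
    dscs = np.array([dice_score(hard[i], store.labels[i])
                     for i in range(len(store))])
    eligible = [i for i in range(len(store)) if not store.high_quality[i]]
    n_corr = int(math.floor(cfg.correction_fraction * len(eligible)))
    selected = sorted(eligible, key=lambda i: (dscs[i], store.ids[i]))[:n_corr]
    for i in selected:
        new = hard[i]
        store.replace_label(i, new, epoch, dsc_before=dscs[i],
                            dsc_after=dice_score(hard[i], new))
    return len(selected)


# --------------------------------------------------------------------------
# the full training loop
# --------------------------------------------------------------------------

def fit(data: TrainingData, store: LabelStore | tuple[LabelStore, LabelStore],
        cfg: AideConfig, model_spec: ModelSpec, dtype=np.float32
        ) -> tuple[MultiStreamUNet, MultiStreamUNet,
                   tuple[LabelStore, LabelStore], TrainingHistory]:
    """Run the full cross-model self-correcting training.

    ``store`` may be a single :class:`LabelStore` (cloned into one
    independent copy per network) or an explicit pair. Fully reproducible
    under ``cfg.seed``.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    if isinstance(store, LabelStore):
        stores = (store.copy(), store.copy())
    else:
        stores = (store[0], store[1])
    rngs = derive_rngs(cfg.seed)
    net_a = build_model(model_spec, rngs["net_a"], dtype,
                        input_shape=data.images.shape)
    net_b = build_model(model_spec, rngs["net_b"], dtype)
    nets = (net_a, net_b)
    opts = [make_optimizer(cfg.optimizer, net.params(), cfg.learning_rate)
            for net in nets]
    history = TrainingHistory()
    n = len(data)
    for epoch in range(cfg.epochs):
        order = rngs["order"].permutation(n)
        epoch_losses = []
        for bidx in epoch_batches(order, cfg.batch_size):
            rec = train_iteration(data.images[bidx], bidx, nets, stores, opts,
                                  cfg, epoch, rngs["augment"])
            epoch_losses.append((rec["loss_a"], rec["loss_b"]))
        dsc_stats, n_corr = [], []
        for net, st in zip(nets, stores):
            probs = predict_dataset(net, data.images, cfg.batch_size)
            dscs = np.array([dice_score((probs[i] >= 0.5).astype(np.uint8),
                                        st.labels[i]) for i in range(n)])
            dsc_stats.append((float(dscs.mean()), float(dscs.std())))
            if cfg.enable_correction and should_correct(epoch, cfg):
                n_corr.append(global_label_correction(net, st, data, epoch,
                                                      cfg, predictions=probs))
            else:
                n_corr.append(0)
        mean_l = tuple(float(np.mean([l[i] for l in epoch_losses]))
                       for i in (0, 1))
        history.records.append(EpochRecord(
            epoch=epoch, ramp=ramp_weight(epoch, cfg.ramp_epochs),
            mean_loss=mean_l,
            train_dsc_mean=(dsc_stats[0][0], dsc_stats[1][0]),
            train_dsc_std=(dsc_stats[0][1], dsc_stats[1][1]),
            n_corrected=(n_corr[0], n_corr[1])))
    return net_a, net_b, stores, history


def predict_ensemble(net_a: MultiStreamUNet, net_b: MultiStreamUNet,
                     image: np.ndarray) -> np.ndarray:
    """Pixel-wise mean of the two networks' softmax outputs, (2, H, W)."""
    if net_a.spec != net_b.spec:
        raise ValueError(f"model specs differ: {net_a.spec} vs {net_b.spec}")
    image = np.asarray(image)
    pa = net_a.predict_proba(image)
    pb = net_b.predict_proba(image)
    return 0.5 * (pa + pb)
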