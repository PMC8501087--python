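"""Task standardization: turning SSL and UDA into noisy-label learning.

Semi-supervised learning (a small labeled subset plus unlabeled data) and
unsupervised domain adaptation (labeled source domain, unlabeled target
domain) are both reduced to noisy-label learning: a baseline network is
pretrained fully-supervised on whatever labeled data exists, low-quality
labels are generated for the unlabeled part with that network, and the
combined dataset — high-quality flags on the originally labeled samples,
low-quality flags on the generated ones — feeds the self-correcting engine.

No feature alignment or adversarial adaptation is applied for UDA; the
standardization step is generation-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import (LabelStore, TrainingData, derive_rngs, epoch_batches,
                     hard_prediction, predict_dataset)
from .losses import LossParams, segmentation_loss_grad
from .metrics import dice_score
from .nn import ModelSpec, build_model, make_optimizer


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    loss_params: LossParams = field(default_factory=LossParams)


@dataclass(frozen=True)
class ScenarioSpec:
    """Which samples carry trusted labels, per learning scenario."""

    mode: str                                # {"ssl", "uda", "nll"}
    labeled_ids: tuple = ()                  # ssl
    unlabeled_ids: tuple = ()                # ssl
    source_ids: tuple = ()                   # uda
    target_ids: tuple = ()                   # uda
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    postprocess_flag: bool = False

    def __post_init__(self):
        if self.mode not in ("ssl", "uda", "nll"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ssl":
            a, b = set(self.labeled_ids), set(self.unlabeled_ids)
        elif self.mode == "uda":
            a, b = set(self.source_ids), set(self.target_ids)
        else:
            a, b = set(), set()
        if a & b:
            raise ValueError(f"overlapping id sets: {sorted(a & b)}")


def pretrain_baseline(images: np.ndarray, labels: np.ndarray,
                      model_spec: ModelSpec,
                      cfg: PretrainConfig = PretrainConfig(),
                      which: str = "a", dtype=np.float32,
                      track_per_sample_dsc: bool = False):
    """Plain fully-supervised training on a labeled subset.

    A deliberately self-contained loop (the engine's degenerate
    configuration must reproduce it bit-exactly under a shared seed): same
    named random streams, same batch assembly, same per-sample gradient
    averaging, one optimizer step per batch.

    A single labeled sample is duplicated within its batch so batch
    normalization stays well defined.

    Returns ``(net, history)`` with per-epoch mean losses and, optionally,
    the per-sample training-set DSC trajectory.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("pretraining requires at least one labeled sample")
    rngs = derive_rngs(cfg.seed)
    net = build_model(model_spec, rngs[f"net_{which}"], dtype,
                      input_shape=images.shape)
    opt = make_optimizer(cfg.optimizer, net.params(), cfg.learning_rate)
    n = len(images)
    history = {"mean_loss": [], "per_sample_dsc": []}
    for _epoch in range(cfg.epochs):
        order = rngs["order"].permutation(n)
        losses = []
        for bidx in epoch_batches(order, cfg.batch_size):
            if len(bidx) == 1:
                bidx = np.repeat(bidx, 2)
            p = net.forward(images[bidx], train=True)
            pf = p[:, 1]
            grads = np.zeros_like(pf, dtype=np.float64)
            for j, gi in enumerate(bidx):
                l, g = segmentation_loss_grad(pf[j], labels[gi],
                                              cfg.loss_params)
                grads[j] = g
                losses.append(l)
            dldp = np.zeros_like(p)
            dldp[:, 1] = (grads / len(bidx)).astype(p.dtype)
            net.backward(dldp)
            opt.step()
        history["mean_loss"].append(float(np.mean(losses)))
        if track_per_sample_dsc:
            probs = predict_dataset(net, images, cfg.batch_size)
            history["per_sample_dsc"].append(np.array(
                [dice_score((probs[i] >= 0.5).astype(np.uint8), labels[i])
                 for i in range(n)]))
    return net, history


def generate_low_quality_labels(net, images: np.ndarray,
                                postprocess_flag: bool = False,
                                batch_size: int = 8) -> np.ndarray:
    """Hard predictions (threshold 0.5, optionally largest-component
    filtered) for a set of unlabeled images; callers flag them low-quality.
    Empty predictions are allowed."""
    images = np.asarray(images, dtype=np.float32)
    if len(images) == 0:
        return np.zeros((0,) + images.shape[-2:], dtype=np.uint8)
    probs = predict_dataset(net, images, batch_size)
    return np.stack([hard_prediction(probs[i], 0.5, postprocess_flag)
                     for i in range(len(images))])


def build_nll_dataset(spec: ScenarioSpec, images: np.ndarray, ids,
                      labels: np.ndarray, model_spec: ModelSpec,
                      quality=None, dtype=np.float32):
    """Standardize a scenario into (data, label store, info).

    * ssl — pretrain on ``labeled_ids``, generate labels for
      ``unlabeled_ids``; labeled samples are flagged high-quality.
    * uda — pretrain on ``source_ids``, generate for ``target_ids``.
    * nll — pass through, with ``quality`` flags as provided (default: all
      low-quality).

    ``info['noise_level']`` is the image-based count ratio
    |low-quality| / |total|; ``info['model']`` the pretrained network (None
    for nll).
    """
    images = np.asarray(images, dtype=np.float32)
    ids = list(ids)
    labels = np.asarray(labels)
    index = {sid: i for i, sid in enumerate(ids)}
    out_labels = labels.astype(np.uint8).copy()
    hq = np.zeros(len(ids), dtype=bool)
    model = None
    if spec.mode == "nll":
        if quality is not None:
            hq = np.asarray(quality, dtype=bool).copy()
    else:
        trusted = spec.labeled_ids if spec.mode == "ssl" else spec.source_ids
        untrusted = (spec.unlabeled_ids if spec.mode == "ssl"
                     else spec.target_ids)
        missing = [s for s in (*trusted, *untrusted) if s not in index]
        if missing:
            raise ValueError(f"ids not in dataset: {missing}")
        t_idx = [index[s] for s in trusted]
        u_idx = [index[s] for s in untrusted]
        model, _ = pretrain_baseline(images[t_idx], labels[t_idx], model_spec,
                                     spec.pretrain, dtype=dtype)
        hq[t_idx] = True
        if u_idx:
            out_labels[u_idx] = generate_low_quality_labels(
                model, images[u_idx], spec.postprocess_flag,
                spec.pretrain.batch_size)
    data = TrainingData(images=images, ids=tuple(ids))
    store = LabelStore(out_labels, hq, ids)
    noise_level = float((~hq).sum() / len(ids))
    return data, store, {"noise_level": noise_level, "model": model}
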