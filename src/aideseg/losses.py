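"""Training losses and pseudo-label construction.

The segmentation loss is the usual Dice + cross-entropy combination

    L_seg(y, y') = 1 - (2 Σ y'_i y_i + ε) / (Σ y'_i + Σ y_i + ε)
                   - (α/N) Σ [ y_i log y'_i + (1 - y_i) log(1 - y'_i) ]

over the foreground-probability map y' and a (possibly soft) target y, with
α balancing the terms (default 1) and ε a smoothing constant (default 1.0).
Probabilities are clamped to [prob_floor, 1 - prob_floor] inside the
logarithms only, which realises the 0·log 0 = 0 convention without special
cases and keeps the Dice term exact.

The consistency loss is a mean-square error between a prediction and a
temperature-sharpened pseudo-label,

    L_cor(ŷ, y') = (1 / 2N) Σ (ŷ_i - y'_i)².

Pseudo-labels are built by averaging the predictions of K augmented views
(rotations by 90° multiples and axis flips, each mapped back through the
inverse transform) and sharpening the mean with a temperature T:

    sharpen(p; T) = p^(1/T) / (p^(1/T) + (1 - p)^(1/T)).

Gradient helpers (``*_grad``) return the analytic derivative with respect to
the foreground probability map; the numpy network consumes these directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LossParams:
    """Hyper-parameters of the segmentation loss."""

    alpha: float = 1.0       # cross-entropy weight
    epsilon: float = 1.0     # Dice smoothing constant
    prob_floor: float = 1e-7  # clamp bound inside logarithms

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not (0 < self.prob_floor < 0.5):
            raise ValueError("prob_floor must lie in (0, 0.5)")


@dataclass(frozen=True)
class PseudoLabel:
    """Soft target for a suspected-noisy sample."""

    foreground: np.ndarray   # per-pixel value in [0, 1]
    source_k: int            # number of augmented views averaged
    temperature: float


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_loss(pred_fg: np.ndarray, ref: np.ndarray, epsilon: float = 1.0) -> float:
    """Smoothed soft-Dice loss term; >= 0 for pred in [0,1] vs binary ref."""
    pred_fg = np.asarray(pred_fg, dtype=float)
    ref = np.asarray(ref, dtype=float)
    _check_shapes(pred_fg, ref)
    num = 2.0 * float((pred_fg * ref).sum()) + epsilon
    den = float(pred_fg.sum()) + float(ref.sum()) + epsilon
    return 1.0 - num / den


def cross_entropy(pred_fg: np.ndarray, ref: np.ndarray,
                  prob_floor: float = 1e-7) -> float:
    """Mean binary cross-entropy with clamped logarithms; targets may be soft."""
    pred_fg = np.asarray(pred_fg, dtype=float)
    ref = np.asarray(ref, dtype=float)
    _check_shapes(pred_fg, ref)
    pc = np.clip(pred_fg, prob_floor, 1.0 - prob_floor)
    n = pred_fg.size
    return float(-(ref * np.log(pc) + (1.0 - ref) * np.log1p(-pc)).sum() / n)


def segmentation_loss(pred_fg: np.ndarray, ref: np.ndarray,
                      params: LossParams = LossParams()) -> float:
    """Dice + α·CE over the foreground channel; zero for a perfect hard
    prediction (up to the log clamp)."""
    return (dice_loss(pred_fg, ref, params.epsilon)
            + params.alpha * cross_entropy(pred_fg, ref, params.prob_floor))


def segmentation_loss_grad(pred_fg: np.ndarray, ref: np.ndarray,
                           params: LossParams = LossParams()
                           ) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``pred_fg``."""
    pred_fg = np.asarray(pred_fg, dtype=float)
    ref = np.asarray(ref, dtype=float)
    _check_shapes(pred_fg, ref)
    eps = params.epsilon
    num = 2.0 * float((pred_fg * ref).sum()) + eps
    den = float(pred_fg.sum()) + float(ref.sum()) + eps
    l_dice = 1.0 - num / den
    # d/dp_i [ -num/den ] = -(2 y_i den - num) / den^2
    g_dice = -(2.0 * ref * den - num) / (den * den)
    pc = np.clip(pred_fg, params.prob_floor, 1.0 - params.prob_floor)
    n = pred_fg.size
    l_ce = float(-(ref * np.log(pc) + (1.0 - ref) * np.log1p(-pc)).sum() / n)
    inside = (pred_fg > params.prob_floor) & (pred_fg < 1.0 - params.prob_floor)
    g_ce = np.where(inside, -(ref / pc - (1.0 - ref) / (1.0 - pc)) / n, 0.0)
    loss = l_dice + params.alpha * l_ce
    return loss, g_dice + params.alpha * g_ce


def consistency_loss(pred_fg: np.ndarray, pseudo) -> float:
    """(1/2N) Σ (ŷ_i - y'_i)²; symmetric, zero iff the maps agree."""
    target = pseudo.foreground if isinstance(pseudo, PseudoLabel) else pseudo
    pred_fg = np.asarray(pred_fg, dtype=float)
    target = np.asarray(target, dtype=float)
    _check_shapes(pred_fg, target)
    n = pred_fg.size
    return float(((target - pred_fg) ** 2).sum() / (2.0 * n))


def consistency_loss_grad(pred_fg: np.ndarray, pseudo
                          ) -> tuple[float, np.ndarray]:
    target = pseudo.foreground if isinstance(pseudo, PseudoLabel) else pseudo
    pred_fg = np.asarray(pred_fg, dtype=float)
    target = np.asarray(target, dtype=float)
    _check_shapes(pred_fg, target)
    n = pred_fg.size
    loss = float(((target - pred_fg) ** 2).sum() / (2.0 * n))
    return loss, (pred_fg - target) / n


def sharpen(mean_fg: np.ndarray, temperature: float) -> np.ndarray:
    """Two-class temperature sharpening p^(1/T)/(p^(1/T)+(1-p)^(1/T)).

    Monotone in p, fixes {0, 0.5, 1}, and approaches the hard indicator as
    T -> 0. T = 1 is the identity.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    p = np.asarray(mean_fg, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities outside [0, 1]")
    if temperature == 1.0:
        return p.copy()
    a = p ** (1.0 / temperature)
    b = (1.0 - p) ** (1.0 / temperature)
    with np.errstate(invalid="ignore"):
        out = a / (a + b)
    # 0^(1/T) + 1^(1/T) is never 0, so the only NaN risk is p exactly 0/1
    # with huge 1/T underflow; pin those explicitly.
    out = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, out))
    return out


# --- geometric augmentation group (rotations by 90° multiples + flips) ----

def apply_transform(x: np.ndarray, rot: int, flip: bool) -> np.ndarray:
    """Apply flip (last axis) then rotation by ``rot`` quarter turns to the
    trailing two axes."""
    if flip:
        x = np.flip(x, axis=-1)
    return np.rot90(x, k=rot, axes=(-2, -1))


def invert_transform(y: np.ndarray, rot: int, flip: bool) -> np.ndarray:
    """Inverse of :func:`apply_transform`."""
    y = np.rot90(y, k=-rot, axes=(-2, -1))
    if flip:
        y = np.flip(y, axis=-1)
    return y


def pseudo_label_from_augmentations(predict_fn, image: np.ndarray, k: int = 4,
                                    temperature: float = 0.5,
                                    rng: np.random.Generator | None = None
                                    ) -> PseudoLabel:
    """Build a sharpened pseudo-label from K augmented views of one image.

    Parameters
    ----------
    predict_fn:
        Callable mapping a (channels, H, W) image to a foreground-probability
        map (H, W). It is evaluated gradient-free (plain numpy).
    image:
        (channels, H, W) input.
    k:
        Number of augmented views; transforms are drawn uniformly from the
        8-element rotation/flip group (square images) or the 4-element
        flip/180° subgroup otherwise.
    rng:
        Seeded generator; required for reproducibility, defaults to a fresh
        unseeded generator.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("image must be (channels, H, W)")
    rng = np.random.default_rng() if rng is None else rng
    square = image.shape[-2] == image.shape[-1]
    rots = (0, 1, 2, 3) if square else (0, 2)
    acc = None
    for _ in range(k):
        rot = int(rng.choice(rots))
        flip = bool(rng.integers(0, 2))
        view = apply_transform(image, rot, flip)
        fg = np.asarray(predict_fn(view), dtype=float)
        fg = invert_transform(fg, rot, flip)
        acc = fg if acc is None else acc + fg
    mean_fg = acc / k
    return PseudoLabel(foreground=sharpen(np.clip(mean_fg, 0.0, 1.0), temperature),
                       source_k=k, temperature=temperature)
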