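"""Segmentation evaluation metrics.

Implements the four metrics commonly reported for binary medical-image
segmentation — Dice similarity coefficient (DSC), relative area/volume
difference (RAVD), average symmetric surface distance (ASSD) and maximum
symmetric surface distance (MSSD) — plus the multi-rater consensus protocol
that thresholds continuous labels at nine probability levels and averages the
per-threshold DSCs.

Conventions (stated once, used everywhere):

* A boundary (surface) pixel is a foreground pixel with at least one
  background neighbour under the configured connectivity (4 or 8 in 2D).
  The image border is *not* treated as background: a mask touching the edge
  has no surface there.
* DSC of two empty masks is 1.0 by convention; empty vs non-empty is 0.0.
  Surface distances are undefined on empty masks and raise.
* Distances are measured in physical units using the per-axis ``spacing``
  (mm per pixel); DSC and RAVD are spacing-free.
* Masks may be 2D slices or 3D stacks (stacked 2D masks with a slice
  spacing); the surface/distance machinery is dimension-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    """Binary structure for the 4/8-neighbourhood convention (faces/full)."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    return ndimage.generate_binary_structure(ndim, 1 if connectivity == 4 else ndim)


@dataclass(frozen=True)
class BinaryMask:
    """A hard {0,1} segmentation mask with physical pixel spacing.

    Parameters
    ----------
    grid:
        2D or 3D integer array with values in {0, 1}.
    spacing:
        Physical size of one pixel along each axis, in mm. Defaults to 1.0
        per axis.
    id:
        Optional sample identifier carried through reports.
    """

    grid: np.ndarray
    spacing: tuple[float, ...] | None = None
    id: str | None = None

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim not in (2, 3):
            raise ValueError(f"mask must be 2D or 3D, got ndim={g.ndim}")
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "grid", g.astype(np.uint8, copy=False))
        sp = self.spacing
        if sp is None:
            sp = (1.0,) * g.ndim
        sp = tuple(float(s) for s in np.atleast_1d(sp))
        if len(sp) != g.ndim:
            raise ValueError(f"spacing has {len(sp)} entries for a {g.ndim}D mask")
        if any(s <= 0 for s in sp):
            raise ValueError("spacing entries must be strictly positive")
        object.__setattr__(self, "spacing", sp)

    @property
    def area(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SurfacePointSet:
    """Boundary pixels of a mask, as an (n, ndim) coordinate array."""

    points: np.ndarray
    spacing: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MetricReport:
    """Per-sample metric bundle. DSC/RAVD are fractions here; reporting
    layers multiply by 100 to print percentages."""

    dsc: float
    ravd: float
    assd: float
    mssd: float
    id: str | None = None
    both_empty: bool = field(default=False)


def _as_mask(m, spacing=None) -> BinaryMask:
    if isinstance(m, BinaryMask):
        return m
    return BinaryMask(np.asarray(m), spacing=spacing)


def _check_compatible(pred: BinaryMask, ref: BinaryMask) -> None:
    if pred.grid.shape != ref.grid.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.grid.shape} vs ref {ref.grid.shape}"
        )
    if pred.spacing != ref.spacing:
        raise ValueError(
            f"spacing mismatch: pred {pred.spacing} vs ref {ref.spacing}"
        )


def confusion_counts(pred, ref) -> ConfusionCounts:
    """Pixel-wise confusion counts; tp+fp+fn+tn partitions all N pixels."""
    pred, ref = _as_mask(pred), _as_mask(ref)
    _check_compatible(pred, ref)
    p = pred.grid.astype(bool)
    r = ref.grid.astype(bool)
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice_score(pred, ref) -> float:
    """DSC = 2 TP / (2 TP + FP + FN); 1.0 when both masks are empty."""
    c = confusion_counts(pred, ref)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def ravd(pred, ref) -> float:
    """Relative area/volume difference (FP - FN) / (TP + FN).

    Equals (|pred| - |ref|) / |ref|; signed, so over-segmentation is
    positive. Raises on an empty reference.
    """
    c = confusion_counts(pred, ref)
    if c.tp + c.fn == 0:
        raise ValueError("RAVD undefined: reference mask is empty")
    return (c.fp - c.fn) / (c.tp + c.fn)


def _surface_mask(grid: np.ndarray, connectivity: int) -> np.ndarray:
    """Boolean array marking foreground pixels with >=1 background neighbour.

    ``border_value=1`` in the erosion keeps the no-implicit-padding
    convention: the image border alone does not create a surface.
    """
    fg = grid.astype(bool)
    if not fg.any():
        return np.zeros_like(fg)
    st = _structure(fg.ndim, connectivity)
    interior = ndimage.binary_erosion(fg, structure=st, border_value=1)
    return fg & ~interior


def surface_points(mask, connectivity: int = 4) -> SurfacePointSet:
    """Extract the boundary pixels of a mask as explicit coordinates."""
    mask = _as_mask(mask)
    sm = _surface_mask(mask.grid, connectivity)
    pts = np.argwhere(sm)
    return SurfacePointSet(points=pts, spacing=mask.spacing)


def _directed_surface_distances(pred: BinaryMask, ref: BinaryMask,
                                connectivity: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-surface distances, pred->ref and ref->pred, in mm.

    Computed with a Euclidean distance transform of each surface using the
    physical ``sampling`` spacing; exact for point-set nearest neighbours.
    """
    _check_compatible(pred, ref)
    sp = _surface_mask(pred.grid, connectivity)
    sr = _surface_mask(ref.grid, connectivity)
    if not sp.any() or not sr.any():
        raise ValueError("surface distance undefined: a mask is empty or has "
                         "no boundary")
    dt_ref = ndimage.distance_transform_edt(~sr, sampling=pred.spacing)
    dt_pred = ndimage.distance_transform_edt(~sp, sampling=pred.spacing)
    return dt_ref[sp], dt_pred[sr]


def assd(pred, ref, connectivity: int = 4) -> float:
    """Average symmetric surface distance in mm.

    Sum of both directed nearest-boundary distance sums, divided by
    |S(pred)| + |S(ref)|.
    """
    pred, ref = _as_mask(pred), _as_mask(ref)
    d_pr, d_rp = _directed_surface_distances(pred, ref, connectivity)
    return float((d_pr.sum() + d_rp.sum()) / (d_pr.size + d_rp.size))


def mssd(pred, ref, connectivity: int = 4) -> float:
    """Maximum symmetric surface distance (symmetric Hausdorff) in mm."""
    pred, ref = _as_mask(pred), _as_mask(ref)
    d_pr, d_rp = _directed_surface_distances(pred, ref, connectivity)
    return float(max(d_pr.max(), d_rp.max()))


QUBIQ_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


def multi_threshold_dice(pred: np.ndarray, ref_continuous: np.ndarray) -> float:
    """Consensus-label protocol: binarize both maps at thresholds
    0.1 ... 0.9 (value >= t -> 1), compute DSC at each level and average.

    Both inputs are per-pixel values in [0, 1]; ``pred`` is typically a
    foreground probability map and ``ref_continuous`` a mean of several
    raters' binary annotations.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref_continuous, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    for name, arr in (("pred", pred), ("ref", ref)):
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError(f"{name} values outside [0, 1]")
    scores = [dice_score((pred >= t).astype(np.uint8), (ref >= t).astype(np.uint8))
              for t in QUBIQ_THRESHOLDS]
    return float(np.mean(scores))


def evaluate_pair(pred, ref, connectivity: int = 4,
                  id: str | None = None) -> MetricReport:
    """All four metrics for one pred/ref pair.

    Surface distances are reported as NaN when either mask is empty (they
    are undefined there); RAVD is NaN for an empty reference. ``both_empty``
    flags the conventional DSC = 1.0 case.
    """
    pred, ref = _as_mask(pred), _as_mask(ref)
    _check_compatible(pred, ref)
    c = confusion_counts(pred, ref)
    both_empty = (c.tp + c.fp + c.fn) == 0
    d = dice_score(pred, ref)
    rv = (c.fp - c.fn) / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    try:
        a = assd(pred, ref, connectivity)
        m = mssd(pred, ref, connectivity)
    except ValueError:
        a = m = float("nan")
    return MetricReport(dsc=d, ravd=rv, assd=a, mssd=m,
                        id=id if id is not None else pred.id,
                        both_empty=both_empty)


def stack_slices(masks: Sequence[BinaryMask], slice_spacing: float) -> BinaryMask:
    """Stack per-slice 2D masks into one 3D mask for volume-wise metrics."""
    grids = [m.grid for m in masks]
    sp2 = masks[0].spacing
    if any(m.spacing != sp2 or m.grid.shape != grids[0].shape for m in masks):
        raise ValueError("slices must share shape and in-plane spacing")
    return BinaryMask(np.stack(grids, axis=0),
                      spacing=(float(slice_spacing),) + sp2)
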