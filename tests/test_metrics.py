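"""Metric definitions against hand-enumerated and brute-force oracles."""

import numpy as np
import pytest

from aideseg.metrics import (BinaryMask, QUBIQ_THRESHOLDS, assd,
                             confusion_counts, dice_score, evaluate_pair,
                             mssd, multi_threshold_dice, ravd, stack_slices,
                             surface_points)
from conftest import random_mask_pair


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def surface_oracle(grid, connectivity=4):
    """Loop-based boundary extraction: fg pixel with a bg neighbour."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    h, w = grid.shape
    pts = set()
    for r in range(h):
        for c in range(w):
            if not grid[r, c]:
                continue
            for dr, dc in nbrs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not grid[rr, cc]:
                    pts.add((r, c))
                    break
    return pts


def surface_distance_oracle(pred, ref, spacing=(1.0, 1.0)):
    """O(|S|^2) all-pairs nearest-neighbour scan over boundary points."""
    sp = np.array(sorted(surface_oracle(pred)), dtype=float)
    sr = np.array(sorted(surface_oracle(ref)), dtype=float)
    scale = np.asarray(spacing)
    d = np.linalg.norm((sp[:, None, :] - sr[None, :, :]) * scale, axis=-1)
    d_pr = d.min(axis=1)
    d_rp = d.min(axis=0)
    a = (d_pr.sum() + d_rp.sum()) / (len(sp) + len(sr))
    m = max(d_pr.max(), d_rp.max())
    return a, m


# --------------------------------------------------------------------------
# confusion counts and overlap metrics
# --------------------------------------------------------------------------

def test_confusion_identity_case():
    ref = np.zeros((10, 10), dtype=np.uint8)
    ref[2:3, 0:5] = 1      # 5 foreground pixels of 100
    c = confusion_counts(ref, ref)
    assert (c.tp, c.fp, c.fn, c.tn) == (5, 0, 0, 95)


def test_confusion_all_background_prediction():
    ref = np.zeros((5, 5), dtype=np.uint8)
    ref.flat[:7] = 1
    c = confusion_counts(np.zeros_like(ref), ref)
    assert (c.tp, c.fp, c.fn) == (0, 0, 7)


def test_confusion_hand_enumerated_4x4():
    # overlap on 2 pixels, one pred-only, one ref-only
    pred = np.zeros((4, 4), dtype=np.uint8)
    ref = np.zeros((4, 4), dtype=np.uint8)
    pred[1, 1] = pred[1, 2] = ref[1, 1] = ref[1, 2] = 1
    pred[2, 1] = 1   # pred-only
    ref[2, 2] = 1    # ref-only
    c = confusion_counts(pred, ref)
    assert (c.tp, c.fp, c.fn) == (2, 1, 1)
    assert c.total == 16
    assert dice_score(pred, ref) == pytest.approx(4 / 6)


def test_confusion_shape_mismatch_names_both_shapes():
    with pytest.raises(ValueError, match=r"\(4, 4\).*\(5, 5\)"):
        confusion_counts(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.uint8))


def test_dice_trivial_cases():
    a = np.zeros((6, 6), dtype=np.uint8)
    a[1:3, 1:3] = 1
    b = np.zeros_like(a)
    b[4:6, 4:6] = 1
    assert dice_score(a, a) == 1.0
    assert dice_score(a, b) == 0.0
    assert dice_score(np.zeros_like(a), np.zeros_like(a)) == 1.0


def test_dice_symmetry_and_ravd_area_identity(rng):
    for _ in range(50):
        pred, ref = random_mask_pair(rng, max_size=16)
        assert dice_score(pred, ref) == dice_score(ref, pred)
        expected = (int(pred.sum()) - int(ref.sum())) / int(ref.sum())
        assert ravd(pred, ref) == pytest.approx(expected, abs=1e-12)


def test_ravd_one_pixel_cases():
    ref = np.zeros((6, 6), dtype=np.uint8)
    ref[2:4, 2:4] = 1     # |ref| = 4
    plus = ref.copy(); plus[0, 0] = 1
    minus = ref.copy(); minus[2, 2] = 0
    assert ravd(plus, ref) == pytest.approx(0.25)
    assert ravd(minus, ref) == pytest.approx(-0.25)
    assert ravd(ref, ref) == 0.0
    with pytest.raises(ValueError, match="empty"):
        ravd(ref, np.zeros_like(ref))


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------

def test_surface_single_pixel_and_filled_square():
    m = np.zeros((7, 7), dtype=np.uint8)
    m[3, 3] = 1
    assert {tuple(p) for p in surface_points(m).points} == {(3, 3)}
    sq = np.zeros((7, 7), dtype=np.uint8)
    sq[2:5, 2:5] = 1
    pts = {tuple(p) for p in surface_points(sq, connectivity=4).points}
    assert len(pts) == 8 and (3, 3) not in pts


def test_surface_all_foreground_has_no_boundary():
    # no background neighbours anywhere; image border is not background
    m = np.ones((8, 8), dtype=np.uint8)
    assert len(surface_points(m)) == 0


@pytest.mark.parametrize("connectivity", [4, 8])
def test_surface_matches_loop_oracle(rng, connectivity):
    for _ in range(20):
        pred, _ = random_mask_pair(rng, max_size=12)
        got = {tuple(p) for p in surface_points(pred, connectivity).points}
        assert got == surface_oracle(pred, connectivity)


# --------------------------------------------------------------------------
# surface distances
# --------------------------------------------------------------------------

def test_assd_mssd_single_pixel_pairs():
    a = np.zeros((8, 8), dtype=np.uint8)
    b = np.zeros_like(a)
    a[2, 2] = 1
    b[2, 5] = 1      # 3 pixels apart along the column axis
    assert assd(a, b) == pytest.approx(3.0)
    assert mssd(a, b) == pytest.approx(3.0)
    assert assd(a, a) == 0.0 and mssd(a, a) == 0.0
    # anisotropic spacing along the separating axis
    am = BinaryMask(a, spacing=(1.0, 2.0))
    bm = BinaryMask(b, spacing=(1.0, 2.0))
    assert mssd(am, bm) == pytest.approx(6.0)
    assert assd(am, bm) == pytest.approx(6.0)


def test_assd_mssd_match_brute_force(rng):
    for _ in range(30):
        pred, ref = random_mask_pair(rng, max_size=16)
        oa, om = surface_distance_oracle(pred, ref)
        assert assd(pred, ref) == pytest.approx(oa, abs=1e-9)
        assert mssd(pred, ref) == pytest.approx(om, abs=1e-9)


def test_spacing_scaling_property(rng):
    pred, ref = random_mask_pair(rng, max_size=16)
    base_a, base_m = assd(pred, ref), mssd(pred, ref)
    c = 2.5
    pm = BinaryMask(pred, spacing=(c, c))
    rm = BinaryMask(ref, spacing=(c, c))
    assert assd(pm, rm) == pytest.approx(c * base_a, rel=1e-12)
    assert mssd(pm, rm) == pytest.approx(c * base_m, rel=1e-12)
    assert dice_score(pm, rm) == dice_score(pred, ref)


def test_assd_le_mssd_and_zero_iff_coincide(rng):
    for _ in range(20):
        pred, ref = random_mask_pair(rng, max_size=12)
        a, m = assd(pred, ref), mssd(pred, ref)
        assert a <= m + 1e-12
        same_surface = (surface_oracle(pred) == surface_oracle(ref))
        assert (m == 0.0) == same_surface


def test_surface_distance_raises_on_empty():
    a = np.zeros((8, 8), dtype=np.uint8)
    b = a.copy(); b[3, 3] = 1
    with pytest.raises(ValueError):
        assd(a, b)
    with pytest.raises(ValueError):
        mssd(b, a)


def test_volume_wise_metrics_via_slice_stack():
    sl = np.zeros((8, 8), dtype=np.uint8)
    sl[3:5, 3:5] = 1
    vol = stack_slices([BinaryMask(sl), BinaryMask(sl)], slice_spacing=5.0)
    assert vol.grid.shape == (2, 8, 8)
    assert vol.spacing == (5.0, 1.0, 1.0)
    assert dice_score(vol, vol) == 1.0
    assert assd(vol, vol) == 0.0


# --------------------------------------------------------------------------
# multi-threshold consensus protocol
# --------------------------------------------------------------------------

def multi_threshold_oracle(pred, ref):
    out = []
    for t in QUBIQ_THRESHOLDS:
        p = (pred >= t).astype(np.uint8)
        r = (ref >= t).astype(np.uint8)
        out.append(dice_score(p, r))
    return float(np.mean(out))


def test_multi_threshold_trivial_and_constant_cases():
    binary = np.zeros((8, 8)); binary[2:5, 2:5] = 1.0
    assert multi_threshold_dice(binary, binary) == 1.0
    const = np.full((4, 4), 0.55)
    assert multi_threshold_dice(const, const) == 1.0


def test_multi_threshold_enumerated_mixed_case():
    pred = np.full((4, 4), 0.35)
    ref = np.full((4, 4), 0.75)
    # thresholds .1-.3: both all-one (DSC 1); .4-.7: pred empty vs full
    # (DSC 0); .8-.9: both empty (DSC 1) -> mean 5/9
    expected = 5 / 9
    assert multi_threshold_dice(pred, ref) == pytest.approx(expected)
    assert multi_threshold_oracle(pred, ref) == pytest.approx(expected)


def test_multi_threshold_matches_oracle_on_random_maps(rng):
    for _ in range(10):
        pred = rng.random((12, 12))
        ref = rng.random((12, 12))
        assert multi_threshold_dice(pred, ref) == pytest.approx(
            multi_threshold_oracle(pred, ref))


def test_multi_threshold_rejects_out_of_range():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        multi_threshold_dice(np.full((2, 2), 1.5), np.zeros((2, 2)))


# --------------------------------------------------------------------------
# report assembly and mask validation
# --------------------------------------------------------------------------

def test_evaluate_pair_reports_and_flags():
    a = np.zeros((8, 8), dtype=np.uint8)
    rep = evaluate_pair(a, a, id="empty")
    assert rep.dsc == 1.0 and rep.both_empty
    assert np.isnan(rep.assd) and np.isnan(rep.ravd)
    b = a.copy(); b[2:4, 2:4] = 1
    rep2 = evaluate_pair(b, b)
    assert rep2.dsc == 1.0 and rep2.assd == 0.0 and not rep2.both_empty


def test_binary_mask_validation():
    with pytest.raises(ValueError, match="0 or 1"):
        BinaryMask(np.array([[0, 2]]))
    with pytest.raises(ValueError, match="positive"):
        BinaryMask(np.zeros((2, 2), np.uint8), spacing=(0.0, 1.0))
    with pytest.raises(ValueError, match="spacing"):
        BinaryMask(np.zeros((2, 2), np.uint8), spacing=(1.0, 1.0, 1.0))
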