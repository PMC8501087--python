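"""Engine mechanics: filtering, scheduling, correction, reproducibility."""

import numpy as np
import pytest

from aideseg.engine import (AideConfig, BatchPartition, LabelStore,
                            TrainingData, _batched_pseudo_labels,
                            derive_rngs, fit, global_label_correction,
                            partition_batch, predict_ensemble, ramp_weight,
                            should_correct, train_iteration)
from aideseg.losses import pseudo_label_from_augmentations
from aideseg.nn import ModelSpec, build_model, make_optimizer
from aideseg.standardize import PretrainConfig, pretrain_baseline
from aideseg.synthdata import PhantomSpec, make_scenario


def tiny_scenario(n_high=2, n_low=6, size=32, seed=11):
    return make_scenario(mode="nll", n_high=n_high, n_low=n_low,
                         phantom=PhantomSpec(size=size, seed=1), seed=seed)


# --------------------------------------------------------------------------
# batch partitioning and schedules
# --------------------------------------------------------------------------

def test_partition_batch_examples():
    losses = [0.1, 0.9, 0.5, 0.2]
    part = partition_batch(losses, 0.5)
    assert set(part.noisy_ids) == {1, 2}
    assert set(part.clean_ids) == {0, 3}
    assert partition_batch(losses, 0.0).noisy_ids == ()
    assert partition_batch(losses, 1.0).clean_ids == ()
    with pytest.raises(ValueError, match="filter_fraction"):
        partition_batch(losses, 1.5)
    with pytest.raises(ValueError, match="finite"):
        partition_batch([0.1, np.nan], 0.5)


def test_partition_batch_tie_break_ascending_id():
    part = partition_batch([0.5, 0.5, 0.5, 0.1], 0.5, ids=[7, 3, 5, 1])
    assert part.noisy_ids == (3, 5)   # equal losses -> smallest ids first


def test_partition_sizes_follow_rounding(rng):
    for n in (3, 5, 8):
        for frac in (0.0, 0.25, 0.5, 0.8, 1.0):
            part = partition_batch(rng.random(n), frac)
            assert len(part.noisy_ids) == int(np.floor(frac * n + 0.5))
            assert set(part.noisy_ids) | set(part.clean_ids) == set(range(n))


def test_ramp_weight_schedule():
    assert ramp_weight(0, 10) == 0.0
    assert ramp_weight(5, 10) == 0.5
    assert ramp_weight(10, 10) == 1.0
    assert ramp_weight(99, 10) == 1.0
    assert ramp_weight(3, 0) == 1.0     # disabled ramp -> constant 1
    vals = [ramp_weight(e, 7) for e in range(20)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_should_correct_rules():
    cfg = AideConfig(warmup_epochs=5, correction_period=10)
    on = {e for e in range(40) if should_correct(e, cfg)}
    assert on == {0, 1, 2, 3, 4, 15, 25, 35}
    cfg0 = AideConfig(warmup_epochs=0, correction_period=10)
    assert should_correct(0, cfg0)
    assert not should_correct(1, cfg0)
    assert should_correct(10, cfg0)


# --------------------------------------------------------------------------
# label store and global correction
# --------------------------------------------------------------------------

def test_label_store_protects_high_quality_and_audits():
    labels = np.zeros((3, 8, 8), dtype=np.uint8)
    store = LabelStore(labels, [True, False, False])
    with pytest.raises(ValueError, match="high-quality"):
        store.replace_label(0, np.ones((8, 8)), 0, 1.0, 1.0)
    store.replace_label(1, np.ones((8, 8)), 0, 0.4, 1.0)
    assert len(store.audit) == 1 and store.audit[0].id == "1"
    assert store.labels[1].all()


def make_store_and_data(n, hq_mask, size=16, fg=True):
    rng = np.random.default_rng(3)
    labels = np.zeros((n, size, size), dtype=np.uint8)
    for i in range(n):
        labels[i, 2:2 + i % 5 + 2, 3:9] = 1
    images = rng.random((n, 1, size, size)).astype(np.float32)
    data = TrainingData(images, tuple(f"s{i:02d}" for i in range(n)))
    store = LabelStore(labels, hq_mask, list(data.ids))
    return data, store


def test_global_correction_fixed_point_and_count():
    n = 10
    data, store = make_store_and_data(n, [True, True] + [False] * 8)
    cfg = AideConfig(warmup_epochs=1, correction_fraction=0.25)
    before = store.labels.copy()
    preds = store.labels.astype(float)   # predictions identical to labels
    touched = global_label_correction(None, store, data, 0, cfg,
                                      predictions=preds)
    assert touched == 2                  # floor(0.25 * 8 eligible)
    assert np.array_equal(store.labels, before)   # fixed point
    assert len(store.audit) == 2


def test_global_correction_respects_quality_flags():
    n = 4
    data, store = make_store_and_data(n, [True, False, False, False])
    cfg = AideConfig(warmup_epochs=1, correction_fraction=0.34,
                     postprocess_corrections=False)
    # predictions disagree most with sample 0 (high-quality) then sample 1
    before_hq = store.labels[0].copy()
    preds = store.labels.astype(float)
    preds[0] = 0.0
    preds[1] = 1.0
    global_label_correction(None, store, data, 0, cfg, predictions=preds)
    corrected = {r.id for r in store.audit}
    assert corrected == {"s01"}          # hq sample skipped, next-lowest used
    assert store.labels[1].all()
    assert np.array_equal(store.labels[0], before_hq)   # hq label untouched


def test_global_correction_rejects_off_schedule_calls():
    data, store = make_store_and_data(4, [False] * 4)
    cfg = AideConfig(warmup_epochs=5, correction_period=10)
    with pytest.raises(RuntimeError, match="schedule"):
        global_label_correction(None, store, data, 7, cfg,
                                predictions=store.labels.astype(float))


# --------------------------------------------------------------------------
# training iterations
# --------------------------------------------------------------------------

def _setup_pair(sc, base=4, seed=0):
    spec = ModelSpec(1, base)
    rngs = derive_rngs(seed)
    nets = (build_model(spec, rngs["net_a"]), build_model(spec, rngs["net_b"]))
    stores = (LabelStore(sc.labels, sc.high_quality, list(sc.ids)),
              LabelStore(sc.labels, sc.high_quality, list(sc.ids)))
    return nets, stores, rngs


def test_train_iteration_zero_ramp_zeroes_suspected_gradients():
    sc = tiny_scenario()
    nets, stores, rngs = _setup_pair(sc)
    cfg = AideConfig(filter_fraction=1.0, ramp_epochs=10, seed=0,
                     suspected_target="pseudo")
    opts = [make_optimizer("adam", n.params(), 1e-3) for n in nets]
    before = [np.concatenate([w.ravel().copy() for w, _ in n.params()])
              for n in nets]
    rec = train_iteration(sc.images, np.arange(len(sc.ids)), nets, stores,
                          opts, cfg, epoch=0, rng_aug=rngs["augment"])
    assert rec["ramp"] == 0.0
    assert rec["loss_a"] == 0.0 and rec["loss_b"] == 0.0
    after = [np.concatenate([w.ravel() for w, _ in n.params()]) for n in nets]
    for b, a in zip(before, after):
        assert np.array_equal(b, a)      # zero gradient -> zero Adam step


def test_train_iteration_rejects_tiny_batch():
    sc = tiny_scenario()
    nets, stores, rngs = _setup_pair(sc)
    opts = [make_optimizer("adam", n.params(), 1e-3) for n in nets]
    with pytest.raises(ValueError, match=">= 2"):
        train_iteration(sc.images[:1], np.arange(1), nets, stores, opts,
                        AideConfig(), 0, rngs["augment"])


def test_batched_pseudo_labels_match_per_sample_op():
    sc = tiny_scenario()
    net = build_model(ModelSpec(1, 4), 7)
    imgs = sc.images[:3]
    batched = _batched_pseudo_labels(net, imgs, k=4, temperature=0.5,
                                     rng=np.random.default_rng(99))
    rng2 = np.random.default_rng(99)
    singles = [pseudo_label_from_augmentations(
        lambda im: net.predict_proba(im)[1], imgs[i], 4, 0.5, rng2)
        for i in range(3)]
    for b, s in zip(batched, singles):
        assert np.allclose(b.foreground, s.foreground, atol=1e-6)


# --------------------------------------------------------------------------
# fit-level contracts
# --------------------------------------------------------------------------

def test_fit_zero_epochs_returns_initial_state():
    sc = tiny_scenario()
    data = TrainingData(sc.images, sc.ids)
    store = LabelStore(sc.labels, sc.high_quality, list(sc.ids))
    cfg = AideConfig(epochs=0, seed=4)
    net_a, net_b, stores, hist = fit(data, store, cfg, ModelSpec(1, 4))
    ref_a = build_model(ModelSpec(1, 4), derive_rngs(4)["net_a"])
    assert net_a.checksum() == ref_a.checksum()
    assert np.array_equal(stores[0].labels, sc.labels)
    assert hist.records == []


def test_fit_reproducible_under_seed_and_protects_hq_labels():
    sc = tiny_scenario(n_high=2, n_low=6)
    data = TrainingData(sc.images, sc.ids)
    cfg = AideConfig(epochs=2, warmup_epochs=1, ramp_epochs=4, batch_size=4,
                     seed=9)
    runs = []
    for _ in range(2):
        store = LabelStore(sc.labels, sc.high_quality, list(sc.ids))
        runs.append(fit(data, store, cfg, ModelSpec(1, 4)))
    (a1, b1, s1, h1), (a2, b2, s2, h2) = runs
    assert a1.checksum() == a2.checksum()
    assert b1.checksum() == b2.checksum()
    assert np.array_equal(s1[0].labels, s2[0].labels)
    # high-quality labels bit-identical through training
    for st in (s1[0], s1[1]):
        assert np.array_equal(st.labels[:2], sc.labels[:2])
    assert len(h1.records) == 2
    assert [r.n_corrected for r in h1.records] == [r.n_corrected
                                                   for r in h2.records]


def test_degenerate_config_equals_supervised_baseline():
    sc = tiny_scenario(n_high=2, n_low=4)
    data = TrainingData(sc.images, sc.ids)
    store = LabelStore(sc.labels, sc.high_quality, list(sc.ids))
    cfg = AideConfig(filter_fraction=0.0, enable_correction=False, epochs=2,
                     batch_size=4, seed=21)
    net_a, net_b, stores, _ = fit(data, store, cfg, ModelSpec(1, 4))
    pcfg = PretrainConfig(epochs=2, batch_size=4, seed=21)
    base_a, _ = pretrain_baseline(sc.images, sc.labels, ModelSpec(1, 4),
                                  pcfg, which="a")
    base_b, _ = pretrain_baseline(sc.images, sc.labels, ModelSpec(1, 4),
                                  pcfg, which="b")
    assert net_a.checksum() == base_a.checksum()
    assert net_b.checksum() == base_b.checksum()
    assert np.array_equal(stores[0].labels, sc.labels)


def test_predict_ensemble_mean_and_spec_check(rng):
    spec = ModelSpec(1, 4)
    a = build_model(spec, 0)
    b = build_model(spec, 1)
    img = rng.random((1, 32, 32)).astype(np.float32)
    pe = predict_ensemble(a, b, img)
    pa, pb = a.predict_proba(img), b.predict_proba(img)
    assert np.allclose(pe, 0.5 * (pa + pb))
    assert np.allclose(pe.sum(axis=0), 1.0, atol=1e-6)
    same = predict_ensemble(a, a, img)
    assert np.allclose(same, pa)
    with pytest.raises(ValueError, match="spec"):
        predict_ensemble(a, build_model(ModelSpec(1, 8), 0), img)
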