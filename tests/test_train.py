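
import numpy as np
import pytest

from arousalkit.model import UNetSpec
from arousalkit.train import (
    TrainConfig,
    TrainRecord,
    augment,
    cyclic_lr,
    lr_range_test,
    make_split,
    suggest_lr_bounds,
    train_model,
)

TINY = UNetSpec(depth=2, base_filters=2, kernel=5, pool_factor=2)


def _toy_record(rid, rng, t=2000, marked=True):
    """Record whose arousal signature is a large offset on the EEG row."""
    pool = {
        "EEG": [rng.standard_normal(t).astype(np.float32)],
        "EOG": [rng.standard_normal(t).astype(np.float32),
                rng.standard_normal(t).astype(np.float32)],
        "EMG": [rng.standard_normal(t).astype(np.float32)],
    }
    y = np.zeros(t, dtype=np.int8)
    if marked:
        lo = int(rng.integers(200, t - 400))
        pool["EEG"][0][lo : lo + 200] += 3.0
        y[lo : lo + 200] = 1
    return TrainRecord(record_id=rid, channel_pool=pool, y=y)


class TestSplit:
    def test_partition_sizes_and_disjointness(self):
        patients = [f"p{i}" for i in range(10)]
        plan = make_split(patients, test_ids=["p0", "p1"], seed=0)
        tr, va, te = (plan.patients(s) for s in ("train", "val", "test"))
        assert sorted(te) == ["p0", "p1"]
        assert len(tr) + len(va) == 8
        assert 1 <= len(va) <= 2
        assert not (set(tr) & set(va)) and not (set(tr) & set(te))

    def test_recordings_follow_their_patient(self):
        # three recordings of one patient resolve through one assignment
        plan = make_split([f"p{i}" for i in range(5)], seed=1)
        recordings = [("p2", "night1"), ("p2", "night2"), ("p2", "night3")]
        splits = {plan.assignment[pid] for pid, _ in recordings}
        assert len(splits) == 1

    def test_same_seed_same_plan(self):
        patients = [f"p{i}" for i in range(20)]
        assert make_split(patients, seed=9) == make_split(patients, seed=9)

    def test_unknown_test_id_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            make_split(["a", "b"], test_ids=["ghost"])

    def test_no_leakage_across_random_seeds(self):
        patients = [f"p{i}" for i in range(37)]
        for seed in range(10):
            plan = make_split(patients, test_ids=patients[:5], seed=seed)
            groups = [set(plan.patients(s)) for s in ("train", "val", "test")]
            assert sum(len(g) for g in groups) == 37
            assert not (groups[0] & groups[1] | groups[0] & groups[2] | groups[1] & groups[2])


class TestAugment:
    def test_degenerate_range_is_identity(self, rng):
        cfg = TrainConfig(noise_low=1.0, noise_high=1.0)
        x = rng.standard_normal((3, 100)).astype(np.float32)
        np.testing.assert_allclose(augment(x, cfg, rng), x, rtol=1e-6)

    def test_factor_mean_matches_uniform_moment(self):
        cfg = TrainConfig()  # U[0.8, 1.3] -> mean 1.05
        rng = np.random.default_rng(0)
        ones = np.ones((1, 1), dtype=np.float32)
        draws = [float(augment(ones, cfg, rng)[0, 0]) for _ in range(10_000)]
        assert abs(np.mean(draws) - 1.05) < 0.01
        assert min(draws) >= 0.8 and max(draws) <= 1.3

    def test_fixed_seed_reproducible(self):
        cfg = TrainConfig()
        x = np.ones((3, 50), dtype=np.float32)
        a = augment(x, cfg, np.random.default_rng(4))
        b = augment(x, cfg, np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)


class TestCyclicLR:
    def test_triangular_anchor_points(self):
        cfg = TrainConfig()
        assert cyclic_lr(0, cfg) == cfg.lr_high
        assert cyclic_lr(4, cfg) == pytest.approx(cfg.lr_low)
        assert cyclic_lr(8, cfg) == cfg.lr_high
        assert cyclic_lr(12, cfg) == pytest.approx(cfg.lr_low)

    def test_linear_between_anchors(self):
        cfg = TrainConfig()
        mid = 0.5 * (cfg.lr_low + cfg.lr_high)
        assert cyclic_lr(2, cfg) == pytest.approx(mid)
        assert cyclic_lr(6, cfg) == pytest.approx(mid)


class TestTrainModel:
    def test_frozen_model_stops_after_patience(self, rng):
        train = [_toy_record(f"t{i}", rng) for i in range(3)]
        val = [_toy_record(f"v{i}", rng) for i in range(2)]
        cfg = TrainConfig(max_epochs=10, early_stop_patience=1, chunk_samples=512, seed=0)
        # zero optimizer steps per epoch freezes the weights: the first epoch
        # sets the best AUPRC, the second fails to improve, training stops
        _, hist = train_model(TINY, train, val, cfg, steps_per_epoch=0)
        assert len(hist) == 2

    def test_history_bookkeeping_matches_schedule(self, rng):
        train = [_toy_record(f"t{i}", rng) for i in range(3)]
        val = [_toy_record(f"v{i}", rng) for i in range(2)]
        cfg = TrainConfig(max_epochs=3, early_stop_patience=5, chunk_samples=512,
                          batch_size=2, seed=0)
        _, hist = train_model(TINY, train, val, cfg, steps_per_epoch=2)
        assert len(hist) <= cfg.max_epochs
        for h in hist:
            assert h["lr"] == cyclic_lr(h["epoch"], cfg)

    def test_all_negative_labels_rejected(self, rng):
        train = [_toy_record("t", rng, marked=False)]
        val = [_toy_record("v", rng)]
        cfg = TrainConfig(chunk_samples=512)
        with pytest.raises(ValueError, match="positive"):
            train_model(TINY, train, val, cfg)

    def test_determinism_with_fixed_seed(self, rng):
        train = [_toy_record(f"t{i}", rng) for i in range(3)]
        val = [_toy_record(f"v{i}", rng) for i in range(2)]
        cfg = TrainConfig(max_epochs=2, chunk_samples=512, batch_size=2, seed=77)
        _, h1 = train_model(TINY, train, val, cfg, steps_per_epoch=3)
        _, h2 = train_model(TINY, train, val, cfg, steps_per_epoch=3)
        assert h1 == h2

    def test_best_checkpoint_auprc_is_running_max(self, rng):
        train = [_toy_record(f"t{i}", rng) for i in range(4)]
        val = [_toy_record(f"v{i}", rng) for i in range(2)]
        cfg = TrainConfig(max_epochs=4, early_stop_patience=10, chunk_samples=512,
                          batch_size=2, seed=5)
        model, hist = train_model(TINY, train, val, cfg, steps_per_epoch=4)
        from arousalkit.train import _validation_auprc

        assert _validation_auprc(model, val) == pytest.approx(
            max(h["val_auprc"] for h in hist), abs=1e-9
        )


class TestLrRangeTest:
    def test_bounds_within_decreasing_region(self):
        lrs = [1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0]
        losses = [1.0, 0.8, 0.3, 0.1, 2.0, 50.0]  # decreases then explodes
        lo, hi = suggest_lr_bounds(lrs, losses)
        assert lo in lrs and hi in lrs
        assert lo <= hi <= 1e-2  # both inside the decreasing region

    def test_single_element_grid(self):
        assert suggest_lr_bounds([0.01], [0.5]) == (0.01, 0.01)

    def test_flat_curve_returns_full_span_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            lo, hi = suggest_lr_bounds([1e-4, 1e-3, 1e-2], [0.7, 0.7, 0.7])
        assert (lo, hi) == (1e-4, 1e-2)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            suggest_lr_bounds([1e-3, 1e-4], [1.0, 1.0])

    def test_probe_run_on_toy_data(self, rng):
        train = [_toy_record(f"t{i}", rng) for i in range(3)]
        cfg = TrainConfig(chunk_samples=512, seed=0)
        lo, hi = lr_range_test(TINY, train, [1e-4, 1e-3, 1e-2], cfg, steps_per_lr=4)
        assert 1e-4 <= lo <= hi <= 1e-2
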