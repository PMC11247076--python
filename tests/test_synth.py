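import numpy as np
import pytest

from arousalkit.io_psg import read_events, read_hypnogram, read_metadata_table, read_recording
from arousalkit.metrics import arousal_index
from arousalkit.synth import (
    SynthConfig,
    generate_cohort,
    generate_events,
    generate_hypnogram,
    generate_recording,
    simulate_predictions,
)

CHMAP = {"EEG": ["C3:A2", "C4:A1"], "EOG": ["EOG-L", "EOG-R"], "EMG": ["Chin"]}


class TestConfig:
    def test_infeasible_rate_rejected(self):
        # 3600/ari must exceed the minimum gap plus the longest arousal
        with pytest.raises(ValueError, match="infeasible"):
            SynthConfig(target_ari=200.0)

    def test_durations_outside_aasm_range_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(arousal_dur_range=(1.0, 15.0))
        with pytest.raises(ValueError):
            SynthConfig(arousal_dur_range=(3.0, 20.0))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(duration_s=300.0, seed=5)
        a = generate_recording(cfg, np.random.default_rng(5))
        b = generate_recording(cfg, np.random.default_rng(5))
        assert a[1].events == b[1].events
        assert a[2].stages == b[2].stages
        assert a[3] == b[3]
        for name in a[0].signals:
            np.testing.assert_array_equal(a[0].signals[name], b[0].signals[name])


class TestEvents:
    def test_constraints_hold(self):
        cfg = SynthConfig(duration_s=7200.0)
        rng = np.random.default_rng(3)
        hyp = generate_hypnogram(cfg, rng)
        events = generate_events(cfg, hyp, rng)
        assert len(events) > 0
        prev_end = None
        for onset, dur, _ in events:
            assert 3.0 <= dur <= 15.0
            # fully inside sleep
            assert hyp.stage_at(onset) != "W"
            assert hyp.stage_at(onset + dur - 1e-6) != "W"
            if prev_end is not None and onset - prev_end < 10.0:
                # gaps under 10 s may only occur across separate sleep regions
                assert any(hyp.stage_at(t) == "W" for t in np.arange(prev_end, onset, 15.0))
            prev_end = onset + dur

    def test_rate_tracks_target(self):
        cfg = SynthConfig(duration_s=8 * 3600.0, target_ari=25.0)
        rng = np.random.default_rng(0)
        aris = []
        for _ in range(20):
            hyp = generate_hypnogram(cfg, rng)
            events = generate_events(cfg, hyp, rng)
            aris.append(arousal_index(events, hyp))
        assert abs(np.mean(aris) - 25.0) < 2.0


class TestSignals:
    def test_burst_raises_band_power(self, short_recording):
        from scipy.signal import butter, sosfiltfilt

        rec, events, hyp, _ = short_recording
        assert len(events) > 0
        x = rec.signals["C3:A2"]
        sos = butter(4, [12, 20], btype="band", fs=200, output="sos")
        bp = sosfiltfilt(sos, x) ** 2
        mask = np.zeros(len(x), dtype=bool)
        for o, d, _ in events:
            mask[int(o * 200) : int((o + d) * 200)] = True
        assert bp[mask].mean() > 10 * bp[~mask].mean()

    def test_rem_arousal_raises_emg(self):
        cfg = SynthConfig(duration_s=3600.0, seed=21)
        for seed in range(21, 40):
            rng = np.random.default_rng(seed)
            rec, events, hyp, _ = generate_recording(cfg, rng)
            rem_events = [e for e in events if hyp.stage_at(e[0]) == "R"]
            if not rem_events:
                continue
            emg = rec.signals["Chin"]
            o, d, _ = rem_events[0]
            inside = emg[int(o * 200) : int((o + d) * 200)].std()
            # same REM epoch, outside the event
            epoch = int(o // 30)
            base = emg[epoch * 6000 : int(o * 200)]
            if len(base) < 200:
                continue
            assert inside > 1.5 * base.std()
            return
        pytest.skip("no REM arousal drawn in probed seeds")

    def test_generated_data_satisfies_io_preconditions(self, short_recording):
        rec = short_recording[0]
        for role in ("EEG", "EOG", "EMG"):
            assert rec.channels_for(role)
        for name, x in rec.signals.items():
            assert len(x) == round(rec.duration_s * rec.sample_rate[name])
            assert np.all(np.isfinite(x))


class TestCohort:
    def test_bundles_round_trip(self, tmp_path):
        cfg = SynthConfig(n_records=4, duration_s=120.0, seed=2)
        ids = generate_cohort(cfg, tmp_path)
        assert len(ids) == 4
        metas = read_metadata_table(tmp_path / "metadata.csv")
        for rid in ids:
            rec = read_recording(tmp_path / f"{rid}.edf", CHMAP)
            events = read_events(tmp_path / f"{rid}.events.tsv")
            hyp = read_hypnogram(tmp_path / f"{rid}.hyp.txt")
            assert rec.duration_s == 120.0
            assert len(hyp) == 4
            assert rid in metas

    def test_group_effect_changes_prediction_error(self, tmp_path):
        cfg = SynthConfig(n_records=6, duration_s=1800.0, seed=8)
        effects = {"NormalFinding": 0.0, "SRBD": 8.0}
        ids = generate_cohort(cfg, tmp_path, group_effects=effects)
        metas = read_metadata_table(tmp_path / "metadata.csv")
        errs = {"NormalFinding": [], "SRBD": []}
        for rid in ids:
            truth = read_events(tmp_path / f"{rid}.events.tsv")
            pred = read_events(tmp_path / f"{rid}.pred.tsv")
            hyp = read_hypnogram(tmp_path / f"{rid}.hyp.txt")
            g = next(iter(metas[rid].diagnosis_groups))
            errs[g].append(abs(arousal_index(pred, hyp) - arousal_index(truth, hyp)))
        assert np.mean(errs["SRBD"]) > np.mean(errs["NormalFinding"])


class TestSimulatePredictions:
    def test_rates_roughly_respected(self):
        cfg = SynthConfig(duration_s=6 * 3600.0, target_ari=20.0)
        rng = np.random.default_rng(1)
        hyp = generate_hypnogram(cfg, rng)
        truth = generate_events(cfg, hyp, rng)
        pred = simulate_predictions(truth, hyp, rng, fp_per_hour=5.0, fn_prob=0.0)
        tst_h = hyp.total_sleep_time_s() / 3600
        extra = (len(pred) - len(truth)) / tst_h
        assert 1.0 < extra < 10.0

    def test_effect_size_recovery_via_stats_module(self):
        # a shifted spurious-detection rate in one group should surface as a
        # moderate Cohen's d of the ArI error against the reference group
        from arousalkit.stats import group_bias_analysis

        cfg = SynthConfig(duration_s=4 * 3600.0, target_ari=20.0)
        rng = np.random.default_rng(42)
        errors = {"NormalFinding": [], "SRBD": []}
        for group, fp_rate in (("NormalFinding", 3.0), ("SRBD", 4.3)):
            for _ in range(120):
                hyp = generate_hypnogram(cfg, rng)
                truth = generate_events(cfg, hyp, rng)
                pred = simulate_predictions(truth, hyp, rng, fp_per_hour=fp_rate, fn_prob=0.05)
                errors[group].append(
                    abs(arousal_index(pred, hyp) - arousal_index(truth, hyp))
                )
        gc = group_bias_analysis(errors)
        assert gc.results["SRBD"].cohens_d > 0
        assert gc.results["SRBD"].effect_bin in ("small", "moderate", "large")
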