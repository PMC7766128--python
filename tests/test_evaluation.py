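import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exobci import evaluation as ev
from exobci import synth
from exobci.filterbank import FilterBank
from exobci.fsm import Action


class TestComputeRates:
    def test_perfect_counts(self):
        rates = ev.compute_rates(ev.ConfusionCounts(10, 10, 0, 0))
        assert rates == {"TPR": 1.0, "FPR": 0.0, "ACC": 1.0}

    def test_hand_computed_example(self):
        rates = ev.compute_rates(ev.ConfusionCounts(8, 7, 3, 2))
        assert rates["TPR"] == pytest.approx(0.8)
        assert rates["FPR"] == pytest.approx(0.3)
        assert rates["ACC"] == pytest.approx(0.75)

    def test_zero_denominator_flagged_not_fatal(self):
        rates = ev.compute_rates(ev.ConfusionCounts(0, 5, 2, 0))
        assert rates["TPR"] is None
        assert rates["FPR"] == pytest.approx(2 / 7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionCounts(-1, 0, 0, 0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 5000))
    def test_matches_brute_force_recount(self, seed):
        r = np.random.default_rng(seed)
        preds = r.integers(0, 2, 50)
        truth = r.integers(0, 2, 50)
        counts = ev.count_confusions(preds, truth, positive=1)
        # independent recount
        tp = int(np.sum((preds == 1) & (truth == 1)))
        tn = int(np.sum((preds == 0) & (truth == 0)))
        fp = int(np.sum((preds == 1) & (truth == 0)))
        fn = int(np.sum((preds == 0) & (truth == 1)))
        assert (counts.nTP, counts.nTN, counts.nFP, counts.nFN) == (tp, tn, fp, fn)
        rates = ev.compute_rates(counts)
        if tp + fn:
            assert rates["TPR"] == pytest.approx(tp / (tp + fn))
        if counts.total:
            assert rates["ACC"] == pytest.approx((tp + tn) / 50)

    def test_online_score_is_min_of_two(self):
        assert ev.online_decoder_accuracy(0.9, 0.84) == 0.84


class TestBitRate:
    def test_perfect_accuracy_log2_3(self):
        assert ev.bit_rate(1.0, 3) == pytest.approx(np.log2(3))

    def test_chance_level_zero(self):
        assert ev.bit_rate(1 / 3, 3) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_at_08(self):
        expected = np.log2(3) + 0.8 * np.log2(0.8) + 0.2 * np.log2(0.2 / 2)
        assert ev.bit_rate(0.8, 3) == pytest.approx(expected)

    def test_monotone_increasing_on_valid_range(self):
        ps = np.linspace(1 / 3, 1.0, 50)
        vals = [ev.bit_rate(p, 3) for p in ps]
        assert np.all(np.diff(vals) > -1e-12)

    def test_below_chance_warns(self):
        with pytest.warns(UserWarning, match="below chance"):
            ev.bit_rate(0.2, 3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ev.bit_rate(1.2, 3)
        with pytest.raises(ValueError):
            ev.bit_rate(0.5, 1)


class TestITR:
    def test_zero_bit_rate_zero_itr(self):
        assert ev.itr(1 / 3, 3, fd=10.0) == pytest.approx(0.0, abs=1e-12)

    def test_default_decision_rates(self):
        assert ev.FD_OFFLINE == 4.60
        assert ev.FD_ONLINE == 5.97

    def test_product_form(self):
        assert ev.itr(0.9, 3, fd=5.97) == pytest.approx(5.97 * ev.bit_rate(0.9, 3))

    def test_nonpositive_fd_rejected(self):
        with pytest.raises(ValueError):
            ev.itr(0.9, 3, fd=0.0)


class TestMetricsReport:
    def test_from_counts_with_itr(self):
        rep = ev.MetricsReport.from_counts(ev.ConfusionCounts(8, 7, 3, 2),
                                           n_tasks=3, fd=4.6)
        assert rep.ACC == pytest.approx(0.75)
        assert rep.ITR == pytest.approx(4.6 * ev.bit_rate(0.75, 3))


class TestBootstrap:
    def test_small_session_mean_high(self, small_session):
        rec, trials = small_session
        res = ev.bootstrap_offline_accuracy(rec, trials, "gvs", n_reps=10, seed=0)
        assert res["mean"] > 80.0

    def test_permuted_labels_near_chance(self, small_session):
        rec, trials = small_session
        res = ev.bootstrap_offline_accuracy(rec, trials, "gvn", n_reps=15,
                                            seed=0, permute_labels=True)
        assert 30.0 < res["mean"] < 70.0

    def test_reproducible_for_fixed_seed(self, small_session):
        rec, trials = small_session
        r1 = ev.bootstrap_offline_accuracy(rec, trials, "gvn", n_reps=4, seed=3)
        r2 = ev.bootstrap_offline_accuracy(rec, trials, "gvn", n_reps=4, seed=3)
        assert np.array_equal(r1["accuracies"], r2["accuracies"])

    def test_too_few_trials_rejected(self, small_session):
        rec, trials = small_session
        with pytest.raises(ValueError, match="too few"):
            ev.bootstrap_offline_accuracy(rec, trials.head(8), "gvn")


class TestFisherRatioMap:
    def test_identical_distributions_near_zero(self, rng):
        a = [rng.standard_normal((31, 1000)) for _ in range(10)]
        b = [rng.standard_normal((31, 1000)) for _ in range(10)]
        fr = ev.fisher_ratio_map(a, b, normalize=False)
        assert np.nanmean(fr) < 0.5  # ~chi2 scale, no structure

    def test_shape_31x6(self, rng):
        a = [rng.standard_normal((31, 1000)) for _ in range(3)]
        b = [rng.standard_normal((31, 1000)) for _ in range(3)]
        assert ev.fisher_ratio_map(a, b).shape == (31, 6)

    def test_cz_erd_argmax(self, small_session):
        from exobci import decoder as dec
        rec, trials = small_session
        fs = rec.sfreq
        def cut(label, span):
            out = []
            for r in trials[trials.label == label].itertuples():
                i0 = int((r.onset_s + 1.0) * fs)
                out.append(rec.data[:, i0:i0 + int(span * fs)])
            return out
        fr = ev.fisher_ratio_map(cut(synth.GAIT_MI, 4.0), cut(synth.NOTHING, 4.0),
                                 fs=fs)
        ch, band = np.unravel_index(np.nanargmax(fr), fr.shape)
        # Gait ERD is midline-weighted in 10-15 Hz -> bands (10,12) or (13,15)
        assert rec.montage.channel_names[ch] in ("Cz", "C1", "C2")
        assert band in (1, 2)

    def test_normalized_max_is_one(self, rng):
        a = [rng.standard_normal((4, 800)) * 2 for _ in range(5)]
        b = [rng.standard_normal((4, 800)) for _ in range(5)]
        fr = ev.fisher_ratio_map(a, b)
        assert np.nanmax(fr) == pytest.approx(1.0)

    def test_too_few_trials_rejected(self, rng):
        a = [rng.standard_normal((4, 800))]
        with pytest.raises(ValueError, match="2 trials"):
            ev.fisher_ratio_map(a, a)


class TestERSP:
    def test_stationary_noise_near_zero_db(self, rng):
        trials = [rng.standard_normal(3000) for _ in range(30)]
        out = ev.ersp(trials, fs=500.0, freqs=np.arange(8, 20, 2.0))
        core = out["power_db"][:, 500:-500]
        assert np.abs(core.mean(axis=1)).max() < 1.0

    def test_amplitude_scale_invariance(self, rng):
        trials = [rng.standard_normal(2000) for _ in range(5)]
        a = ev.ersp(trials, freqs=np.arange(8, 16, 2.0))
        b = ev.ersp([2.0 * t for t in trials], freqs=np.arange(8, 16, 2.0))
        assert np.allclose(a["power_db"], b["power_db"], atol=1e-9)

    def test_erd_negative_db_during_mi(self, small_session):
        rec, trials = small_session
        fs = rec.sfreq
        cz = rec.channel("Cz")
        cut = []
        for r in trials[trials.label == synth.GAIT_MI].itertuples():
            i0 = int((r.onset_s - 1.0) * fs)
            cut.append(cz[i0:i0 + int(10.0 * fs)])  # -1..9 s around cue
        out = ev.ersp(cut, fs=fs, freqs=np.arange(10, 16, 1.0))
        mi_span = slice(int(2.5 * fs), int(8.5 * fs))   # 1.5-7.5 s post-cue
        assert out["power_db"][:, mi_span].mean() < -1.0

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="same length"):
            ev.ersp([rng.standard_normal(100), rng.standard_normal(101)])


class TestScenarioTiming:
    def _actions(self, times):
        names = [Action.STAND_UP, Action.GAIT_START, Action.GAIT_STOP,
                 Action.GAIT_START, Action.GAIT_STOP, Action.SIT_DOWN]
        return list(zip(times, names))

    def test_ratio_arithmetic(self):
        res = ev.scenario_timing(self._actions([10, 30, 60, 80, 110, 145]),
                                 reference_s=100.0)
        assert res.completed
        assert res.completion_s == pytest.approx(145.0)
        assert res.time_ratio_pct == pytest.approx(145.0)

    def test_incomplete_scenario_flagged(self):
        partial = self._actions([10, 30, 60, 80, 110, 145])[:4]
        res = ev.scenario_timing(partial, reference_s=100.0)
        assert not res.completed
        assert res.completion_s is None
        assert res.time_ratio_pct is None

    def test_start_offset(self):
        res = ev.scenario_timing(self._actions([70, 90, 110, 130, 150, 165]),
                                 reference_s=100.0, start_s=65.0)
        assert res.completion_s == pytest.approx(100.0)
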