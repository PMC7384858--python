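import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirrorpop import preprocess as pp
from mirrorpop import synthetic_data as sd
from mirrorpop.dataio import TrialRecord
from mirrorpop.preprocess import (
    ANOVA_EPOCHS,
    CORRELATION_EPOCHS,
    NormalizationSpec,
    RateTensor,
)


class TestBinSpikes:
    def test_no_spikes(self):
        assert np.array_equal(pp.bin_spikes([], (0, 100), 10), np.zeros(10))

    def test_boundary_spike_goes_right(self):
        # spike exactly at a bin edge t belongs to the bin starting at t
        counts = pp.bin_spikes([20.0], (0, 100), 10)
        assert counts[2] == 1 and counts.sum() == 1

    def test_spike_at_window_end_excluded(self):
        assert pp.bin_spikes([100.0], (0, 100), 10).sum() == 0

    def test_histogram_oracle_uniform(self, rng):
        spikes = rng.uniform(0, 1000, 1000)
        counts = pp.bin_spikes(spikes, (0, 1000), 10)
        assert counts.sum() == 1000
        # independent oracle: numpy digitize
        oracle = np.bincount(np.digitize(spikes, np.arange(0, 1000, 10)) - 1,
                             minlength=100)
        assert np.array_equal(counts, oracle)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="empty"):
            pp.bin_spikes([1.0], (100, 100), 10)

    def test_bad_width_raises(self):
        with pytest.raises(ValueError):
            pp.bin_spikes([1.0], (0, 100), 0)

    @given(st.lists(st.floats(0, 999), max_size=50))
    @settings(max_examples=25, deadline=None)
    def test_count_conservation(self, spikes):
        assert pp.bin_spikes(spikes, (0, 1000), 7).sum() == len(spikes)


class TestSmoothing:
    def test_constant_preserved(self):
        x = np.full(200, 7.5)
        np.testing.assert_allclose(pp.smooth_gaussian(x, 50, 10), x, atol=1e-12)

    def test_pulse_matches_closed_form(self):
        # single-bin pulse far from edges -> sampled Gaussian to 1e-10
        x = np.zeros(401)
        x[200] = 1.0
        out = pp.smooth_gaussian(x, 50, 10)
        t = (np.arange(401) - 200) * 10.0
        kern = np.exp(-0.5 * (t / 50.0) ** 2)
        kern[np.abs(t) > 200.0] = 0.0  # truncation at 4 SD
        kern /= kern.sum()
        np.testing.assert_allclose(out, kern, atol=1e-10)

    def test_mass_conserved(self):
        x = np.zeros(100)
        x[50] = 3.0
        assert pp.smooth_gaussian(x, 50, 10).sum() == pytest.approx(3.0, abs=1e-6)

    def test_2d_rows_independent(self, rng):
        x = rng.normal(size=(3, 120))
        out = pp.smooth_gaussian(x, 30, 10)
        np.testing.assert_allclose(out[1], pp.smooth_gaussian(x[1], 30, 10))

    def test_bad_sd(self):
        with pytest.raises(ValueError):
            pp.gaussian_kernel(0, 10)


def _const_rate_trial(index, rate_hz, events, start, stop, nid="n0",
                      condition="execution", grasp="PG"):
    # deterministic regular spike train at rate_hz
    step = 1000.0 / rate_hz
    spikes = np.arange(start, stop, step)
    return TrialRecord(index, condition, grasp, events, {nid: spikes},
                       "correct", start, stop)


class TestMultiAlign:
    def _events(self, go, rt, mt):
        return {"LCDon": go - 1050.0, "ObjCue": go - 800.0, "GoNogo": go,
                "HPR": go + rt, "DO": go + rt + mt, "HO": go + rt + mt + 100.0,
                "HOFF": go + rt + mt + 1100.0, "HPN": go + rt + mt + 1500.0}

    def test_identity_when_events_canonical(self):
        # all trials at canonical times -> equals single-aligned average
        trials = [
            _const_rate_trial(i, 50.0, self._events(2000.0, 300.0, 300.0),
                              0.0, 6000.0)
            for i in range(4)
        ]
        canonical = {"GoNogo": 0.0, "HPR": 300.0, "DO": 600.0}
        out = pp.multi_align(trials, ["n0"], canonical, (-500, 1500),
                             smooth_sd=50.0)
        single = pp.psth_single(trials, ["n0"], "GoNogo", (-500, 1500),
                                smooth_sd=50.0)
        # identical away from the window edges (the stitched version has
        # extra kernel support there; the single-aligned one renormalizes)
        np.testing.assert_allclose(out.values[:, 25:-25],
                                   single.values[:, 25:-25], atol=1e-9)

    def test_constant_rate_flat_output(self):
        trials = [
            _const_rate_trial(i, 40.0, self._events(2000.0 + 13 * i, 250.0 + 7 * i,
                                                    280.0 + 11 * i), 0.0, 6000.0)
            for i in range(5)
        ]
        canonical = {"GoNogo": 0.0, "HPR": 280.0, "DO": 570.0}
        out = pp.multi_align(trials, ["n0"], canonical, (-500, 1500))
        assert np.all(np.abs(out.values - 40.0) < 1.0)

    def test_continuity_at_boundaries(self, small_bundle):
        trials = small_bundle.select_trials("execution", "PG")
        canonical = pp.canonical_event_times(
            small_bundle.select_trials("execution"))
        out = pp.multi_align(trials, small_bundle.neuron_ids, canonical,
                             (-500, 1500))
        jumps = np.abs(np.diff(out.values, axis=1)).max()
        # smoothed rates on a 10 ms grid: adjacent-bin jumps stay small
        assert jumps < 20.0

    def test_do_locked_bump_recovered(self):
        # planted bump locked to DO with jittered RT/MT: multi-align puts the
        # peak at canonical DO; Go-only alignment smears it
        rng = np.random.default_rng(5)
        trials = []
        for i in range(40):
            rt = float(rng.uniform(200, 500))
            mt = float(rng.uniform(200, 500))
            ev = self._events(2000.0, rt, mt)
            do = ev["DO"]
            n_sp = 60
            spikes = np.sort(rng.normal(do, 40.0, n_sp))
            spikes = spikes[(spikes > 0) & (spikes < 5800)]
            trials.append(TrialRecord(i, "execution", "PG", ev,
                                      {"n0": spikes}, "correct", 0.0, 6000.0))
        canonical = {"GoNogo": 0.0, "HPR": 350.0, "DO": 700.0}
        multi = pp.multi_align(trials, ["n0"], canonical, (-500, 1500))
        single = pp.psth_single(trials, ["n0"], "GoNogo", (-500, 1500))
        peak_multi = multi.time_axis[np.argmax(multi.values[0])]
        assert abs(peak_multi - 700.0) <= 20.0  # canonical DO +/- 2 bins
        # multi-aligned peak is sharper than the Go-aligned one
        assert multi.values.max() > 1.3 * single.values.max()

    def test_missing_event_trial_skipped(self, caplog):
        ev_full = self._events(2000.0, 300.0, 300.0)
        ev_nogo = {k: ev_full[k] for k in ("LCDon", "ObjCue", "GoNogo")}
        trials = [
            _const_rate_trial(0, 30.0, ev_full, 0.0, 6000.0),
            TrialRecord(1, "nogo", "PG", ev_nogo, {"n0": np.array([100.0])},
                        "correct", 0.0, 3000.0),
        ]
        canonical = {"GoNogo": 0.0, "HPR": 300.0, "DO": 600.0}
        import logging

        with caplog.at_level(logging.WARNING, logger="mirrorpop.preprocess"):
            out = pp.multi_align(trials, ["n0"], canonical, (-500, 1500))
        assert "skipping" in caplog.text
        assert np.all(np.abs(out.values - 30.0) < 1.0)


class TestBaselineAndNormalize:
    def _tensor(self, values, **kw):
        values = np.asarray(values, dtype=float)
        return RateTensor(values=values,
                          time_axis=np.arange(values.shape[-1]) * 10.0,
                          bin_width=10.0, alignment="single:GoNogo", **kw)

    def test_baseline_zeroes_constant(self):
        t = self._tensor(np.full((3, 10), 4.0))
        out = pp.baseline_correct({"a": t}, np.full(3, 4.0))
        assert np.all(out["a"].values == 0.0)

    def test_shift_invariance(self, rng):
        vals = rng.normal(size=(4, 20))
        base = rng.normal(size=4)
        t1 = {"a": self._tensor(vals)}
        t2 = {"a": self._tensor(vals + 2.5)}
        out1 = pp.baseline_correct(t1, base)
        out2 = pp.baseline_correct(t2, base + 2.5)
        np.testing.assert_allclose(out1["a"].values, out2["a"].values)

    def test_planted_baseline_recovered(self):
        cfg = sd.GroundTruthConfig(n_neurons=10, trials_per_condition=60,
                                   emg=False, conditions=("execution",),
                                   grasps=("PG",), latent_scale=20.0)
        bundle, rec = sd.generate_session(cfg, seed=9)
        est = pp.baseline_rates(bundle)
        n_tr = len(bundle.trials)
        se = np.sqrt(rec.baselines / (n_tr * 0.25))
        assert np.all(np.abs(est - rec.baselines) < 4 * se + 1e-9)

    def test_range_soft_formula(self):
        # neuron range 45, peak 45 -> 45/50 = 0.9
        vals = np.zeros((1, 10))
        vals[0, 3] = 45.0
        out = pp.soft_normalize({"a": self._tensor(vals)},
                                NormalizationSpec(mode="range_soft", constant=5))
        assert out["a"].values.max() == pytest.approx(0.9)

    def test_silent_neuron_stays_zero(self):
        out = pp.soft_normalize({"a": self._tensor(np.zeros((2, 8)))})
        assert np.all(out["a"].values == 0.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_strictly_inside_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 50, size=(3, 30))
        for mode in ("range_soft", "absmax_soft"):
            out = pp.soft_normalize(
                {"a": self._tensor(vals)}, NormalizationSpec(mode=mode))
            assert np.abs(out["a"].values).max() < 1.0

    def test_absmax_mode(self):
        vals = np.array([[-20.0, 10.0, 0.0]])
        out = pp.soft_normalize({"a": self._tensor(vals)},
                                NormalizationSpec(mode="absmax_soft", constant=5))
        np.testing.assert_allclose(out["a"].values,
                                   vals / 25.0)

    def test_range_across_conditions_shared(self):
        a = self._tensor(np.array([[0.0, 45.0]]))
        b = self._tensor(np.array([[0.0, -45.0]]))
        out = pp.soft_normalize({"a": a, "b": b})
        # range across both conditions = 90 -> denominator 95
        assert out["a"].values.max() == pytest.approx(45.0 / 95.0)

    def test_bad_constant(self):
        with pytest.raises(ValueError):
            NormalizationSpec(constant=0.0)


class TestEpochAverage:
    def test_constant_rate_all_epochs(self):
        ev = {"LCDon": 1000.0, "ObjCue": 1250.0, "GoNogo": 2050.0,
              "HPR": 2350.0, "DO": 2650.0, "HO": 2750.0, "HOFF": 3750.0,
              "HPN": 4150.0}
        # 200 Hz regular train: every epoch boundary is a multiple of the
        # 5 ms inter-spike interval, so epoch means are exactly 200
        trials = [_const_rate_trial(i, 200.0, ev, 0.0, 5000.0) for i in range(3)]
        from mirrorpop.dataio import NeuronMeta, SessionBundle

        b = SessionBundle("s", [NeuronMeta("n0", "M1", "PTN")], trials)
        df = pp.epoch_average(b, ANOVA_EPOCHS)
        assert set(df["epoch"]) == {"Baseline", "Reach", "GraspHold"}
        np.testing.assert_allclose(df["rate"], 200.0)

    def test_reach_halves_average_to_full(self):
        ev = {"LCDon": 1000.0, "ObjCue": 1250.0, "GoNogo": 2050.0,
              "HPR": 2350.0, "DO": 2750.0, "HO": 2850.0}
        tr = _const_rate_trial(0, 20.0, ev, 0.0, 5000.0)
        from mirrorpop.dataio import NeuronMeta, SessionBundle

        b = SessionBundle("s", [NeuronMeta("n0", "M1", "PTN")], [tr])
        df = pp.epoch_average(b, CORRELATION_EPOCHS)
        by = df.set_index("epoch")["rate"]
        full = 0.5 * (by["EarlyReach"] + by["LateReach"])
        # piecewise-constant rate: halves average to the full-reach mean
        assert full == pytest.approx(20.0, rel=0.05)

    def test_nogo_epochs_unresolvable_omitted(self, small_bundle):
        df = pp.epoch_average(small_bundle, ANOVA_EPOCHS)
        nogo = df[df["condition"] == "nogo"]
        assert set(nogo["epoch"]) == {"Baseline"}

    def test_planted_reach_bump_elevates_reach_epoch(self):
        cfg = sd.GroundTruthConfig(n_neurons=12, trials_per_condition=40,
                                   emg=False, conditions=("execution",),
                                   grasps=("PG",), latent_scale=50.0)
        bundle, rec = sd.generate_session(cfg, seed=21)
        df = pp.epoch_average(bundle, ANOVA_EPOCHS)
        piv = df.pivot_table(index="neuron_id", columns="epoch", values="rate")
        dev = (piv["Reach"] - piv["Baseline"]).abs().mean()
        base_noise = piv["Baseline"].std()
        assert dev > 1.0  # planted task modulation visible on average


class TestBehaviour:
    def test_simple_subtraction(self):
        ev = {"LCDon": 0.0, "ObjCue": 250.0, "GoNogo": 1000.0, "HPR": 1310.0,
              "DO": 1616.0, "HO": 1716.0}
        tr = TrialRecord(0, "execution", "PG", ev, {}, "correct", 0.0, 3000.0)
        from mirrorpop.dataio import SessionBundle

        b = SessionBundle("s", [], [tr])
        table = pp.compute_behaviour(b)
        assert table.loc[0, "RT"] == pytest.approx(310.0)
        assert table.loc[0, "MT"] == pytest.approx(306.0)

    def test_nogo_excluded(self, small_bundle):
        table = pp.compute_behaviour(small_bundle)
        assert "nogo" not in set(table["condition"])

    def test_median_rt_recovery(self):
        cfg = sd.GroundTruthConfig(n_neurons=9, trials_per_condition=500,
                                   emg=False, conditions=("execution",),
                                   grasps=("PG", "WHG"))
        bundle, _ = sd.generate_session(cfg, seed=2)
        table = pp.compute_behaviour(bundle)
        med = pp.behaviour_medians(table)
        sem = 25.0 / np.sqrt(500)
        for _, row in med.iterrows():
            assert abs(row["RT"] - 310.0) < 3 * sem + 2.0

    def test_negative_interval_raises(self):
        ev = {"LCDon": 0.0, "ObjCue": 250.0, "GoNogo": 1000.0, "HPR": 1310.0,
              "DO": 1616.0}
        tr = TrialRecord(0, "execution", "PG", ev, {}, "correct", 0.0, 3000.0)
        tr.events["HPR"] = 1700.0  # DO before HPR
        from mirrorpop.dataio import SessionBundle

        b = SessionBundle("s", [], [tr])
        with pytest.raises(ValueError, match="trial 0"):
            pp.compute_behaviour(b)


class TestRateTensor:
    def test_window_slicing(self):
        t = RateTensor(np.arange(20, dtype=float).reshape(1, 20),
                       np.arange(20) * 10.0, 10.0, "single:GoNogo")
        w = t.window(50.0, 100.0)
        assert w.values.shape == (1, 5)
        assert w.time_axis[0] == 50.0

    def test_window_outside_raises(self):
        t = RateTensor(np.zeros((1, 5)), np.arange(5) * 10.0, 10.0, "x")
        with pytest.raises(ValueError):
            t.window(1000.0, 2000.0)

    def test_value_at(self):
        t = RateTensor(np.arange(10, dtype=float).reshape(1, 10),
                       np.arange(10) * 10.0, 10.0, "x")
        assert t.value_at(35.0)[0] == 3.0
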