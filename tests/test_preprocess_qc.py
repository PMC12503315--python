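import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergscreen.preprocess_qc import (
    apply_overrides,
    average_trials,
    baseline_correct,
    baseline_correct_cohort,
    extreme_value_qc,
    mad_qc,
    sample_size_gate,
    trial_mad_score,
    QCFlag,
)
from ergscreen.waveform_io import Cohort

from conftest import full_grid_traces, make_session, make_trace


class TestBaselineCorrect:
    def test_constant_offset(self):
        tr = make_trace("m1", samples=None)
        tr.samples = tr.samples + 12.0
        out = baseline_correct(tr)
        np.testing.assert_allclose(out.samples, tr.samples - 12.0)

    def test_identity_when_zero(self):
        tr = make_trace("m1")
        out = baseline_correct(tr)
        np.testing.assert_array_equal(out.samples, tr.samples)

    def test_ramp_mean_oracle(self):
        tr = make_trace("m1")
        ramp = np.arange(1, 41, dtype=float)  # pre-stimulus 40-point ramp
        tr.samples[:40] = ramp
        m = ramp.sum() / 40.0  # independent arithmetic mean
        out = baseline_correct(tr)
        np.testing.assert_allclose(out.samples, tr.samples - m)
        n_base = 40
        assert abs(out.samples[:n_base].mean()) < 1e-9

    def test_photopic_uses_20_points(self):
        tr = make_trace("m1", condition="photopic")
        tr.samples[:20] = 5.0
        out = baseline_correct(tr)
        assert abs(out.samples[:20].mean()) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        tr = make_trace("m1")
        tr.samples = rng.normal(3.0, 2.0, len(tr.samples))
        once = baseline_correct(tr)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-12)

    def test_insufficient_prestim(self):
        tr = make_trace("m1")
        tr.t0_offset_s = 0.005  # only 10 pre-stimulus samples
        with pytest.raises(ValueError, match="pre-stimulus"):
            baseline_correct(tr)


class TestTrialMadScore:
    def test_identical_trials_zero(self):
        trials = [make_trace("m1", trial=i) for i in range(1, 4)]
        assert trial_mad_score(trials) == 0.0

    def test_constant_difference_hand_oracle(self):
        # two trials 1 uV apart at every point: deviations +/-0.5 -> N*0.5
        t1 = make_trace("m1", trial=1)
        t2 = make_trace("m1", trial=2)
        t2.samples = t2.samples + 1.0
        n = len(t1.samples)
        assert trial_mad_score([t1, t2]) == pytest.approx(n * 0.5)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        trials = []
        for i in range(3):
            tr = make_trace("m1", trial=i + 1)
            tr.samples = rng.normal(0, 5, len(tr.samples))
            trials.append(tr)
        # independent loop implementation
        expected = 0.0
        n = len(trials[0].samples)
        for j in range(n):
            vals = [t.samples[j] for t in trials]
            mean = sum(vals) / 3
            expected += sum(abs(v - mean) for v in vals) / 3
        assert trial_mad_score(trials) == pytest.approx(expected, rel=1e-12)

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        trials = []
        for i in range(3):
            tr = make_trace("m1", trial=i + 1)
            tr.samples = rng.normal(0, 5, len(tr.samples))
            trials.append(tr)
        assert trial_mad_score(trials) == pytest.approx(
            trial_mad_score(trials[::-1])
        )

    def test_common_constant_invariant(self):
        rng = np.random.default_rng(3)
        trials = []
        for i in range(2):
            tr = make_trace("m1", trial=i + 1)
            tr.samples = rng.normal(0, 5, len(tr.samples))
            trials.append(tr)
        shifted = []
        for t in trials:
            s = make_trace("m1", trial=t.trial)
            s.samples = t.samples + 7.7
            shifted.append(s)
        assert trial_mad_score(trials) == pytest.approx(
            trial_mad_score(shifted), rel=1e-12
        )

    def test_errors(self):
        t1 = make_trace("m1", trial=1)
        with pytest.raises(ValueError, match="2 trials"):
            trial_mad_score([t1])
        t2 = make_trace("m1", trial=2)
        t2.samples = t2.samples[:-5]
        with pytest.raises(ValueError, match="unequal"):
            trial_mad_score([t1, t2])


class TestMadQC:
    def test_all_identical_zero_flags(self):
        sessions = [make_session(f"m{i}") for i in range(5)]
        traces = [t for s in sessions for t in full_grid_traces(s.mouse_id)]
        flags, scores = mad_qc(Cohort(sessions=sessions, traces=traces))
        assert flags == []
        assert (scores["score"] == 0).all()

    def test_planted_artifact_recovered(self):
        rng = np.random.default_rng(10)
        sessions = [make_session(f"m{i:02d}") for i in range(25)]
        traces = []
        for s in sessions:
            traces.extend(full_grid_traces(s.mouse_id, rng))
        # corrupt one scotopic trial of m07 with high-variance noise
        for t in traces:
            if t.key == ("m07", "L", "scotopic", 2):
                t.samples = t.samples + rng.normal(0, 100, len(t.samples))
        cohort = baseline_correct_cohort(Cohort(sessions=sessions, traces=traces))
        flags, scores = mad_qc(cohort)
        scot = [f for f in flags if f.condition == "scotopic"]
        assert [f.mouse_id for f in scot] == ["m07"]


class TestAverageTrials:
    def test_single_trial_identity(self):
        tr = make_trace("m1")
        tr.samples = np.arange(len(tr.samples), dtype=float)
        out = average_trials([tr])
        np.testing.assert_array_equal(out.samples, tr.samples)
        assert out.trial_count == 1

    def test_symmetry_cancels(self):
        t1 = make_trace("m1", trial=1)
        t2 = make_trace("m1", trial=2)
        rng = np.random.default_rng(4)
        v = rng.normal(0, 10, len(t1.samples))
        t1.samples = v
        t2.samples = -v
        out = average_trials([t1, t2])
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_pointwise_mean_spot_checks(self):
        rng = np.random.default_rng(5)
        trials = []
        for i in range(3):
            tr = make_trace("m1", trial=i + 1)
            tr.samples = rng.normal(0, 5, len(tr.samples))
            trials.append(tr)
        out = average_trials(trials)
        for j in [0, 100, 999, 5000, len(out.samples) - 1]:
            expected = (
                trials[0].samples[j] + trials[1].samples[j] + trials[2].samples[j]
            ) / 3.0
            assert out.samples[j] == pytest.approx(expected, rel=1e-12)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            average_trials([])


def _amp_frame(rows):
    return pd.DataFrame(
        rows, columns=["mouse_id", "eye", "condition", "parameter", "amplitude_uV"]
    )


def _session_frame(mice):
    return pd.DataFrame(
        [
            {"mouse_id": m, "strain_id": s, "zygosity": "x", "sex": "M",
             "test_date": "2020-01-01", "batch_id": "b"}
            for m, s in mice
        ]
    )


class TestExtremeValueQC:
    def test_degenerate_sd_flags_any_difference(self):
        rows = [(f"w{i}", "L", "scotopic", "a", 100.0) for i in range(5)]
        rows.append(("mut", "L", "scotopic", "a", 100.5))
        sessions = _session_frame(
            [(f"w{i}", "wildtype") for i in range(5)] + [("mut", "sX")]
        )
        flags, limits = extreme_value_qc(_amp_frame(rows), sessions)
        assert [f.mouse_id for f in flags] == ["mut"]
        assert limits.iloc[0]["sd"] == 0.0

    def test_boundary_value_passes(self):
        wt_vals = [90.0, 95.0, 100.0, 105.0, 110.0]
        mean = np.mean(wt_vals)
        sd = np.std(wt_vals, ddof=1)
        rows = [(f"w{i}", "L", "scotopic", "a", v) for i, v in enumerate(wt_vals)]
        rows.append(("mut", "L", "scotopic", "a", mean + 3 * sd))  # exactly on limit
        sessions = _session_frame(
            [(f"w{i}", "wildtype") for i in range(5)] + [("mut", "sX")]
        )
        flags, _ = extreme_value_qc(_amp_frame(rows), sessions)
        assert flags == []

    def test_planted_outliers_recovered(self):
        rng = np.random.default_rng(11)
        wt = rng.normal(100, 10, 200)
        rows = [(f"w{i}", "L", "scotopic", "a", v) for i, v in enumerate(wt)]
        mean, sd = wt.mean(), wt.std(ddof=1)
        planted = []
        for i in range(5):
            mid = f"out{i}"
            sign = 1 if i % 2 else -1
            rows.append((mid, "L", "scotopic", "a", mean + sign * 6 * sd))
            planted.append(mid)
        # normal mutants inside the limits
        for i in range(20):
            rows.append((f"mut{i}", "L", "scotopic", "a", rng.normal(100, 10)))
        sessions = _session_frame(
            [(f"w{i}", "wildtype") for i in range(200)]
            + [(m, "sX") for m in planted]
            + [(f"mut{i}", "sX") for i in range(20)]
        )
        flags, _ = extreme_value_qc(_amp_frame(rows), sessions)
        assert sorted(f.mouse_id for f in flags) == sorted(planted)

    def test_limits_independent_of_mutants(self):
        rng = np.random.default_rng(12)
        wt_rows = [
            (f"w{i}", "L", "scotopic", "a", rng.normal(100, 10)) for i in range(50)
        ]
        mut_a = [("m1", "L", "scotopic", "a", 500.0)]
        mut_b = [("m1", "L", "scotopic", "a", -500.0), ("m2", "L", "scotopic", "a", 7.0)]
        s_a = _session_frame(
            [(f"w{i}", "wildtype") for i in range(50)] + [("m1", "sX")]
        )
        s_b = _session_frame(
            [(f"w{i}", "wildtype") for i in range(50)]
            + [("m1", "sX"), ("m2", "sX")]
        )
        _, lim_a = extreme_value_qc(_amp_frame(wt_rows + mut_a), s_a)
        _, lim_b = extreme_value_qc(_amp_frame(wt_rows + mut_b), s_b)
        pd.testing.assert_frame_equal(lim_a, lim_b)

    def test_too_few_wildtype(self):
        rows = [("w0", "L", "scotopic", "a", 100.0), ("m", "L", "scotopic", "a", 1.0)]
        sessions = _session_frame([("w0", "wildtype"), ("m", "sX")])
        with pytest.raises(ValueError, match="wildtype"):
            extreme_value_qc(_amp_frame(rows), sessions)


class TestSampleSizeGate:
    def _setup(self, n_scot, n_phot):
        mice = [(f"m{i}", "sX") for i in range(max(n_scot, n_phot))]
        rows = []
        for i, (m, _) in enumerate(mice):
            if i < n_scot:
                rows.append((m, "L", "scotopic", "a", 100.0))
            if i < n_phot:
                rows.append((m, "L", "photopic", "a", 20.0))
        return _session_frame(mice), _amp_frame(rows)

    def test_six_scotopic_four_photopic(self):
        sessions, amps = self._setup(6, 4)
        gate = sample_size_gate(sessions, amps, [])
        by = gate.set_index("condition")
        assert bool(by.loc["scotopic", "eligible"]) is True
        assert bool(by.loc["photopic", "eligible"]) is False

    def test_exactly_five_eligible(self):
        sessions, amps = self._setup(5, 5)
        gate = sample_size_gate(sessions, amps, [])
        assert gate["eligible"].all()

    def test_zero_passing(self):
        sessions, amps = self._setup(5, 5)
        flags = [QCFlag(f"m{i}", c, "mad", "x")
                 for i in range(5) for c in ("scotopic", "photopic")]
        gate = sample_size_gate(sessions, amps, flags)
        assert not gate["eligible"].any()
        assert (gate["n_pass"] == 0).all()


class TestOverrides:
    def test_keep_and_drop(self):
        flags = [QCFlag("m1", "scotopic", "mad", "x")]
        overrides = pd.DataFrame(
            [{"mouse_id": "m1", "decision": "keep", "reason": "reviewed"},
             {"mouse_id": "m2", "decision": "drop", "reason": "bad electrode"}]
        )
        out = apply_overrides(flags, overrides)
        assert all(f.mouse_id != "m1" for f in out)
        assert {f.mouse_id for f in out} == {"m2"}
        assert all(f.stage == "metadata" for f in out)


class TestQCChainProperties:
    @given(offset=st.floats(-1000, 1000, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_baseline_absorbs_any_constant(self, offset):
        tr = make_trace("m1")
        rng = np.random.default_rng(6)
        base = rng.normal(0, 5, len(tr.samples))
        tr.samples = base + offset
        out = baseline_correct(tr)
        ref = make_trace("m1")
        ref.samples = base
        np.testing.assert_allclose(
            out.samples, baseline_correct(ref).samples, atol=1e-9
        )

    def test_chain_never_alters_retained_values(self, tiny_clean):
        cohort, _ = tiny_clean
        corrected = baseline_correct_cohort(cohort)
        before = {t.key: t.samples.copy() for t in corrected.traces}
        mad_qc(corrected)
        for t in corrected.traces:
            np.testing.assert_array_equal(t.samples, before[t.key])
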