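"""Staircase rules, exact binomial thresholds, session simulation."""

import numpy as np
import pytest

from pacinia.psychophysics import (
    PerceptualThreshold,
    SessionLog,
    StaircaseConfig,
    TrialRecord,
    binomial_threshold,
    run_session,
    sensitivity_curve,
    staircase_update,
)
from pacinia.synthetic import ObserverModel

CFG = StaircaseConfig(start_amplitude_um=10.0)


class TestStaircaseUpdate:
    def test_good_block_attenuates_four_db(self):
        nxt = staircase_update([True] * 11 + [False], 1.0, CFG)
        assert nxt == pytest.approx(10 ** (-4 / 20))

    def test_poor_block_amplifies_four_db(self):
        nxt = staircase_update([True] * 6 + [False] * 6, 1.0, CFG)
        assert nxt == pytest.approx(10 ** (4 / 20))

    def test_intermediate_block_holds(self):
        nxt = staircase_update([True] * 8 + [False] * 4, 1.0, CFG)  # 66.7%
        assert nxt == 1.0

    def test_amplification_capped_at_start(self):
        nxt = staircase_update([False] * 12, 9.0, CFG)
        assert nxt == CFG.start_amplitude_um

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            staircase_update([], 1.0, CFG)


def _log(records):
    log = SessionLog(frequency_hz=700.0, config=CFG, seed=0)
    log.trials = records
    return log


def _vib(i, step, correct, amp=None):
    amp = CFG.start_amplitude_um / CFG.step_factor**step if amp is None else amp
    return TrialRecord(i, "vibration", amp, step, correct)


class TestBinomialThreshold:
    def test_exact_tail_probabilities(self):
        # 11/12 correct: p = 13/4096; 8/12: p = 794/4096; 6/6: p = 1/64
        log = _log([_vib(i, 0, i < 11) for i in range(12)])
        thr = binomial_threshold(log)
        assert thr.per_amplitude[0].p_value == pytest.approx(13 / 4096)
        log = _log([_vib(i, 0, i < 8) for i in range(12)])
        thr = binomial_threshold(log)
        assert thr.per_amplitude[0].p_value == pytest.approx(794 / 4096)
        assert not thr.defined
        log = _log([_vib(i, 0, True) for i in range(6)])
        thr = binomial_threshold(log)
        assert thr.per_amplitude[0].p_value == pytest.approx(1 / 64)
        assert thr.defined

    def test_threshold_is_lowest_significant_amplitude(self):
        records = [_vib(i, 0, True) for i in range(6)]
        records += [_vib(6 + i, 2, True) for i in range(6)]        # lower, significant
        records += [_vib(12 + i, 3, i % 2 == 0) for i in range(6)]  # lowest, chance
        log = _log(records)
        thr = binomial_threshold(log)
        assert thr.defined
        assert thr.threshold_um == pytest.approx(10.0 / CFG.step_factor**2)

    def test_catch_trials_excluded_by_default(self):
        records = [_vib(i, 0, True) for i in range(6)]
        records += [
            TrialRecord(6 + i, "catch", CFG.start_amplitude_um, 0, True) for i in range(6)
        ]
        pooled = binomial_threshold(log := _log(records), include_catch=True)
        vib_only = binomial_threshold(log)
        assert vib_only.per_amplitude[0].n_trials == 6
        assert pooled.per_amplitude[0].n_trials == 12

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            binomial_threshold(_log([]))


class TestRunSession:
    def test_reproducible_under_seed(self):
        obs = ObserverModel(threshold_db=-10.0)
        a = run_session(obs, CFG, 700.0, 120, seed=3)
        b = run_session(obs, CFG, 700.0, 120, seed=3)
        assert a.trials == b.trials

    def test_no_more_than_three_consecutive_same_type(self):
        obs = ObserverModel(threshold_db=-10.0)
        log = run_session(obs, CFG, 700.0, 400, seed=1)
        run, prev = 1, None
        for t in log.trials:
            run = run + 1 if t.trial_type == prev else 1
            prev = t.trial_type
            assert run <= 3

    def test_amplitude_descends_for_sensitive_observer(self):
        obs = ObserverModel(threshold_db=-40.0, lapse_rate=0.0, catch_accuracy=1.0)
        log = run_session(obs, CFG, 700.0, 60, seed=2)
        steps = [t.amplitude_step for t in log.trials]
        assert sorted(steps) == steps  # monotone attenuation
        assert steps[-1] > 0

    def test_amplitudes_bounded_by_start_and_floor(self):
        obs = ObserverModel(threshold_db=30.0, lapse_rate=0.1, catch_accuracy=0.5)
        log = run_session(obs, CFG, 700.0, 300, seed=4)
        amps = [t.amplitude_um for t in log.trials]
        assert max(amps) <= CFG.start_amplitude_um + 1e-12
        assert min(amps) >= CFG.floor_amplitude_um - 1e-12

    def test_easy_fixed_amplitude_near_perfect(self):
        obs = ObserverModel(threshold_db=-40.0, lapse_rate=0.0, catch_accuracy=1.0)
        log = run_session(obs, CFG, 700.0, 100, seed=5)
        vib = [t for t in log.trials if t.trial_type == "vibration"]
        assert all(t.correct for t in vib)

    def test_perfect_observer_threshold_is_lowest_testable_amplitude(self):
        # the smallest n with one-sided p < 0.05 at chance 0.5 is 5 trials
        obs = ObserverModel(threshold_db=-80.0, lapse_rate=0.0, catch_accuracy=1.0)
        log = run_session(obs, CFG, 700.0, 200, seed=6)
        thr = binomial_threshold(log)
        counts = {}
        for t in log.trials:
            if t.trial_type == "vibration":
                counts[t.amplitude_um] = counts.get(t.amplitude_um, 0) + 1
        lowest_testable = min(a for a, n in counts.items() if n >= 5)
        assert thr.defined and thr.threshold_um == pytest.approx(lowest_testable)

    def test_session_shorter_than_block_rejected(self):
        obs = ObserverModel(threshold_db=-10.0)
        with pytest.raises(ValueError):
            run_session(obs, CFG, 700.0, 3, seed=0)


class TestSensitivityCurve:
    def _thr(self, f, um):
        return PerceptualThreshold(f, um, um is not None, [])

    def test_single_session_identity(self):
        curve = sensitivity_curve([self._thr(300.0, 2.0)], frequency_set_hz=(300.0,))
        assert curve == {300.0: 2.0}

    def test_mean_of_repeated_sessions(self):
        curve = sensitivity_curve(
            [self._thr(300.0, 2.0), self._thr(300.0, 4.0)], frequency_set_hz=(300.0,)
        )
        assert curve[300.0] == pytest.approx(3.0)

    def test_missing_frequency_flagged_none(self):
        curve = sensitivity_curve(
            [self._thr(300.0, 2.0)], frequency_set_hz=(300.0, 700.0)
        )
        assert curve[700.0] is None

    def test_v_shape_recovered_from_u_shaped_observer(self):
        # per-frequency observers with a U-shaped dB threshold profile
        freqs = (300.0, 700.0, 2000.0)
        db = {300.0: -2.0, 700.0: -14.0, 2000.0: -6.0}
        thresholds = []
        for f in freqs:
            obs = ObserverModel(threshold_db=db[f], slope_db=2.0)
            for s in range(3):
                log = run_session(obs, CFG, f, 200, seed=100 + s)
                thresholds.append(binomial_threshold(log))
        curve = sensitivity_curve(thresholds, freqs)
        assert curve[700.0] < curve[300.0] and curve[700.0] < curve[2000.0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_curve([])
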