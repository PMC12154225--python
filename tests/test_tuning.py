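"""Unit gating, responsiveness, tuning fits and threshold extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pacinia.datatypes import SpikeTrain, VibrationEpoch
from pacinia.synthetic import make_ramp_evoked_spikes
from pacinia.tuning import (
    TrialResponseSet,
    first_spike_threshold,
    fit_tuning,
    is_responsive,
    sustained_rate_threshold,
    tuning_index,
    waveform_snr,
)


class TestWaveformSnr:
    @pytest.mark.parametrize("peak,sd,expect_snr,expect_pass", [
        (50.0, 5.0, 10.0, True),
        (10.0, 5.0, 2.0, False),
        (25.0, 5.0, 5.0, False),  # the gate is strict
    ])
    def test_gate(self, peak, sd, expect_snr, expect_pass):
        snr, ok = waveform_snr([0.0, peak, -peak / 2], sd)
        assert snr == pytest.approx(expect_snr)
        assert ok is expect_pass

    def test_zero_noise_rejected(self):
        with pytest.raises(ValueError):
            waveform_snr([1.0, 2.0], 0.0)


def _trials(best_rates, baseline_mean=10.0, baseline_sd=2.0):
    return TrialResponseSet(
        stimuli=[(100.0, 1.0), (400.0, 1.0)],
        trial_rates=[np.full(10, baseline_mean), np.asarray(best_rates, float)],
        baseline_mean_hz=baseline_mean,
        baseline_sd_hz=baseline_sd,
    )


class TestResponsiveness:
    def test_baseline_level_responses_are_not_responsive(self):
        assert not is_responsive(_trials(np.full(10, 10.0)))

    def test_all_three_criteria_met(self):
        assert is_responsive(_trials(np.full(10, 20.0)))  # >5%, >2SD, all trials

    def test_trial_fraction_is_inclusive_at_twenty_percent(self):
        # 19 of 100 single trials above baseline + 2 SD -> fail; 20 -> pass
        # (mean responses beat both the 5% and 2-SD criteria in either case)
        below, above = 10.0, 40.0
        rates_19 = np.r_[np.full(81, below), np.full(19, above)]
        rates_20 = np.r_[np.full(80, below), np.full(20, above)]
        t19 = _trials(rates_19)
        t20 = _trials(rates_20)
        assert not is_responsive(t19)
        assert is_responsive(t20)

    def test_mean_must_beat_two_sd(self):
        # mean above 5% margin but below baseline + 2 SD
        assert not is_responsive(_trials(np.full(10, 13.0), baseline_sd=2.0))


class TestFitTuning:
    def test_exact_recovery_of_degree6_polynomial(self):
        f = np.linspace(100.0, 900.0, 9)
        coef = np.array([0.2, 1e-3, -2e-6, 3e-9, -1e-12, 2e-16, -1e-20])
        y = np.polynomial.polynomial.polyval(f, coef)
        y = y - y.min() + 0.1  # keep positive
        curve = fit_tuning(f, y)
        assert curve.fit_r == pytest.approx(1.0, abs=1e-9)
        fitted = np.polynomial.polynomial.polyval(f, curve.coefficients)
        assert np.allclose(fitted, y / y.max(), atol=1e-9)

    def test_symmetric_tent_peaks_at_centre(self):
        f = np.linspace(100.0, 700.0, 13)
        y = 1.0 - np.abs(f - 400.0) / 400.0
        curve = fit_tuning(f, y)
        assert curve.preferred_frequency_hz == pytest.approx(400.0, abs=1.0)

    def test_gaussian_tuning_recovers_centre(self):
        f = np.arange(100.0, 701.0, 25.0)
        y = np.exp(-0.5 * ((f - 400.0) / 150.0) ** 2)
        curve = fit_tuning(f, y)
        assert curve.preferred_frequency_hz == pytest.approx(400.0, abs=1.0)
        assert curve.width_defined and curve.half_width_hz > 0

    def test_preferred_frequency_scale_invariant(self):
        f = np.arange(100.0, 701.0, 25.0)
        y = np.exp(-0.5 * ((f - 300.0) / 120.0) ** 2)
        c1 = fit_tuning(f, y)
        c2 = fit_tuning(f, 7.3 * y)
        assert c1.preferred_frequency_hz == c2.preferred_frequency_hz

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError):
            fit_tuning(np.arange(7), np.arange(7.0) + 1)


class TestTuningIndex:
    @pytest.mark.parametrize("pref,ortho,expected", [
        (10.0, 2.0, 2 / 3),
        (5.0, 5.0, 0.0),
        (4.0, 0.0, 1.0),
    ])
    def test_examples(self, pref, ortho, expected):
        assert tuning_index(pref, ortho) == pytest.approx(expected)

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, pref, frac, k):
        ortho = pref * frac
        assert tuning_index(k * pref, k * ortho) == pytest.approx(
            tuning_index(pref, ortho), rel=1e-9
        )

    def test_undefined_for_two_zero_responses(self):
        with pytest.raises(ValueError):
            tuning_index(0.0, 0.0)


class TestFirstSpikeThreshold:
    def test_linear_mapping_of_first_spike(self):
        epoch = VibrationEpoch(0.0, 20.0, 400.0, "ramp", 20.0)
        train = SpikeTrain(np.array([5.0, 6.0, 7.0]))
        res = first_spike_threshold(train, epoch)
        assert res.defined and res.amplitude_um == pytest.approx(5.0)

    def test_silent_unit_is_undefined(self):
        epoch = VibrationEpoch(0.0, 20.0, 400.0, "ramp", 20.0)
        res = first_spike_threshold(SpikeTrain(np.empty(0)), epoch)
        assert not res.defined and res.amplitude_um is None

    def test_constant_epoch_rejected(self):
        epoch = VibrationEpoch(0.0, 20.0, 400.0, "constant", 20.0)
        with pytest.raises(ValueError):
            first_spike_threshold(SpikeTrain(np.array([1.0])), epoch)

    def test_recovers_generator_threshold_within_one_ramp_step(self):
        rng = np.random.default_rng(21)
        step = 20.0 / (20.0 * 400.0)  # amplitude per stimulus cycle
        for _ in range(20):
            thr = rng.uniform(1.0, 15.0)
            train, epoch = make_ramp_evoked_spikes(thr, 20.0, 20.0, 400.0)
            rec = first_spike_threshold(train, epoch)
            assert 0 <= rec.amplitude_um - thr <= step + 1e-12

    def test_monotone_in_generator_threshold(self):
        recs = []
        for thr in (2.0, 5.0, 9.0, 14.0):
            train, epoch = make_ramp_evoked_spikes(thr, 20.0, 20.0, 400.0)
            recs.append(first_spike_threshold(train, epoch).amplitude_um)
        assert all(a < b for a, b in zip(recs, recs[1:]))


class TestSustainedRateThreshold:
    def test_external_maximum_rate(self):
        res = sustained_rate_threshold([1, 2, 3, 4], [5, 15, 25, 60], max_rate_hz=100.0)
        assert res.defined and res.amplitude_um == 3.0

    def test_monotone_response_crossing(self):
        res = sustained_rate_threshold([1, 2, 3], [5.0, 21.0, 80.0])
        assert res.amplitude_um == 2.0  # 20% of max (80) is 16

    def test_maximum_always_qualifies(self):
        res = sustained_rate_threshold([1, 2, 3], [1.0, 2.0, 50.0])
        assert res.amplitude_um == 3.0

    def test_all_silent_is_undefined(self):
        res = sustained_rate_threshold([1, 2], [0.0, 0.0])
        assert not res.defined

    def test_single_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sustained_rate_threshold([1], [10.0])
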