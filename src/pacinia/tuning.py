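"""Unit gating, responsiveness, frequency tuning and mechanical thresholds.

These are the single-unit statistics used to characterize vibration-driven
afferents: a waveform signal-to-noise gate for accepting single units, a
three-part responsiveness criterion against baseline firing, a degree-6
polynomial fit of the normalized frequency tuning curve (with preferred
frequency, half width at half maximum and a tuning index), and two
mechanical threshold definitions — the ramp amplitude at the first evoked
spike, and the smallest amplitude driving 20% of the unit's maximum
sustained rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.stats import pearsonr

from .datatypes import SpikeTrain, VibrationEpoch

#: single-unit acceptance gate on waveform signal-to-noise ratio (strict)
SNR_GATE = 5.0

#: frequency-selectivity gates on fit quality and tuning index
FIT_R_GATE = 0.7
TI_GATE = 0.2

#: default sustained-response window after stimulus onset (seconds)
SUSTAINED_WINDOW_S = (0.050, 0.250)


# ---------------------------------------------------------------------------
# unit gating and responsiveness
# ---------------------------------------------------------------------------

def waveform_snr(mean_waveform_uv, noise_sd_uv: float) -> tuple[float, bool]:
    """SNR = max |mean spike waveform| / background-noise SD; pass iff SNR > 5.

    The inequality is strict: a unit at exactly the gate is rejected.
    """
    if noise_sd_uv <= 0:
        raise ValueError("noise SD must be positive")
    wf = np.asarray(mean_waveform_uv, dtype=float)
    if wf.size == 0:
        raise ValueError("empty waveform")
    snr = float(np.max(np.abs(wf)) / noise_sd_uv)
    return snr, snr > SNR_GATE


@dataclass(frozen=True)
class TrialResponseSet:
    """Per-stimulus trial firing rates plus the baseline statistics.

    ``stimuli`` are (frequency Hz, amplitude um) pairs; ``trial_rates[i]``
    holds the per-trial rates (Hz) for ``stimuli[i]``.
    """

    stimuli: list[tuple[float, float]]
    trial_rates: list[np.ndarray]
    baseline_mean_hz: float
    baseline_sd_hz: float

    def __post_init__(self) -> None:
        if len(self.stimuli) != len(self.trial_rates):
            raise ValueError("one rate array per stimulus required")
        if any(len(r) == 0 for r in self.trial_rates):
            raise ValueError("every stimulus needs at least one trial")
        object.__setattr__(
            self, "trial_rates", [np.asarray(r, dtype=float) for r in self.trial_rates]
        )
        if any(r.min() < 0 for r in self.trial_rates):
            raise ValueError("rates must be non-negative")

    def mean_rates(self) -> np.ndarray:
        return np.array([r.mean() for r in self.trial_rates])


def is_responsive(
    trials: TrialResponseSet,
    rel_margin: float = 0.05,
    trial_fraction: float = 0.20,
) -> bool:
    """Three-part responsiveness criterion against baseline firing.

    A unit is responsive iff its best stimulus response (i) exceeds the
    baseline mean by more than ``rel_margin`` (5%) on average, (ii) exceeds
    baseline mean + 2 SD, and (iii) single trials of that stimulus exceed
    baseline mean + 2 SD on at least ``trial_fraction`` (20%) of trials.
    The 5% margin is relative to the baseline mean rate.
    """
    if not trials.stimuli:
        raise ValueError("no trials provided")
    means = trials.mean_rates()
    best = int(np.argmax(means))
    best_mean = means[best]
    mu, sd = trials.baseline_mean_hz, trials.baseline_sd_hz
    if best_mean <= mu * (1.0 + rel_margin):
        return False
    if best_mean <= mu + 2.0 * sd:
        return False
    rates = trials.trial_rates[best]
    frac = np.mean(rates > mu + 2.0 * sd)
    return bool(frac >= trial_fraction)


# ---------------------------------------------------------------------------
# frequency tuning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningCurve:
    """Degree-6 polynomial fit of a peak-normalized frequency tuning curve."""

    frequencies_hz: np.ndarray
    normalized_responses: np.ndarray
    coefficients: np.ndarray  # power-basis coefficients, ascending
    fit_r: float
    fit_p: float
    preferred_frequency_hz: float
    half_width_hz: float | None
    tuning_index_value: float
    width_defined: bool

    @property
    def selective(self) -> bool:
        """Frequency-selectivity gate: well fit (r > 0.7, P < 0.05) and TI > 0.2."""
        return (
            self.fit_r > FIT_R_GATE
            and self.fit_p < 0.05
            and self.tuning_index_value > TI_GATE
        )


def tuning_index(mu_pref: float, mu_ortho: float) -> float:
    """Tuning index TI = (mu_pref - mu_ortho) / (mu_pref + mu_ortho).

    ``mu_pref`` is the mean response at the preferred frequency and
    ``mu_ortho`` the mean response at the least preferred frequency; the
    index is scale-invariant and lies in [0, 1] for non-negative responses.
    """
    if mu_pref < mu_ortho:
        raise ValueError("mu_pref must be >= mu_ortho")
    if mu_ortho < 0:
        raise ValueError("responses must be non-negative")
    if mu_pref + mu_ortho == 0:
        raise ValueError("tuning index undefined for two zero responses")
    return (mu_pref - mu_ortho) / (mu_pref + mu_ortho)


def fit_tuning(
    frequencies_hz,
    mean_responses,
    grid_step_hz: float = 1.0,
    degree: int = 6,
) -> TuningCurve:
    """Fit a degree-6 polynomial to the peak-normalized tuning curve.

    Responses are normalized to their maximum, fit by least squares, and the
    fitted curve is evaluated on a dense grid (1-Hz steps) within the
    sampled range. The preferred frequency is the grid argmax (ties broken
    toward the lower frequency); the tuning width is the full width at half
    maximum of the fitted curve divided by two, undefined when the fitted
    curve is nowhere positive. ``fit_r`` is the Pearson correlation between
    fitted and observed normalized responses.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    y = np.asarray(mean_responses, dtype=float)
    if f.size != y.size:
        raise ValueError("frequencies and responses must have equal length")
    if np.unique(f).size < degree + 2:
        raise ValueError(
            f"need >= {degree + 2} distinct frequencies for an identifiable "
            f"degree-{degree} fit, got {np.unique(f).size}"
        )
    peak = y.max()
    if peak <= 0:
        raise ValueError("responses must contain a positive value")
    ynorm = y / peak
    # fit in a scaled domain for conditioning; convert back to power basis
    poly = Polynomial.fit(f, ynorm, degree)
    fitted = poly(f)
    r, p = pearsonr(ynorm, fitted)
    grid = np.arange(f.min(), f.max() + 0.5 * grid_step_hz, grid_step_hz)
    curve = poly(grid)
    i_peak = int(np.argmax(curve))  # first occurrence -> lower frequency on ties
    preferred = float(grid[i_peak])
    peak_val = float(curve[i_peak])
    if peak_val <= 0:
        half_width, defined = None, False
    else:
        half = peak_val / 2.0
        above = curve >= half
        lo = i_peak
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i_peak
        while hi < grid.size - 1 and above[hi + 1]:
            hi += 1
        half_width, defined = float(grid[hi] - grid[lo]) / 2.0, True
    ti = tuning_index(float(ynorm.max()), float(max(ynorm.min(), 0.0)))
    return TuningCurve(
        frequencies_hz=f,
        normalized_responses=ynorm,
        coefficients=poly.convert().coef,
        fit_r=float(r),
        fit_p=float(p),
        preferred_frequency_hz=preferred,
        half_width_hz=half_width,
        tuning_index_value=ti,
        width_defined=defined,
    )


# ---------------------------------------------------------------------------
# mechanical thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdResult:
    """A unit's mechanical threshold, or an undefined flag when silent."""

    unit_id: int | str
    amplitude_um: float | None
    defined: bool
    method: str
    window_s: tuple[float, float] | None = None


def first_spike_threshold(train: SpikeTrain, epoch: VibrationEpoch) -> ThresholdResult:
    """Ramp amplitude at the first spike inside a linearly increasing epoch.

    The stimulus must have a ramp profile; a unit with no in-epoch spikes
    gets an undefined (not an error) result.
    """
    if epoch.profile != "ramp":
        raise ValueError("first-spike threshold requires a ramp-profile epoch")
    spikes = train.in_window(epoch.onset_s, epoch.end_s)
    if spikes.size == 0:
        return ThresholdResult(train.unit_id, None, False, "first_spike")
    amp = float(epoch.amplitude_at(spikes[0]))
    return ThresholdResult(train.unit_id, amp, True, "first_spike")


def sustained_rate_threshold(
    amplitudes_um,
    sustained_rates_hz,
    max_rate_hz: float | None = None,
    window_s: tuple[float, float] = SUSTAINED_WINDOW_S,
    fraction: float = 0.20,
    unit_id: int | str = 0,
) -> ThresholdResult:
    """Smallest amplitude whose sustained rate reaches 20% of the unit's maximum.

    ``sustained_rates_hz`` are firing rates in the sustained window (by
    convention 200 ms starting 50 ms after onset), one per tested amplitude.
    ``max_rate_hz`` defaults to the maximum over the tested amplitudes but
    can be supplied when the unit's maximum firing was established elsewhere.
    """
    amps = np.asarray(amplitudes_um, dtype=float)
    rates = np.asarray(sustained_rates_hz, dtype=float)
    if amps.size != rates.size:
        raise ValueError("one rate per amplitude required")
    if amps.size < 2:
        raise ValueError("need >= 2 tested amplitudes")
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    order = np.argsort(amps)
    amps, rates = amps[order], rates[order]
    ref = float(max_rate_hz) if max_rate_hz is not None else float(rates.max())
    if ref <= 0:
        return ThresholdResult(unit_id, None, False, "sustained_rate", window_s)
    qualifying = np.nonzero(rates >= fraction * ref)[0]
    if qualifying.size == 0:
        return ThresholdResult(unit_id, None, False, "sustained_rate", window_s)
    return ThresholdResult(
        unit_id, float(amps[qualifying[0]]), True, "sustained_rate", window_s
    )
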