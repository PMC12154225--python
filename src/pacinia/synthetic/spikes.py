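"""Synthetic spike trains: phase-locked, Poisson, and ramp-evoked.

All generators take an explicit seed and never touch global random state.
"""

from __future__ import annotations

import numpy as np

from ..datatypes import SpikeTrain, VibrationEpoch


def _finish(times: np.ndarray, duration_s: float, unit_id) -> SpikeTrain:
    times = np.sort(times[(times >= 0) & (times < duration_s)])
    times = np.unique(times)  # coincidences are measure-zero; drop duplicates
    return SpikeTrain(times, unit_id=unit_id)


def make_phase_locked_spikes(
    freq_hz: float,
    duration_s: float,
    jitter_sd_s: float = 0.0,
    miss_prob: float = 0.0,
    seed: int | None = None,
    unit_id: int | str = 0,
) -> SpikeTrain:
    """One candidate spike per stimulus cycle, at cycle onset plus Gaussian jitter.

    Each cycle's spike is independently skipped with probability
    ``miss_prob``, modelling sub-harmonic entrainment. With zero jitter and
    no misses the train is exactly periodic at the stimulus frequency.
    """
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if jitter_sd_s < 0:
        raise ValueError("jitter SD must be non-negative")
    if not 0 <= miss_prob < 1:
        raise ValueError("miss probability must be in [0, 1)")
    rng = np.random.default_rng(seed)
    period = 1.0 / freq_hz
    n_cycles = int(np.floor(duration_s * freq_hz))
    times = np.arange(n_cycles) * period
    if miss_prob > 0:
        times = times[rng.random(n_cycles) >= miss_prob]
    if jitter_sd_s > 0:
        times = times + rng.normal(0.0, jitter_sd_s, size=times.size)
    return _finish(times, duration_s, unit_id)


def make_poisson_spikes(
    rate_hz: float,
    duration_s: float,
    seed: int | None = None,
    unit_id: int | str = 0,
) -> SpikeTrain:
    """Homogeneous Poisson spike train on ``[0, duration)``.

    A zero duration yields an empty train; negative durations and
    non-positive rates are rejected.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    if duration_s == 0:
        return SpikeTrain(np.empty(0), unit_id=unit_id)
    n = rng.poisson(rate_hz * duration_s)
    times = rng.uniform(0.0, duration_s, size=n)
    return _finish(times, duration_s, unit_id)


def make_ramp_evoked_spikes(
    unit_threshold_um: float,
    ramp_peak_um: float,
    ramp_duration_s: float,
    freq_hz: float,
    seed: int | None = None,
    jitter_sd_s: float = 0.0,
    unit_id: int | str = 0,
) -> tuple[SpikeTrain, VibrationEpoch]:
    """Phase-locked firing once a linear amplitude ramp crosses the unit threshold.

    The epoch amplitude rises linearly from 0 to ``ramp_peak_um`` over
    ``ramp_duration_s``. No spikes are emitted while the instantaneous
    amplitude is below ``unit_threshold_um``; afterwards the unit fires once
    per cycle. A threshold above the ramp peak yields an empty (sub-threshold)
    train rather than an error.
    """
    if unit_threshold_um <= 0:
        raise ValueError("unit threshold must be positive")
    if ramp_peak_um <= 0 or ramp_duration_s <= 0 or freq_hz <= 0:
        raise ValueError("ramp peak, duration and frequency must be positive")
    epoch = VibrationEpoch(0.0, ramp_duration_s, freq_hz, "ramp", ramp_peak_um)
    if unit_threshold_um > ramp_peak_um:
        return SpikeTrain(np.empty(0), unit_id=unit_id), epoch
    rng = np.random.default_rng(seed)
    period = 1.0 / freq_hz
    t0 = unit_threshold_um / ramp_peak_um * ramp_duration_s
    first_cycle = int(np.ceil(t0 / period - 1e-12))
    n_cycles = int(np.floor(ramp_duration_s * freq_hz))
    times = np.arange(first_cycle, n_cycles + 1) * period
    times = times[times <= ramp_duration_s]
    if jitter_sd_s > 0:
        times = times + rng.normal(0.0, jitter_sd_s, size=times.size)
    times = np.unique(np.sort(times[(times >= t0) & (times <= ramp_duration_s)]))
    return SpikeTrain(times, unit_id=unit_id), epoch
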