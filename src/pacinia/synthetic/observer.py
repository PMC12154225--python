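"""Simulated observers for the vibrotactile detection task.

The observer is a parametric stand-in for a trained, head-restrained mouse
performing a two-alternative forced-choice detection task: on vibration
trials its probability of a correct report follows a lapse-adjusted
cumulative-Gaussian psychometric function of amplitude in dB, floored at the
0.5 chance level; on catch (stimulus-absent) trials it responds correctly
with a fixed accuracy. ``inhibition_factor`` multiplies the linear detection
threshold and emulates a pharmacological/optogenetic elevation of the
perceptual threshold (a factor of 5 corresponds to ~+14 dB).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr


def amplitude_to_db(amplitude_um: float | np.ndarray) -> float | np.ndarray:
    """Amplitude in dB re 1 um: ``20 * log10(A / 1 um)``."""
    return 20.0 * np.log10(amplitude_um)


def db_to_amplitude(db: float | np.ndarray) -> float | np.ndarray:
    return 10.0 ** (np.asarray(db, dtype=float) / 20.0)


@dataclass(frozen=True)
class ObserverModel:
    """Parametric psychometric observer.

    Parameters
    ----------
    threshold_db
        Amplitude (dB re 1 um) at which detection probability reaches its
        half-way point; with zero lapse the accuracy there is 0.75.
    slope_db
        SD of the cumulative Gaussian in dB (smaller = steeper).
    lapse_rate
        Asymptotic error rate on easy trials, in [0, 0.1].
    catch_accuracy
        Probability of a correct rejection on catch trials, in [0.5, 1].
        In this observer form chance-level vibration performance is 0.5, so
        a catch accuracy far above 0.5 encodes a strongly conservative
        response bias without the matching drop in vibration hits; the
        default 0.65 keeps the observer close to bias-consistent.
    inhibition_factor
        Multiplier (>= 1) on the linear threshold, i.e.
        ``+20 * log10(factor)`` dB of threshold elevation.
    """

    threshold_db: float
    slope_db: float = 2.0
    lapse_rate: float = 0.02
    catch_accuracy: float = 0.65
    inhibition_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.slope_db <= 0:
            raise ValueError("slope must be positive")
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse rate must be in [0, 0.1]")
        if not 0.5 <= self.catch_accuracy <= 1:
            raise ValueError("catch accuracy must be in [0.5, 1]")
        if self.inhibition_factor < 1:
            raise ValueError("inhibition factor must be >= 1")

    @property
    def effective_threshold_db(self) -> float:
        return self.threshold_db + 20.0 * math.log10(self.inhibition_factor)

    @property
    def effective_threshold_um(self) -> float:
        return float(db_to_amplitude(self.effective_threshold_db))

    def p_correct(self, amplitude_um: float | None) -> float:
        """Probability of a correct response.

        ``amplitude_um=None`` (or a catch trial) returns ``catch_accuracy``;
        a zero amplitude degenerates to the 0.5 chance floor.
        """
        if amplitude_um is None:
            return self.catch_accuracy
        if amplitude_um < 0:
            raise ValueError("amplitude must be non-negative")
        if amplitude_um == 0:
            return 0.5
        x = (amplitude_to_db(amplitude_um) - self.effective_threshold_db) / self.slope_db
        return 0.5 + (0.5 - self.lapse_rate) * float(ndtr(x))

    def respond(self, amplitude_um: float | None, rng: np.random.Generator) -> bool:
        """Draw one binary trial outcome (True = correct)."""
        return bool(rng.random() < self.p_correct(amplitude_um))


def observer_response(
    observer: ObserverModel,
    amplitude_um: float | None,
    rng: np.random.Generator | int | None = None,
) -> bool:
    """Single trial outcome for ``observer``; ``amplitude_um=None`` is a catch trial."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return observer.respond(amplitude_um, rng)
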