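"""Adaptive staircase, binomial threshold rule and sensitivity curves.

Implements the two-alternative forced-choice vibrotactile detection
procedure: sessions start at the largest amplitude the actuator can produce
at the tested frequency and attenuate in -4 dB steps after every block of
six vibration trials (about twelve trials including catch trials) whenever
the proportion of correct responses exceeds 70%; the amplitude is raised by
4 dB when it falls below 60%, and held otherwise. Trial types are drawn
pseudo-randomly (50% vibration / 50% catch, at most three of the same type
in a row). The perceptual threshold of a session is the lowest visited
amplitude whose pooled correct-response ratio beats chance (0.5) in a
one-sided exact binomial test at P < 0.05; thresholds of repeated sessions
are averaged per frequency into a (V-shaped) sensitivity curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

#: standard frequency set of the detection task (Hz)
DEFAULT_FREQUENCY_SET_HZ = (300.0, 450.0, 700.0, 1000.0, 1300.0, 1600.0, 2000.0)


@dataclass(frozen=True)
class StaircaseConfig:
    """Rules of the adaptive staircase."""

    start_amplitude_um: float
    step_db: float = 4.0
    down_rule: float = 0.70  # attenuate when correct fraction exceeds this
    up_rule: float = 0.60    # amplify when correct fraction falls below this
    vibration_trials_per_block: int = 6
    floor_amplitude_um: float = 1e-4
    max_same_type_run: int = 3

    def __post_init__(self) -> None:
        if self.start_amplitude_um <= 0:
            raise ValueError("start amplitude must be positive")
        if self.step_db <= 0:
            raise ValueError("step must be positive")
        if not 0.5 < self.up_rule < self.down_rule < 1.0:
            raise ValueError("rules must satisfy 0.5 < up < down < 1")
        if self.vibration_trials_per_block < 1:
            raise ValueError("block must contain at least one vibration trial")
        if not 0 < self.floor_amplitude_um <= self.start_amplitude_um:
            raise ValueError("floor must be positive and below the start amplitude")

    @property
    def step_factor(self) -> float:
        """Multiplicative amplitude factor of one step: 10^(step_db/20)."""
        return 10.0 ** (self.step_db / 20.0)


@dataclass(frozen=True)
class TrialRecord:
    index: int
    trial_type: str  # "vibration" | "catch"
    amplitude_um: float  # staircase amplitude in force at this trial
    amplitude_step: int  # attenuation steps below the start amplitude
    correct: bool


@dataclass
class SessionLog:
    """Ordered trial records of one detection session at one frequency."""

    frequency_hz: float
    config: StaircaseConfig
    seed: int | None
    trials: list[TrialRecord] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def amplitudes_visited_um(self) -> list[float]:
        return sorted({t.amplitude_um for t in self.trials})


@dataclass(frozen=True)
class AmplitudeOutcome:
    amplitude_um: float
    n_trials: int
    n_correct: int
    p_value: float


@dataclass(frozen=True)
class PerceptualThreshold:
    """Per-session threshold and the per-amplitude binomial table behind it."""

    frequency_hz: float
    threshold_um: float | None
    defined: bool
    per_amplitude: list[AmplitudeOutcome]


def staircase_update(
    block_outcomes,
    current_amplitude_um: float,
    config: StaircaseConfig,
) -> float:
    """Next amplitude after a completed block.

    ``block_outcomes`` are the block's correct/incorrect booleans (vibration
    and catch trials both count). Correct fraction above the down rule
    attenuates by one step, below the up rule amplifies by one step (capped
    at the start amplitude); in between the amplitude is held.
    """
    outcomes = [bool(o) for o in block_outcomes]
    if not outcomes:
        raise ValueError("empty block")
    frac = sum(outcomes) / len(outcomes)
    amp = current_amplitude_um
    if frac > config.down_rule:
        amp = amp / config.step_factor
    elif frac < config.up_rule:
        amp = min(amp * config.step_factor, config.start_amplitude_um)
    return max(amp, config.floor_amplitude_um)


def _draw_trial_type(rng: np.random.Generator, recent: list[str], max_run: int) -> str:
    if len(recent) >= max_run and len(set(recent[-max_run:])) == 1:
        return "catch" if recent[-1] == "vibration" else "vibration"
    return "vibration" if rng.random() < 0.5 else "catch"


def run_session(
    observer,
    config: StaircaseConfig,
    frequency_hz: float,
    n_trials: int,
    seed: int | None = None,
) -> SessionLog:
    """Simulate one staircase session against an observer.

    ``observer`` is anything with a ``respond(amplitude_um | None, rng)``
    method returning True for a correct report (catch trials pass ``None``).
    The amplitude changes only at block boundaries (after every
    ``vibration_trials_per_block`` vibration trials) and is tracked as an
    integer number of dB steps below the start amplitude so that repeated
    visits to an amplitude compare exactly equal.
    """
    if n_trials < config.vibration_trials_per_block:
        raise ValueError("session shorter than one block")
    rng = np.random.default_rng(seed)
    log = SessionLog(frequency_hz=frequency_hz, config=config, seed=seed)
    step = 0  # attenuation steps below start (>= 0)
    min_step = int(
        np.floor(
            20.0 * np.log10(config.start_amplitude_um / config.floor_amplitude_um)
            / config.step_db
        )
    )
    block: list[bool] = []
    block_vibration = 0
    types: list[str] = []
    for i in range(n_trials):
        amp = config.start_amplitude_um / config.step_factor**step
        ttype = _draw_trial_type(rng, types, config.max_same_type_run)
        types.append(ttype)
        correct = observer.respond(amp if ttype == "vibration" else None, rng)
        log.trials.append(TrialRecord(i, ttype, amp, step, bool(correct)))
        block.append(bool(correct))
        if ttype == "vibration":
            block_vibration += 1
        if block_vibration >= config.vibration_trials_per_block:
            frac = sum(block) / len(block)
            if frac > config.down_rule:
                step = min(step + 1, min_step)
            elif frac < config.up_rule:
                step = max(step - 1, 0)
            block = []
            block_vibration = 0
    return log


def binomial_threshold(
    log: SessionLog,
    alpha: float = 0.05,
    per_bout: bool = False,
    include_catch: bool = False,
) -> PerceptualThreshold:
    """Lowest amplitude whose correct ratio beats chance (one-sided binomial).

    By default only vibration trials are tested: a catch trial carries no
    stimulus amplitude, and because correct rejections stay well above
    chance even when nothing is detectable, pooling them would let purely
    guessed amplitudes drift to significance. ``include_catch=True`` pools
    the catch trials delivered while the staircase sat at each amplitude.
    All of an amplitude's trials are pooled across the session by default;
    ``per_bout=True`` instead tests each contiguous bout at an amplitude
    separately and accepts an amplitude if any of its bouts is significant.
    """
    if not log.trials:
        raise ValueError("empty session log")
    # a "bout" is one maximal run of trials at the same staircase amplitude
    bout_ids: list[int] = []
    bout = 0
    for i, t in enumerate(log.trials):
        if i and t.amplitude_step != log.trials[i - 1].amplitude_step:
            bout += 1
        bout_ids.append(bout)
    groups: dict[int, list[tuple[int, TrialRecord]]] = {}
    for bid, t in zip(bout_ids, log.trials):
        if not include_catch and t.trial_type != "vibration":
            continue
        groups.setdefault(t.amplitude_step, []).append((bid, t))
    if not groups:
        raise ValueError("no vibration trials in session log")

    def test(trials: list[TrialRecord]) -> float:
        k = sum(t.correct for t in trials)
        return binomtest(k, len(trials), 0.5, alternative="greater").pvalue

    per_amp: list[AmplitudeOutcome] = []
    qualifying: list[float] = []
    for step_key in sorted(groups):
        tagged = groups[step_key]
        trials = [t for _, t in tagged]
        amp = trials[0].amplitude_um
        if per_bout:
            bouts: dict[int, list[TrialRecord]] = {}
            for bid, t in tagged:
                bouts.setdefault(bid, []).append(t)
            p = min(test(b) for b in bouts.values())
        else:
            p = test(trials)
        per_amp.append(
            AmplitudeOutcome(amp, len(trials), sum(t.correct for t in trials), float(p))
        )
        if p < alpha:
            qualifying.append(amp)
    if qualifying:
        return PerceptualThreshold(log.frequency_hz, min(qualifying), True, per_amp)
    return PerceptualThreshold(log.frequency_hz, None, False, per_amp)


def sensitivity_curve(
    thresholds: list[PerceptualThreshold],
    frequency_set_hz=DEFAULT_FREQUENCY_SET_HZ,
) -> dict[float, float | None]:
    """Arithmetic mean threshold per frequency over repeated sessions.

    Frequencies of the set with no defined threshold map to ``None``; with a
    U-shaped observer threshold profile the resulting amplitude curve is the
    V-shaped vibrotactile sensitivity curve.
    """
    if not thresholds:
        raise ValueError("no thresholds supplied")
    curve: dict[float, float | None] = {}
    for f in frequency_set_hz:
        vals = [t.threshold_um for t in thresholds if t.frequency_hz == f and t.defined]
        curve[float(f)] = float(np.mean(vals)) if vals else None
    return curve
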