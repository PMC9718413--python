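"""Game logic for the target-aiming neurofeedback games.

Three visual metaphors (paper toss, archery, frisbee) share one paradigm:
an attempt succeeds when the current MMN amplitude strictly exceeds a
stage threshold expressed as a fraction of the participant's maximal MMN
(20/40/50/60% for stages 1-4).  A stage is cleared when strictly more than
half of its attempts succeed; an uncleared stage is replayed.  In the
yoked-sham mode the feedback driving the game comes from a donor
participant's recorded estimates, severing the contingency with the
player's own brain activity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import CalibrationError, ParameterError, ShamError
from .online import CalibrationResult
from .signal_core import MMNEstimate

GAMES = ("paper_toss", "archery", "frisbee")
STAGE_FRACTIONS = (0.20, 0.40, 0.50, 0.60)
_PERMUTATIONS = tuple(itertools.permutations(GAMES))  # lexicographic, 6 orders


@dataclass(frozen=True)
class GameConfig:
    """Session and stage structure of one training day."""

    games: tuple = GAMES
    stage_fractions: tuple = STAGE_FRACTIONS
    attempts_per_stage: int = 10
    sounds_per_session: int = 300
    soa_ms: float = 800.0
    sessions_per_game_per_day: int = 4

    def __post_init__(self):
        fr = self.stage_fractions
        if any(not (0.0 < f <= 1.0) for f in fr) or any(
            a >= b for a, b in zip(fr, fr[1:])
        ):
            raise ParameterError("stage fractions must be strictly increasing in (0, 1]")
        if self.attempts_per_stage < 1:
            raise ParameterError("attempts_per_stage must be >= 1")

    @property
    def games_per_day(self) -> int:
        return len(self.games)

    @property
    def sessions_per_day(self) -> int:
        return self.games_per_day * self.sessions_per_game_per_day

    @property
    def n_stages(self) -> int:
        return len(self.stage_fractions)

    @property
    def session_duration_s(self) -> float:
        """0.8 s x 300 sounds = 240 s by default."""
        return self.soa_ms / 1000.0 * self.sounds_per_session

    @property
    def attempt_every_n_sounds(self) -> int:
        """Attempt cadence: one attempt per stage-block share of a session."""
        return max(1, self.sounds_per_session // self.attempts_per_stage)


@dataclass
class StageState:
    """Current stage and the running attempt outcomes of its block."""

    stage_index: int = 1
    outcomes: list = field(default_factory=list)

    def cleared(self, attempts_per_stage: int) -> bool:
        """Strictly more than half of the block's attempts succeeded."""
        return sum(self.outcomes) * 2 > attempts_per_stage


@dataclass
class FeedbackSource:
    """Genuine feedback, or a yoked-sham donor stream of estimates.

    ``donor_stream[t]`` is the donor's estimate at trial index ``t``
    (``None`` where the donor was still warming up).
    """

    mode: str = "genuine"
    donor_stream: Sequence | None = None

    def __post_init__(self):
        if self.mode not in ("genuine", "yoked"):
            raise ParameterError(f"bad feedback mode {self.mode!r}")
        if self.mode == "yoked" and self.donor_stream is None:
            raise ParameterError("yoked mode requires a donor stream")


def evaluate_attempt(
    estimate: MMNEstimate,
    calibration: CalibrationResult,
    stage_index: int,
    config: GameConfig = GameConfig(),
) -> bool:
    """True iff amplitude strictly exceeds the stage threshold.

    threshold = stage_fraction[stage] * maximal MMN; the comparison is
    strict, so amplitude exactly at threshold fails.
    """
    if calibration is None or calibration.max_mmn <= 0:
        raise CalibrationError("valid calibration required to score attempts")
    if not 1 <= stage_index <= config.n_stages:
        raise ParameterError(f"stage_index must be in 1..{config.n_stages}")
    threshold = config.stage_fractions[stage_index - 1] * calibration.max_mmn
    return estimate.amplitude > threshold


def advance_stage(state: StageState, config: GameConfig = GameConfig()) -> StageState:
    """Close an attempt block: move up on clear (capped at the top stage),
    stay otherwise; outcomes reset either way."""
    if state.cleared(config.attempts_per_stage):
        nxt = min(state.stage_index + 1, config.n_stages)
    else:
        nxt = state.stage_index
    return StageState(stage_index=nxt, outcomes=[])


def route_feedback(
    source: FeedbackSource, live_estimate: MMNEstimate | None, t: int
) -> MMNEstimate | None:
    """Select the estimate that drives the game at trial index ``t``.

    Genuine mode is the identity on the live estimate; yoked mode reads the
    donor stream and never the live participant's own estimate.
    """
    if source.mode == "genuine":
        return live_estimate
    try:
        return source.donor_stream[t]
    except IndexError:
        raise ShamError(f"donor stream exhausted at trial {t}") from None


@dataclass(frozen=True)
class SessionPlan:
    game: str
    session_of_game: int
    n_sounds: int
    soa_ms: float

    @property
    def duration_s(self) -> float:
        return self.soa_ms / 1000.0 * self.n_sounds


@dataclass(frozen=True)
class TrainingDayPlan:
    game_order: tuple
    sessions: tuple


def plan_training_day(
    participant_seed: int, day_index: int = 0, config: GameConfig = GameConfig()
) -> TrainingDayPlan:
    """Ordered plan of one training day: 12 sessions in 3 contiguous
    4-session blocks, one block per game.

    The game order is one of the 6 permutations, assigned by a Latin-square
    rule keyed on ``(participant_seed + day_index)``, so any 6 consecutive
    participant seeds cover all 6 orders, and a participant's order rotates
    across days.
    """
    order = _PERMUTATIONS[(int(participant_seed) + int(day_index)) % len(_PERMUTATIONS)]
    sessions = tuple(
        SessionPlan(g, k, config.sounds_per_session, config.soa_ms)
        for g in order
        for k in range(1, config.sessions_per_game_per_day + 1)
    )
    return TrainingDayPlan(order, sessions)


@dataclass
class AttemptRecord:
    """One scored attempt within a session."""

    sound_index: int          # 1-based index of the sound that triggered it
    stage_index: int
    feedback_amplitude: float
    threshold: float
    success: bool


@dataclass
class SessionResult:
    attempts: list
    state: StageState
    n_trials: int


def run_session(
    estimates: Iterable,
    state: StageState,
    calibration: CalibrationResult,
    config: GameConfig = GameConfig(),
    source: FeedbackSource = FeedbackSource(),
) -> SessionResult:
    """Play one session of attempts over a per-trial estimate stream.

    ``estimates`` yields the live estimate in force after each sound
    (``None`` during warm-up), e.g. from ``online.stream_session``.
    Attempts are scheduled every ``config.attempt_every_n_sounds`` sounds
    and use the routed (genuine or yoked) estimate; no estimate available
    means no attempt.  When a block of ``attempts_per_stage`` outcomes is
    complete the stage advances (or repeats) immediately.
    """
    attempts: list[AttemptRecord] = []
    every = config.attempt_every_n_sounds
    n = 0
    for i, live in enumerate(estimates, start=1):
        n = i
        if i % every != 0:
            continue
        fb = route_feedback(source, live, i - 1)
        if fb is None:
            continue
        success = evaluate_attempt(fb, calibration, state.stage_index, config)
        threshold = config.stage_fractions[state.stage_index - 1] * calibration.max_mmn
        attempts.append(
            AttemptRecord(i, state.stage_index, fb.amplitude, threshold, success)
        )
        state.outcomes.append(success)
        if len(state.outcomes) >= config.attempts_per_stage:
            state = advance_stage(state, config)
    return SessionResult(attempts, state, n)
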