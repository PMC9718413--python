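"""Behavioral paradigms: the same/different auditory discrimination (BAD)
test and the two-alternative forced-choice identification training.

Both tasks use the word pair "light"/"right".  The BAD test presents 96
pair trials (four permutations in equal proportion, balanced across two
blocks) and is scored as the proportion of correct same/different
judgments; chance is 50% by design.  The 2AFC training presents the
orthographies 300 ms before the spoken word, allows 1.9 s to respond, and
in the feedback condition plays a chime for a correct response and a
buzzer for an incorrect one; the control condition is identical without
feedback.  Responders are plug-in callables, so human replay logs and
simulated policies run through the same code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError

WORDS = ("light", "right")
BAD_PAIRS = (
    ("light", "right"),
    ("light", "light"),
    ("right", "right"),
    ("right", "light"),
)
WITHIN_PAIR_SOA_MS = 800.0
RESPONSE_WINDOW_S = 1.9
ORTHOGRAPHY_LEAD_MS = 300.0


@dataclass
class BADTrial:
    """One same/different trial; ``response`` is ``"same"``, ``"different"``
    or ``None`` for a timeout (scored incorrect)."""

    first: str
    second: str
    block: int = 1
    within_pair_soa_ms: float = WITHIN_PAIR_SOA_MS
    response: str | None = None
    correct: bool | None = None

    @property
    def is_different(self) -> bool:
        return self.first != self.second


@dataclass
class TrainingTrial:
    """One 2AFC identification trial.

    ``screen_sides`` is the (left word, right word) layout shown 300 ms
    before the sound; ``response`` is ``"left"``, ``"right"`` or ``None``.
    """

    spoken: str
    screen_sides: tuple
    block: int = 1
    response_window_s: float = RESPONSE_WINDOW_S
    orthography_lead_ms: float = ORTHOGRAPHY_LEAD_MS
    response: str | None = None
    rt_ms: float | None = None
    correct: bool | None = None
    feedback: str = "none"

    @property
    def correct_side(self) -> str:
        return "left" if self.screen_sides[0] == self.spoken else "right"


@dataclass(frozen=True)
class BADScore:
    n_correct: int
    n_incorrect: int

    @property
    def proportion(self) -> float:
        return self.n_correct / (self.n_correct + self.n_incorrect)


def generate_bad_sequence(
    seed: int, n_trials: int = 96, n_blocks: int = 2
) -> list[BADTrial]:
    """Seeded 96-trial BAD sequence, counterbalanced across blocks.

    Each of the four pair permutations appears ``n_trials / n_blocks / 4``
    times per block (12 by default), shuffled within block.
    """
    per_block = n_trials // n_blocks
    if n_trials != per_block * n_blocks or per_block % len(BAD_PAIRS) != 0:
        raise ParameterError(
            "n_trials must split into blocks with equal counts per permutation"
        )
    rng = np.random.default_rng(seed)
    trials: list[BADTrial] = []
    for b in range(1, n_blocks + 1):
        block = [
            BADTrial(first, second, block=b)
            for first, second in BAD_PAIRS
            for _ in range(per_block // len(BAD_PAIRS))
        ]
        rng.shuffle(block)
        trials.extend(block)
    return trials


def score_bad_trial(trial: BADTrial) -> bool:
    """Correct iff the response matches whether the pair members differ;
    a timeout counts as incorrect."""
    if trial.response is None:
        return False
    return (trial.response == "different") == trial.is_different


def run_bad_test(
    trials: Sequence[BADTrial], responder: Callable[[BADTrial], str | None]
) -> list[BADTrial]:
    """Collect and score responses for a BAD sequence (in place)."""
    for t in trials:
        t.response = responder(t)
        t.correct = score_bad_trial(t)
    return list(trials)


def score_bad(trials: Sequence[BADTrial]) -> BADScore:
    """Totals over answered/timed-out trials."""
    if not trials:
        raise ParameterError("cannot score an empty trial list")
    n_ok = sum(1 for t in trials if score_bad_trial(t))
    return BADScore(n_ok, len(trials) - n_ok)


def generate_training_sequence(seed: int, n_trials: int = 96, n_blocks: int = 2) -> list[TrainingTrial]:
    """Seeded 2AFC sequence: spoken words balanced, screen layout
    balanced within each spoken word (prevents position bias)."""
    per_block = n_trials // n_blocks
    if n_trials != per_block * n_blocks or per_block % 4 != 0:
        raise ParameterError("n_trials must split into blocks divisible by 4")
    rng = np.random.default_rng(seed)
    layouts = (WORDS, WORDS[::-1])
    trials: list[TrainingTrial] = []
    for b in range(1, n_blocks + 1):
        block = [
            TrainingTrial(spoken, sides, block=b)
            for spoken in WORDS
            for sides in layouts
            for _ in range(per_block // 4)
        ]
        rng.shuffle(block)
        trials.extend(block)
    return trials


def run_training_block(
    trials: Sequence[TrainingTrial],
    feedback_on: bool,
    responder: Callable[[TrainingTrial], str | None],
) -> list[TrainingTrial]:
    """Run the identification task over prepared trials (in place).

    Fills responses and correctness; in the feedback condition a correct
    response earns a chime and an incorrect one (including a timeout) a
    buzzer; without feedback every trial's feedback is ``"none"``.
    """
    for t in trials:
        t.response = responder(t)
        t.correct = t.response is not None and t.response == t.correct_side
        t.feedback = ("chime" if t.correct else "buzzer") if feedback_on else "none"
    return list(trials)


def bernoulli_responder(p_correct: float, rng: np.random.Generator):
    """Simulated policy answering correctly with probability ``p_correct``.

    Works for both tasks: it inspects the trial type to find the correct
    answer and returns it (or the single alternative) accordingly.
    """

    def _respond(trial):
        ok = rng.random() < p_correct
        if isinstance(trial, BADTrial):
            truth = "different" if trial.is_different else "same"
            alt = "same" if truth == "different" else "different"
        else:
            truth = trial.correct_side
            alt = "left" if truth == "right" else "right"
        return truth if ok else alt

    return _respond
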