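"""Adaptive two-consecutive staircase over 10 difficulty levels.

One level harder after two consecutive correct trials, one level easier
after two consecutive errors, unchanged otherwise (streak resets after every
level move).  With any monotone per-level accuracy crossing 0.5 this rule
drives mean accuracy to ~50%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = ["StaircaseState", "staircase_update"]

MIN_LEVEL, MAX_LEVEL = 1, 10


@dataclass(frozen=True)
class StaircaseState:
    level: int = 5
    streak_outcome: Optional[bool] = None  # True=correct, False=error, None=no streak
    streak_len: int = 0

    def __post_init__(self) -> None:
        if not MIN_LEVEL <= self.level <= MAX_LEVEL:
            raise ValueError(f"level must be in [{MIN_LEVEL}, {MAX_LEVEL}]")
        if self.streak_len not in (0, 1, 2):
            raise ValueError("streak_len must be 0, 1 or 2")
        if (self.streak_len == 0) != (self.streak_outcome is None):
            raise ValueError("streak_len == 0 iff streak_outcome is None")


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial outcome.

    Level 10 is hardest; an "upgrade" after two consecutive corrects means
    +1 level (harder), clamped to [1, 10]; two consecutive errors mean -1
    level (easier).  The streak resets after every level change.
    """
    correct = bool(correct)
    if state.streak_outcome == correct:
        # second consecutive identical outcome: move and reset
        delta = 1 if correct else -1
        new_level = min(MAX_LEVEL, max(MIN_LEVEL, state.level + delta))
        return StaircaseState(level=new_level)
    return replace(state, streak_outcome=correct, streak_len=1)
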