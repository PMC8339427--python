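"""Session scoring: Accuracy, Speed, ICA Index and ICA Score.

The three published scoring transforms are:

    Accuracy  = 100 * (number correct) / (number of main-block trials)
    Speed     = min(100, 100 * exp(-mean_correct_RT / 1025 + 0.341))
    ICA Index = (Speed/100) * (Accuracy/100) * 100

Mean correct RT averages reaction times of correctly answered, responded
main-block trials only.  The Speed transform maps latency to a 0-100 scale
and saturates at 100 for mean RTs at or below 1025 * 0.341 = 349.525 ms.

The classifier's output probability is presented on the same 0-100 scale:

    ICA Score = (1 - AI probability) * 100

with higher scores indicating the healthy direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .session import TrialRecord

__all__ = [
    "SpeedConstants",
    "SessionScore",
    "DEFAULT_SPEED_CONSTANTS",
    "accuracy",
    "speed_from_rt",
    "ica_index",
    "ica_score",
    "score_session",
    "scores_to_frame",
]


@dataclass(frozen=True)
class SpeedConstants:
    """Constants of the latency-to-speed transform."""

    rt_scale_ms: float = 1025.0
    offset: float = 0.341
    cap: float = 100.0

    def __post_init__(self) -> None:
        for name in ("rt_scale_ms", "offset", "cap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cap_rt_ms(self) -> float:
        """Largest mean correct RT that still maps to the speed cap."""
        return self.rt_scale_ms * self.offset


DEFAULT_SPEED_CONSTANTS = SpeedConstants()


@dataclass(frozen=True)
class SessionScore:
    """Summary scores for one session."""

    accuracy_pct: float
    mean_correct_rt_ms: float
    speed: float
    ica_index: float

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy_pct <= 100:
            raise ValueError("accuracy_pct must be in [0, 100]")
        if not self.mean_correct_rt_ms > 0:
            raise ValueError("mean_correct_rt_ms must be positive")
        if not 0 < self.speed <= 100:
            raise ValueError("speed must be in (0, 100]")
        if abs(self.ica_index - self.speed * self.accuracy_pct / 100.0) > 1e-9:
            raise ValueError("ica_index must equal speed * accuracy / 100")


def accuracy(records: Sequence[TrialRecord]) -> float:
    """Percent correct over main-phase trials; no-response trials count as errors."""
    main = [r for r in records if r.phase == "main"]
    if not main:
        raise ValueError("accuracy requires at least one main-phase record")
    return 100.0 * sum(1 for r in main if r.correct) / len(main)


def speed_from_rt(
    mean_correct_rt_ms: float, constants: SpeedConstants = DEFAULT_SPEED_CONSTANTS
) -> float:
    """Latency-to-speed transform; capped at 100, strictly decreasing above the cap."""
    if not mean_correct_rt_ms > 0:
        raise ValueError(f"mean correct RT must be positive, got {mean_correct_rt_ms}")
    return min(
        constants.cap,
        100.0 * math.exp(-mean_correct_rt_ms / constants.rt_scale_ms + constants.offset),
    )


def ica_index(speed: float, accuracy_pct: float) -> float:
    """Combined 0-100 index: product of normalized speed and accuracy."""
    if not 0 <= speed <= 100:
        raise ValueError(f"speed must be in [0, 100], got {speed}")
    if not 0 <= accuracy_pct <= 100:
        raise ValueError(f"accuracy_pct must be in [0, 100], got {accuracy_pct}")
    return speed * accuracy_pct / 100.0


def ica_score(ai_probability: float) -> float:
    """Convert a model impairment probability to the 0-100 score (higher = healthier)."""
    if not 0 <= ai_probability <= 1:
        raise ValueError(f"ai_probability must be in [0, 1], got {ai_probability}")
    return (1.0 - ai_probability) * 100.0


def score_session(
    records: Iterable[TrialRecord], constants: SpeedConstants = DEFAULT_SPEED_CONSTANTS
) -> SessionScore:
    """Score one session from its trial records.

    Practice trials never contribute.  Accuracy counts all main trials
    (timeouts as incorrect); mean correct RT averages correct responded
    trials only, so a session with no correct responses has undefined speed
    and raises ``ValueError``.
    """
    main = [r for r in records if r.phase == "main"]
    if not main:
        raise ValueError("score_session requires at least one main-phase record")
    acc = 100.0 * sum(1 for r in main if r.correct) / len(main)
    correct_rts = [r.rt_ms for r in main if r.correct and r.rt_ms is not None]
    if not correct_rts:
        raise ValueError("speed undefined: session has no correct responded trials")
    mean_rt = float(np.mean(correct_rts))
    spd = speed_from_rt(mean_rt, constants)
    return SessionScore(
        accuracy_pct=acc,
        mean_correct_rt_ms=mean_rt,
        speed=spd,
        ica_index=ica_index(spd, acc),
    )


def scores_to_frame(scores: dict[str, SessionScore]) -> pd.DataFrame:
    """Tabulate per-participant scores (one row per session)."""
    rows = [
        {
            "participant_id": pid,
            "accuracy_pct": s.accuracy_pct,
            "mean_correct_rt_ms": s.mean_correct_rt_ms,
            "speed": s.speed,
            "ica_index": s.ica_index,
        }
        for pid, s in scores.items()
    ]
    return pd.DataFrame(rows, columns=["participant_id", "accuracy_pct", "mean_correct_rt_ms", "speed", "ica_index"])
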