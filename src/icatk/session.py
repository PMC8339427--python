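"""Test-session construction: practice gate, main block, trial timeline, logs.

A session starts with a 10-item practice block (5 animal, 5 non-animal).
Participants scoring above chance (>50%, i.e. at least 6 of 10 correct)
proceed to the 100-trial main block (50 animal, 50 non-animal, randomized
order).  A failed first practice block triggers a retry with a fresh block;
a second failure restarts the flow.  The number of attempts used is retained
because it is itself informative about impairment.

Each trial presents the image for 100 ms, a 20 ms blank inter-stimulus
interval, a 250 ms dynamic mask, then a response window.  Reaction time is
measured from image onset.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "StimulusItem",
    "TrialRecord",
    "TimelineSpec",
    "SessionPlan",
    "GateDecision",
    "TrialEvent",
    "build_session_plan",
    "evaluate_practice_block",
    "expand_timeline",
    "write_session_log",
    "read_session_log",
    "MAIN_TRIALS_PER_CATEGORY",
    "PRACTICE_BLOCK_SIZE",
    "PRACTICE_PASS_THRESHOLD",
]

CATEGORIES = ("animal", "non_animal")
MAIN_TRIALS_PER_CATEGORY = 50
PRACTICE_BLOCK_SIZE = 10
PRACTICE_PER_CATEGORY = 5
#: minimum correct of 10 that counts as above chance (>50%)
PRACTICE_PASS_THRESHOLD = 6

LOG_COLUMNS = ("item_id", "category", "response", "correct", "rt_ms", "phase", "trial_index")


@dataclass(frozen=True)
class StimulusItem:
    """One image in the item bank.

    ``difficulty`` is a latent parameter used only by the response simulator;
    a real deployment would carry image metadata here instead.
    """

    item_id: str
    category: str
    difficulty: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation and the participant's response."""

    item_id: str
    category: str
    response: str  # "animal", "non_animal" or "none" (no response)
    correct: bool
    rt_ms: float | None
    phase: str  # "practice" or "main"
    trial_index: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        if self.response not in CATEGORIES + ("none",):
            raise ValueError(f"response must be one of {CATEGORIES + ('none',)}")
        if self.phase not in ("practice", "main"):
            raise ValueError("phase must be 'practice' or 'main'")
        if self.response == "none":
            if self.correct:
                raise ValueError("a no-response trial cannot be correct")
            if self.rt_ms is not None:
                raise ValueError("a no-response trial cannot carry a reaction time")
        else:
            if self.correct != (self.response == self.category):
                raise ValueError("correct flag inconsistent with response/category")
            if self.rt_ms is None or not self.rt_ms > 0:
                raise ValueError("rt_ms must be positive for responded trials")


@dataclass(frozen=True)
class TimelineSpec:
    """Per-trial event durations in milliseconds."""

    image_ms: float = 100.0
    isi_ms: float = 20.0
    mask_ms: float = 250.0
    response_window_ms: float = 3000.0

    def __post_init__(self) -> None:
        for name in ("image_ms", "isi_ms", "mask_ms", "response_window_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SessionPlan:
    """Planned stimulus order for one session."""

    practice_blocks: tuple[tuple[StimulusItem, ...], ...]
    main_trials: tuple[StimulusItem, ...]
    timing: TimelineSpec = field(default_factory=TimelineSpec)

    def __post_init__(self) -> None:
        if len(self.main_trials) != 2 * MAIN_TRIALS_PER_CATEGORY:
            raise ValueError(f"main block must hold {2 * MAIN_TRIALS_PER_CATEGORY} trials")
        n_animal = sum(1 for it in self.main_trials if it.category == "animal")
        if n_animal != MAIN_TRIALS_PER_CATEGORY:
            raise ValueError("main block must hold 50 animal and 50 non-animal items")
        ids = [it.item_id for it in self.main_trials]
        if len(set(ids)) != len(ids):
            raise ValueError("main block items must be distinct")
        main_ids = set(ids)
        for block in self.practice_blocks:
            if len(block) != PRACTICE_BLOCK_SIZE:
                raise ValueError(f"practice blocks must hold {PRACTICE_BLOCK_SIZE} items")
            if sum(1 for it in block if it.category == "animal") != PRACTICE_PER_CATEGORY:
                raise ValueError("practice blocks must hold 5 animal and 5 non-animal items")
            if any(it.item_id in main_ids for it in block):
                raise ValueError("practice items must be disjoint from the main block")


@dataclass(frozen=True)
class GateDecision:
    """Outcome of one practice block evaluation."""

    outcome: str  # "proceed", "retry" or "restart"
    attempts_used: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.outcome not in ("proceed", "retry", "restart"):
            raise ValueError("outcome must be proceed/retry/restart")
        if self.attempts_used < 1:
            raise ValueError("attempts_used must be >= 1")
        if self.outcome == "restart" and self.attempts_used < 2:
            raise ValueError("restart requires at least two attempts")


@dataclass(frozen=True)
class TrialEvent:
    name: str  # "image", "isi", "mask", "response_window"
    onset_ms: float
    duration_ms: float


def build_session_plan(
    bank: Sequence[StimulusItem],
    rng_seed: int,
    n_practice_blocks: int = 2,
    timing: TimelineSpec | None = None,
) -> SessionPlan:
    """Draw a randomized session plan from an item bank.

    The main block takes 50 animal and 50 non-animal items without
    replacement; practice blocks are drawn from the remaining items so they
    never re-use main-block images.
    """
    by_cat = {c: [it for it in bank if it.category == c] for c in CATEGORIES}
    need = MAIN_TRIALS_PER_CATEGORY + n_practice_blocks * PRACTICE_PER_CATEGORY
    for cat in CATEGORIES:
        if len(by_cat[cat]) < need:
            raise ValueError(
                f"item bank too small: need {need} '{cat}' items "
                f"({MAIN_TRIALS_PER_CATEGORY} main + "
                f"{n_practice_blocks * PRACTICE_PER_CATEGORY} practice), "
                f"got {len(by_cat[cat])}"
            )
    rng = np.random.default_rng(rng_seed)
    picks: dict[str, list[StimulusItem]] = {}
    for cat in CATEGORIES:
        idx = rng.permutation(len(by_cat[cat]))
        picks[cat] = [by_cat[cat][i] for i in idx]

    main = picks["animal"][:MAIN_TRIALS_PER_CATEGORY] + picks["non_animal"][:MAIN_TRIALS_PER_CATEGORY]
    main_order = rng.permutation(len(main))
    main_trials = tuple(main[i] for i in main_order)

    blocks = []
    for b in range(n_practice_blocks):
        lo = MAIN_TRIALS_PER_CATEGORY + b * PRACTICE_PER_CATEGORY
        hi = lo + PRACTICE_PER_CATEGORY
        block = picks["animal"][lo:hi] + picks["non_animal"][lo:hi]
        order = rng.permutation(len(block))
        blocks.append(tuple(block[i] for i in order))

    return SessionPlan(
        practice_blocks=tuple(blocks),
        main_trials=main_trials,
        timing=timing or TimelineSpec(),
    )


def evaluate_practice_block(
    records: Sequence[TrialRecord], attempts_so_far: int = 0
) -> GateDecision:
    """Apply the practice gate to one 10-trial block.

    At least 6 of 10 correct (above chance) proceeds to the main task.  A
    failed first attempt of a cycle yields ``retry`` (instructions re-shown,
    new block); a failed second attempt yields ``restart``.  ``attempts_so_far``
    accumulates across restarts, so the attempts-required count — itself a
    predictor of impairment — keeps growing.
    """
    if len(records) != PRACTICE_BLOCK_SIZE:
        raise ValueError(f"practice block must hold {PRACTICE_BLOCK_SIZE} records, got {len(records)}")
    if attempts_so_far < 0:
        raise ValueError("attempts_so_far must be >= 0")
    n_correct = sum(1 for r in records if r.correct)
    attempts_used = attempts_so_far + 1
    if n_correct >= PRACTICE_PASS_THRESHOLD:
        outcome = "proceed"
    elif attempts_so_far % 2 == 0:  # first failed attempt of this cycle
        outcome = "retry"
    else:
        outcome = "restart"
    return GateDecision(outcome=outcome, attempts_used=attempts_used, n_correct=n_correct)


def expand_timeline(plan: SessionPlan) -> list[list[TrialEvent]]:
    """Expand the main block into per-trial timed events with cumulative onsets.

    Each trial is image -> ISI -> mask -> response window; reaction time is
    referenced to image onset.
    """
    t = plan.timing
    events_per_trial: list[list[TrialEvent]] = []
    onset = 0.0
    for _item in plan.main_trials:
        trial_events = []
        for name, dur in (
            ("image", t.image_ms),
            ("isi", t.isi_ms),
            ("mask", t.mask_ms),
            ("response_window", t.response_window_ms),
        ):
            trial_events.append(TrialEvent(name=name, onset_ms=onset, duration_ms=dur))
            onset += dur
        events_per_trial.append(trial_events)
    return events_per_trial


def write_session_log(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trial records to CSV (one row per trial, header included)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.item_id,
                    r.category,
                    r.response,
                    int(r.correct),
                    "" if r.rt_ms is None else repr(float(r.rt_ms)),
                    r.phase,
                    r.trial_index,
                ]
            )


def read_session_log(path: str | Path) -> list[TrialRecord]:
    """Read a session log CSV, validating every row.

    Raises ``ValueError`` naming the offending line on malformed rows; an
    empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[TrialRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            logger.warning("session log %s is empty", path)
            return []
        if tuple(header) != LOG_COLUMNS:
            raise ValueError(f"{path}: line 1: expected header {LOG_COLUMNS}, got {tuple(header)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                if len(row) != len(LOG_COLUMNS):
                    raise ValueError(f"expected {len(LOG_COLUMNS)} fields, got {len(row)}")
                rt_raw = row[4].strip()
                rt = None if rt_raw == "" else float(rt_raw)
                if rt is not None and not (math.isfinite(rt) and rt > 0):
                    raise ValueError(f"rt_ms must be positive, got {rt}")
                records.append(
                    TrialRecord(
                        item_id=row[0],
                        category=row[1],
                        response=row[2],
                        correct=bool(int(row[3])),
                        rt_ms=rt,
                        phase=row[5],
                        trial_index=int(row[6]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records
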