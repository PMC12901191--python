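"""Rodent memory scoring from pre-scored behavioral event logs.

Two assays are covered. Novel object recognition (NOR): the
discrimination ratio is the time spent exploring the novel object over
total object exploration time in the test session. Y-maze spontaneous
alternation: the fraction of consecutive arm-entry triplets visiting
three distinct arms, over (entries - 2), expressed as a percentage.

Inputs are pre-scored logs (bout durations, arm-entry sequences); the
proximity and arm-entry scoring rules applied upstream (head within 2 cm
of the object; all four paws plus tail inside the arm) are ingestion
semantics, not recomputed here. Standard exclusion rules: animals with
< 7 s total object exploration in either NOR session, or fewer than 8
arm entries, are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NORSession",
    "ArmEntrySequence",
    "ExclusionRules",
    "discrimination_ratio",
    "spontaneous_alternation",
    "apply_exclusions",
    "group_summary",
]

ARMS = ("A", "B", "C")


@dataclass(frozen=True)
class NORSession:
    """Object-exploration bouts for one animal in one NOR phase."""

    animal: str
    group: str
    phase: str  # "training" | "test"
    bouts: tuple[tuple[str, float], ...]  # (object label, duration s)

    def __post_init__(self) -> None:
        if self.phase not in ("training", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")
        for obj, dur in self.bouts:
            if dur <= 0:
                raise ValueError("bout durations must be > 0")
        if self.phase == "test":
            labels = {obj for obj, _ in self.bouts}
            if self.bouts and not labels <= {"novel", "familiar"}:
                raise ValueError("test-phase objects must be 'novel' or 'familiar'")

    def total_exploration(self) -> float:
        return sum(d for _, d in self.bouts)

    def object_time(self, label: str) -> float:
        return sum(d for obj, d in self.bouts if obj == label)


@dataclass(frozen=True)
class ArmEntrySequence:
    """Ordered Y-maze arm entries for one animal.

    Re-entry into the currently occupied arm is not a new entry;
    consecutive duplicates are collapsed with a warning by default
    (``strict=True`` at construction rejects them instead).
    """

    animal: str
    group: str
    entries: tuple[str, ...]
    strict: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        bad = set(self.entries) - set(ARMS)
        if bad:
            raise ValueError(f"unknown arm symbols: {sorted(bad)}")
        collapsed = tuple(
            a for i, a in enumerate(self.entries)
            if i == 0 or a != self.entries[i - 1]
        )
        if collapsed != self.entries:
            if self.strict:
                raise ValueError("consecutive duplicate arm entries")
            warnings.warn(
                f"{self.animal}: collapsed consecutive duplicate arm entries",
                stacklevel=2,
            )
            object.__setattr__(self, "entries", collapsed)


def discrimination_ratio(session: NORSession) -> float:
    """Novel-object seconds / total object seconds, in [0, 1]."""
    if session.phase != "test":
        raise ValueError("discrimination ratio is defined on the test session")
    novel = session.object_time("novel")
    total = session.total_exploration()
    if total <= 0:
        raise ValueError(
            "zero total exploration: session should be excluded, not scored"
        )
    return novel / total


def spontaneous_alternation(seq: ArmEntrySequence) -> float:
    """Percent of length-3 entry windows visiting three distinct arms.

    100 * (alternation triplets) / (entries - 2).
    """
    e = seq.entries
    if len(e) < 3:
        raise ValueError("fewer than 3 entries: score undefined, exclude session")
    wins = sum(
        1 for i in range(len(e) - 2) if len({e[i], e[i + 1], e[i + 2]}) == 3
    )
    return 100.0 * wins / (len(e) - 2)


@dataclass(frozen=True)
class ExclusionRules:
    min_exploration_s: float = 7.0   # per NOR session (training and test)
    min_entries: int = 8             # Y-maze arm entries


def apply_exclusions(
    nor_sessions: Sequence[NORSession] = (),
    ymaze_sequences: Sequence[ArmEntrySequence] = (),
    rules: ExclusionRules = ExclusionRules(),
) -> tuple[list[NORSession], list[ArmEntrySequence], list[tuple[str, str]]]:
    """Deterministic exclusion filtering with per-animal reason codes.

    A NOR animal is excluded (both phases) if EITHER its training or its
    test session has total exploration below the threshold. Returns
    (kept NOR sessions, kept Y-maze sequences, [(animal, reason), ...]).
    """
    excluded: list[tuple[str, str]] = []

    by_animal: dict[str, list[NORSession]] = {}
    for s in nor_sessions:
        by_animal.setdefault(s.animal, []).append(s)
    bad_nor: set[str] = set()
    for animal, sessions in by_animal.items():
        for s in sessions:
            tot = s.total_exploration()
            if tot < rules.min_exploration_s:
                bad_nor.add(animal)
                excluded.append(
                    (animal,
                     f"exploration < {rules.min_exploration_s:g} s "
                     f"({s.phase}: {tot:.1f} s)")
                )
                break
    kept_nor = [s for s in nor_sessions if s.animal not in bad_nor]

    kept_ym: list[ArmEntrySequence] = []
    for q in ymaze_sequences:
        if len(q.entries) < rules.min_entries:
            excluded.append(
                (q.animal, f"arm entries < {rules.min_entries} ({len(q.entries)})")
            )
        else:
            kept_ym.append(q)
    return kept_nor, kept_ym, excluded


def group_summary(scores: Iterable[tuple[str, float]]) -> dict[str, dict[str, float]]:
    """Per-group mean, SD, SEM and n of (group, score) pairs."""
    by_group: dict[str, list[float]] = {}
    for group, score in scores:
        by_group.setdefault(group, []).append(score)
    out = {}
    for group, vals in sorted(by_group.items()):
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[group] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sd": sd,
            "sem": sd / np.sqrt(arr.size) if arr.size > 0 else float("nan"),
        }
    return out
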