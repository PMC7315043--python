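"""Score model for semi-hocket singing.

A semi-hocket score splits one melody over two parts that (almost) strictly
alternate notes, so the merged onset stream realizes a single sequence of
inter-onset intervals (IOIs).  The melody uses exactly three note-duration
classes — eighth, quarter and dotted-quarter notes — whose durations stand in
the exact ratio 1:2:3.  This module represents the score as the ordered
sequence of expected IOI classes and converts classes to nominal durations at
a given tempo.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import FormatError, InvalidInputError

__all__ = [
    "IOIClass",
    "Note",
    "ScoreSpec",
    "expected_class_sequence",
    "class_durations_at_tempo",
    "load_score",
    "toy_score",
]


class IOIClass(enum.IntEnum):
    """The three IOI duration classes, in eighth-note units (ratio 1:2:3)."""

    SHORT = 1  # eighth note
    MID = 2    # quarter note
    LONG = 3   # dotted quarter note

    @property
    def nominal_beats(self) -> Fraction:
        """Nominal duration in quarter-note beats (SHORT=1/2, MID=1, LONG=3/2)."""
        return Fraction(self.value, 2)

    @property
    def units(self) -> int:
        """Duration in eighth-note units; additive under note merging."""
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "IOIClass":
        key = str(label).strip().upper()
        aliases = {
            "S": cls.SHORT, "SHORT": cls.SHORT,
            "M": cls.MID, "MID": cls.MID,
            "L": cls.LONG, "LONG": cls.LONG,
        }
        try:
            return aliases[key]
        except KeyError:
            raise InvalidInputError(f"unknown IOI class label: {label!r}") from None

    @property
    def label(self) -> str:
        return {1: "S", 2: "M", 3: "L"}[self.value]


@dataclass(frozen=True)
class Note:
    """One note of the merged melody: who sings it and its duration class."""

    part: str
    ioi_class: IOIClass


@dataclass
class ScoreSpec:
    """Ordered notes of the merged semi-hocket melody.

    ``notes`` lists the melody in performance order; each note carries the
    part (singer) that performs it and its duration class.  The IOI between
    note *i* and note *i+1* inherits the duration class of note *i*, whoever
    sings either onset.
    """

    notes: list[Note]
    sections: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.notes:
            raise InvalidInputError("score must contain at least one note")
        for n in self.notes:
            if not isinstance(n.ioi_class, IOIClass):
                raise InvalidInputError(f"invalid IOI class in score: {n!r}")

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def combined_sequence(self) -> list[IOIClass]:
        """Duration classes of the merged melody, one entry per note."""
        return [n.ioi_class for n in self.notes]

    @property
    def parts(self) -> dict[str, list[IOIClass]]:
        out: dict[str, list[IOIClass]] = {}
        for n in self.notes:
            out.setdefault(n.part, []).append(n.ioi_class)
        return out

    @property
    def part_ids(self) -> list[str]:
        seen: list[str] = []
        for n in self.notes:
            if n.part not in seen:
                seen.append(n.part)
        return seen


def expected_class_sequence(
    score: ScoreSpec, n_repeats: int, drop_terminal: bool = True
) -> list[IOIClass]:
    """Expected IOI-class sequence for ``n_repeats`` passes through the score.

    The final note of the final repeat has no following onset, so by default
    the terminal IOI is dropped: a performance of N notes yields N-1 IOIs.
    """
    if not isinstance(n_repeats, int) or n_repeats < 1:
        raise InvalidInputError(f"n_repeats must be a positive integer, got {n_repeats!r}")
    seq = score.combined_sequence * n_repeats
    if drop_terminal:
        seq = seq[:-1]
    return seq


def class_durations_at_tempo(tempo_bpm: float) -> dict[IOIClass, float]:
    """Nominal class durations in seconds at ``tempo_bpm`` quarter notes/min.

    MID (quarter note) lasts 60/tempo seconds; SHORT and LONG scale by the
    exact 1:2:3 eighth-note ratio.
    """
    if not tempo_bpm > 0:
        raise InvalidInputError(f"tempo must be positive, got {tempo_bpm!r}")
    eighth = 30.0 / float(tempo_bpm)
    return {c: c.units * eighth for c in IOIClass}


def load_score(path: str | Path) -> ScoreSpec:
    """Load a score from a plain CSV or JSON file.

    CSV: columns ``part,index,class`` (header required); ``class`` is one of
    S/M/L (or SHORT/MID/LONG); rows are sorted by ``index`` (melody order).
    JSON: ``{"notes": [{"part": "A", "class": "S"}, ...]}`` in melody order.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        try:
            notes = [Note(str(n["part"]), IOIClass.from_label(n["class"])) for n in data["notes"]]
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path}: malformed score JSON ({exc})") from exc
        return ScoreSpec(notes)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"part", "index", "class"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: score CSV needs columns part,index,class")
        for i, row in enumerate(reader, start=2):
            try:
                rows.append((int(row["index"]), str(row["part"]), IOIClass.from_label(row["class"])))
            except (ValueError, InvalidInputError) as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from exc
    rows.sort(key=lambda r: r[0])
    return ScoreSpec([Note(part, cls) for _, part, cls in rows])


# 16-note toy fixture: two alternating parts with occasional same-part doubles
# (semi-hocket), class mix roughly matching a melody dominated by eighth notes
# (9 S : 5 M : 2 L per repeat).
_TOY_PATTERN: list[tuple[str, str]] = [
    ("A", "S"), ("B", "S"), ("A", "M"), ("B", "S"),
    ("A", "S"), ("B", "M"), ("A", "S"), ("A", "L"),
    ("B", "S"), ("A", "S"), ("B", "M"), ("A", "S"),
    ("B", "M"), ("B", "S"), ("A", "M"), ("B", "L"),
]


def toy_score() -> ScoreSpec:
    """The bundled 16-note two-part toy score used by the simulator."""
    return ScoreSpec([Note(p, IOIClass.from_label(c)) for p, c in _TOY_PATTERN])
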