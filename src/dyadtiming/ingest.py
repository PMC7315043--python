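"""Reading and merging performance data.

Each singer contributes a strictly increasing list of note-onset times
(seconds).  The dyad-level signal is the *relative* IOI series: both singers'
onsets merged into one stream, successive differences forming the IOIs,
whoever sang the delimiting onsets.  This module also reads the continuous
quality-annotation traces (1000 MIDI-valued samples per rater per trial),
the per-trial metadata/ratings table, and force-plate sensor CSVs, and flags
trials whose IOIs are too short to be valid eighth notes (near-simultaneous
singing, which the hocket task forbids).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError, InvalidInputError

__all__ = [
    "OnsetSeries",
    "RelativeIOISeries",
    "AnnotationSeries",
    "AgencyRating",
    "TrialMeta",
    "merge_onsets",
    "flag_simultaneous",
    "read_onsets_csv",
    "read_annotation_csv",
    "read_trials_csv",
    "mean_annotation",
]

CONDITIONS = ("movement", "non_movement")
EXPERT_GROUPS = ("expert", "non_expert")


@dataclass
class OnsetSeries:
    """One singer's onset times in seconds, strictly increasing."""

    singer_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise InvalidInputError("onset times must be a 1-D sequence")
        if self.times.size and not np.all(np.isfinite(self.times)):
            raise InvalidInputError("onset times must be finite")
        if self.times.size and self.times[0] < 0:
            raise InvalidInputError("onset times must be non-negative")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("onset times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RelativeIOISeries:
    """Merged two-singer onset stream and its successive IOIs."""

    times: np.ndarray            # merged onset times, strictly increasing
    sources: np.ndarray          # singer id per onset
    n_dropped_simultaneous: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sources = np.asarray(self.sources, dtype=object)
        if self.times.size != self.sources.size:
            raise InvalidInputError("times and sources must have equal length")
        if self.times.size < 2:
            raise InsufficientDataError("need at least 2 onsets to form an IOI")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("merged onset times must be strictly increasing")

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def start_times(self) -> np.ndarray:
        return self.times[:-1]

    @property
    def end_times(self) -> np.ndarray:
        return self.times[1:]

    @property
    def n_iois(self) -> int:
        return self.times.size - 1

    @property
    def total_span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class AnnotationSeries:
    """Continuous quality annotation: 1000 samples of integers in [0, 127]."""

    rater_id: str
    values: np.ndarray
    trial_duration_s: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.size != 1000:
            warnings.warn(
                f"annotation series for rater {self.rater_id!r} has "
                f"{self.values.size} samples; resampling to 1000",
                stacklevel=2,
            )
            x_old = np.linspace(0.0, 1.0, self.values.size)
            x_new = np.linspace(0.0, 1.0, 1000)
            self.values = np.interp(x_new, x_old, self.values.astype(float))
        self.values = np.rint(self.values).astype(int)
        if self.values.min() < 0 or self.values.max() > 127:
            raise InvalidInputError("annotation values must lie in [0, 127]")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class AgencyRating:
    """7-point joint-agency rating: 0 independent, 3 shared, 6 complete unity."""

    trial_id: str
    value: int

    def __post_init__(self) -> None:
        if not 0 <= int(self.value) <= 6:
            raise InvalidInputError(f"agency rating must be in [0, 6], got {self.value}")


@dataclass(frozen=True)
class TrialMeta:
    duo_id: str
    trial_index: int
    condition: str                 # movement | non_movement
    expert_group: str = "expert"   # third-person label, consumed as metadata

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidInputError(f"condition must be one of {CONDITIONS}")
        if self.expert_group not in EXPERT_GROUPS:
            raise InvalidInputError(f"expert_group must be one of {EXPERT_GROUPS}")


def merge_onsets(a: OnsetSeries, b: OnsetSeries) -> RelativeIOISeries:
    """Merge two singers' onsets into the dyad-level relative-IOI series.

    Onsets are sorted by time with a stable tie-break on singer id.  Exact
    ties across singers violate the hocket constraint and would produce
    zero-duration IOIs (which break log2 errors): the later duplicate is
    dropped with a warning and counted in ``n_dropped_simultaneous``.
    """
    times = np.concatenate([a.times, b.times])
    sources = np.array([a.singer_id] * len(a) + [b.singer_id] * len(b), dtype=object)
    order = np.lexsort((sources, times))
    times, sources = times[order], sources[order]
    keep = np.ones(times.size, dtype=bool)
    if times.size > 1:
        keep[1:] = np.diff(times) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} simultaneous onset(s) shared by both singers",
            stacklevel=2,
        )
    times, sources = times[keep], sources[keep]
    if times.size < 2:
        raise InsufficientDataError(
            f"need at least 2 onsets to form an IOI, got {times.size}"
        )
    return RelativeIOISeries(times, sources, n_dropped_simultaneous=n_dropped)


def flag_simultaneous(
    series: RelativeIOISeries,
    min_valid_ioi: float = 0.1,
    max_flagged_fraction: float = 0.10,
) -> tuple[np.ndarray, str, float]:
    """Flag IOIs too short to be valid eighth notes; return a trial verdict.

    ``min_valid_ioi`` defaults to 0.1 s; when a tempo estimate exists, pass
    50% of the nominal SHORT duration instead.  Exact-tie onsets dropped at
    merge time count toward the flagged fraction.  The verdict is "exclude"
    when the flagged fraction exceeds ``max_flagged_fraction``.
    """
    if not min_valid_ioi > 0:
        raise InvalidInputError("min_valid_ioi must be positive")
    flags = series.durations < min_valid_ioi
    n_bad = int(flags.sum()) + series.n_dropped_simultaneous
    n_tot = series.n_iois + series.n_dropped_simultaneous
    fraction = n_bad / n_tot
    verdict = "exclude" if fraction > max_flagged_fraction else "include"
    return flags, verdict, fraction


def read_onsets_csv(path: str | Path, singer_id: str | None = None) -> OnsetSeries:
    """Read one singer's onset list from a CSV of rows ``time_s[,label]``.

    A non-numeric first row is treated as a header and skipped.  Unsorted or
    duplicate times raise :class:`FormatError` naming the offending row.
    """
    path = Path(path)
    times: list[float] = []
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            try:
                t = float(row[0])
            except ValueError:
                if row_no == 1:  # header row
                    continue
                raise FormatError(f"{path}: row {row_no}: cannot parse time {row[0]!r}")
            if times and t <= times[-1]:
                kind = "duplicate" if t == times[-1] else "unsorted"
                raise FormatError(f"{path}: row {row_no}: {kind} onset time {t}")
            times.append(t)
    return OnsetSeries(singer_id or path.stem, np.asarray(times))


def read_annotation_csv(path: str | Path, rater_id: str | None = None) -> AnnotationSeries:
    """Read a 1000-sample annotation trace (one integer per row or one row of 1000)."""
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=1)
    return AnnotationSeries(rater_id or path.stem, values.ravel())


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-trial metadata/ratings table.

    Required columns: duo, trial, condition, expert_group, agency_a, agency_b.
    """
    df = pd.read_csv(path)
    required = {"duo", "trial", "condition", "expert_group", "agency_a", "agency_b"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("agency_a", "agency_b"):
        if ((df[col] < 0) | (df[col] > 6)).any():
            raise FormatError(f"{path}: {col} values must lie in [0, 6]")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"{path}: unknown condition values {sorted(bad)}")
    bad = set(df["expert_group"]) - set(EXPERT_GROUPS)
    if bad:
        raise FormatError(f"{path}: unknown expert_group values {sorted(bad)}")
    return df


def mean_annotation(
    a: AnnotationSeries, b: AnnotationSeries
) -> tuple[np.ndarray, float]:
    """Element-wise mean of two raters' traces and its per-trial scalar mean."""
    if a.values.size != b.values.size:
        raise InvalidInputError("annotation series lengths differ")
    trace = (a.values.astype(float) + b.values.astype(float)) / 2.0
    return trace, float(trace.mean())
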