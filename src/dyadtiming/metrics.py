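"""Per-trial timing-error markers derived from a tracker trace.

Three markers summarize a trial:

* **fluctuation** — micro-timing: RMSE of the log2(measured/predicted)
  residuals, computed per IOI class over non-collapse IOIs and averaged
  over the classes that occurred;
* **narration** — meso-timing: the percentage of IOIs whose assigned class
  matches the score-expected class, after aligning the observed stream to
  the expected sequence with a score follower that absorbs omissions;
* **collapse** — macro-timing: the percentage of IOIs flagged as breakdown
  gaps (more than 2 SD above the LONG-class belief).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError, UndefinedMetricError
from .score import IOIClass
from .tracker import TrackerTrace, detect_collapse  # noqa: F401  (re-exported)

__all__ = [
    "ErrorSummary",
    "fluctuation_rmse",
    "narration_matching",
    "align_narration",
    "detect_collapse",
    "collapse_percentage",
    "summarize_trace",
]


@dataclass
class ErrorSummary:
    """The three per-trial markers plus their bookkeeping counts."""

    fluctuation_rmse_per_class: dict[IOIClass, float]
    fluctuation_rmse_mean: float
    narration_matching_pct: float
    collapse_pct: float
    n_iois: int
    n_collapses: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.narration_matching_pct <= 100.0
        assert 0.0 <= self.collapse_pct <= 100.0
        assert self.n_collapses <= self.n_iois

    def to_dict(self) -> dict:
        d = {
            f"fluctuation_rmse_{c.label}": self.fluctuation_rmse_per_class.get(c, np.nan)
            for c in IOIClass
        }
        d.update(
            fluctuation_rmse=self.fluctuation_rmse_mean,
            narration_pct=self.narration_matching_pct,
            collapse_pct=self.collapse_pct,
            n_iois=self.n_iois,
            n_collapses=self.n_collapses,
        )
        return d


def fluctuation_rmse(trace: TrackerTrace) -> tuple[dict[IOIClass, float], float]:
    """Per-class RMSE of the log2 residuals over non-collapse IOIs, and the mean.

    Classes with no scored member are excluded from the mean with a warning.
    An all-collapse trace has no defined fluctuation.
    """
    if trace.n_iois == 0:
        raise UndefinedMetricError("empty trace has no fluctuation RMSE")
    valid = ~trace.is_collapse
    if not valid.any():
        raise UndefinedMetricError("all IOIs are collapses; fluctuation undefined")
    per_class: dict[IOIClass, float] = {}
    for c in IOIClass:
        errs = trace.log2_error[valid & (trace.assigned_class == int(c))]
        if errs.size:
            per_class[c] = float(np.sqrt(np.mean(errs**2)))
    missing = [c.label for c in IOIClass if c not in per_class]
    if missing:
        warnings.warn(
            f"IOI class(es) {missing} have no scored IOIs; excluded from the "
            "fluctuation mean",
            stacklevel=2,
        )
    return per_class, float(np.mean(list(per_class.values())))


def _merged_class(e1: IOIClass, e2: IOIClass) -> IOIClass:
    """Class nearest in log2 to the duration of two merged expected notes.

    A merged pair spans e1+e2 eighth-note units; sums above 3 have no exact
    class, so the nearest class (the one the tracker would assign to the
    merged duration) defines the omission hypothesis.
    """
    total = e1.units + e2.units
    return min(IOIClass, key=lambda c: abs(np.log2(total / c.units)))


def _hypothesis_score(
    observed: Sequence[IOIClass], expected: Sequence[IOIClass], i: int, j: int, lookahead: int
) -> int:
    """Best achievable match count over the next ``lookahead`` observed symbols.

    Evaluates the same match / substitution / omission-merge moves the
    follower itself uses, so clustered errors inside the window are scored
    correctly.  Branches only on mismatches, so the recursion stays small.
    """
    if lookahead == 0 or i >= len(observed) or j >= len(expected):
        return 0
    if observed[i] == expected[j]:
        return 1 + _hypothesis_score(observed, expected, i + 1, j + 1, lookahead - 1)
    best = _hypothesis_score(observed, expected, i + 1, j + 1, lookahead - 1)
    if j + 1 < len(expected) and observed[i] == _merged_class(expected[j], expected[j + 1]):
        best = max(
            best, _hypothesis_score(observed, expected, i + 1, j + 2, lookahead - 1)
        )
    return best


def align_narration(
    observed: Sequence[IOIClass],
    expected: Sequence[IOIClass],
    scored: Sequence[bool] | None = None,
    lookahead: int = 8,
    method: str = "greedy",
) -> tuple[int, int]:
    """Align observed class labels to the expected sequence; count matches.

    The default greedy follower keeps one pointer into the expected sequence.
    On a mismatch it weighs two hypotheses — an *omission* (the observed IOI
    merges the next two expected notes, legal only when the observed class
    duration equals their sum in eighth-note units) against a *substitution*
    — and takes the one whose next ``lookahead`` symbols realign better,
    preferring substitution on ties.  Entries with ``scored[i]`` False
    advance the pointer but count in neither numerator nor denominator
    (used for the unscored init-window prefix).

    ``method="edit"`` instead counts matched pairs in a minimal
    edit-distance (substitution/insertion/deletion) alignment.

    Returns ``(n_matched, n_scored)``.
    """
    observed = list(observed)
    expected = list(expected)
    if not expected:
        raise InvalidInputError("expected sequence must be non-empty")
    if scored is None:
        scored = [True] * len(observed)
    if len(scored) != len(observed):
        raise InvalidInputError("scored mask length must match observed length")

    if method == "edit":
        return _align_edit(observed, expected, scored)
    if method != "greedy":
        raise InvalidInputError(f"unknown alignment method {method!r}")
    return _follow_with_collapses(
        observed, expected, scored, [False] * len(observed), lookahead, method
    )


def _align_edit(
    observed: list[IOIClass], expected: list[IOIClass], scored: Sequence[bool]
) -> tuple[int, int]:
    """Matched pairs under a minimal unit-cost edit alignment (documented alternative)."""
    n, m = len(observed), len(expected)
    # dp cost and best matched count achieving it
    cost = np.zeros((n + 1, m + 1), dtype=int)
    match = np.zeros((n + 1, m + 1), dtype=int)
    cost[:, 0] = np.arange(n + 1)
    cost[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for jj in range(1, m + 1):
            hit = observed[i - 1] == expected[jj - 1]
            options = [
                (cost[i - 1, jj - 1] + (0 if hit else 1), match[i - 1, jj - 1] + (1 if hit else 0)),
                (cost[i - 1, jj] + 1, match[i - 1, jj]),
                (cost[i, jj - 1] + 1, match[i, jj - 1]),
            ]
            c = min(o[0] for o in options)
            cost[i, jj] = c
            match[i, jj] = max(o[1] for o in options if o[0] == c)
    n_scored = int(sum(scored))
    # Scale matches to the scored subset (prefix entries are unscored).
    n_matched = int(match[n, m]) - (len(observed) - n_scored)
    return max(n_matched, 0), n_scored


def narration_matching(
    trace_or_classes,
    expected: Sequence[IOIClass],
    prefix_classes: Sequence[IOIClass] | None = None,
    lookahead: int = 8,
    method: str = "greedy",
) -> float:
    """Percentage of scored IOIs whose class matches the score expectation.

    Accepts either a :class:`~dyadtiming.tracker.TrackerTrace` or a plain
    sequence of observed class labels.  For a trace, collapse records consume
    one expected position without being scored (the gap subsumes a scheduled
    note), and ``prefix_classes`` — typically the tracker's retrospective
    classification of the unscored init-window IOIs — anchors the follower at
    the start of the expected sequence.
    """
    if not list(expected):
        raise InvalidInputError("expected sequence must be non-empty")
    if isinstance(trace_or_classes, TrackerTrace):
        trace = trace_or_classes
        observed = [IOIClass(int(c)) for c in trace.assigned_class]
        scored = [not bool(col) for col in trace.is_collapse]
        collapse_unscored = list(trace.is_collapse)
    else:
        observed = [IOIClass(c) for c in trace_or_classes]
        scored = [True] * len(observed)
        collapse_unscored = [False] * len(observed)
    if prefix_classes:
        observed = [IOIClass(c) for c in prefix_classes] + observed
        scored = [False] * len(prefix_classes) + scored
        collapse_unscored = [False] * len(prefix_classes) + collapse_unscored

    matched, n_scored = _follow_with_collapses(
        observed, list(expected), scored, collapse_unscored, lookahead, method
    )
    if n_scored == 0:
        raise UndefinedMetricError("no scored IOIs; narration matching undefined")
    return 100.0 * matched / n_scored


def _follow_with_collapses(observed, expected, scored, is_collapse, lookahead, method):
    if method == "edit" and not any(is_collapse):
        return _align_edit(observed, expected, scored)
    matched = n_scored = 0
    j = 0
    for i, obs in enumerate(observed):
        if is_collapse[i]:
            j = min(j + 1, len(expected))  # gap subsumes one scheduled IOI
            continue
        if scored[i]:
            n_scored += 1
        if j >= len(expected):
            continue
        if obs == expected[j]:
            if scored[i]:
                matched += 1
            j += 1
            continue
        advance = 1
        if j + 1 < len(expected) and obs == _merged_class(expected[j], expected[j + 1]):
            merge_score = _hypothesis_score(observed, expected, i + 1, j + 2, lookahead)
            sub_score = _hypothesis_score(observed, expected, i + 1, j + 1, lookahead)
            if merge_score > sub_score:
                advance = 2
        j += advance
    return matched, n_scored


def collapse_percentage(trace: TrackerTrace) -> float:
    """Collapses as a percentage of all IOIs in the trace (collapses included)."""
    if trace.n_iois == 0:
        raise UndefinedMetricError("empty trace has no collapse percentage")
    return 100.0 * trace.n_collapses / trace.n_iois


def summarize_trace(
    trace: TrackerTrace,
    expected: Sequence[IOIClass],
    prefix_classes: Sequence[IOIClass] | None = None,
    method: str = "greedy",
) -> ErrorSummary:
    """Reduce a trace plus the expected class sequence to the three markers."""
    per_class, mean_rmse = fluctuation_rmse(trace)
    narration = narration_matching(
        trace, expected, prefix_classes=prefix_classes, method=method
    )
    return ErrorSummary(
        fluctuation_rmse_per_class=per_class,
        fluctuation_rmse_mean=mean_rmse,
        narration_matching_pct=narration,
        collapse_pct=collapse_percentage(trace),
        n_iois=trace.n_iois,
        n_collapses=trace.n_collapses,
    )
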