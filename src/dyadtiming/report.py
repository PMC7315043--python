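"""Per-trial tables, exclusion rules, and marker-rating correlations.

Trials are excluded when the participants broke the protocol: movement
detected in a non-movement trial, or so much (near-)simultaneous singing
that the IOIs cannot be valid eighth notes.  Over the included trials the
three timing markers are correlated with the subjective ratings using
Kendall's tau-b — ratings are Likert-style and heavily tied, so a
tie-corrected rank statistic is the appropriate choice.  Inferential
group comparisons (ANOVA and friends) are deliberately not implemented;
the tidy tables exported here are shaped for external statistics software.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "apply_exclusions",
    "kendall_tau",
    "correlate_markers",
    "correlation_table",
    "exclusion_table",
    "MARKER_COLUMNS",
    "RATING_COLUMNS",
]

MARKER_COLUMNS = {
    "fluctuation": "fluctuation_rmse",
    "narration": "narration_pct",
    "collapse": "collapse_pct",
}
RATING_COLUMNS = {"quality": "quality_mean", "agency": "agency_mean"}
SUBSETS = ("all", "movement", "non_movement")


def apply_exclusions(
    records: pd.DataFrame, simultaneity_limit: float = 0.10
) -> pd.DataFrame:
    """Flag protocol-violating trials; idempotent.

    Requires columns ``condition``, ``moving`` (bool) and
    ``simultaneous_fraction``.  A trial is excluded when movement was
    detected in a non-movement trial, or when the flagged-simultaneous IOI
    fraction exceeds ``simultaneity_limit``.
    """
    df = records.copy()
    required = {"condition", "moving", "simultaneous_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"records missing columns {sorted(missing)}")
    movement_violation = (df["condition"] == "non_movement") & df["moving"].astype(bool)
    simultaneous = df["simultaneous_fraction"] > simultaneity_limit
    reasons = []
    for mv, si in zip(movement_violation, simultaneous):
        r = []
        if si:
            r.append("simultaneous_singing")
        if mv:
            r.append("movement_in_still")
        reasons.append("+".join(r))
    df["excluded"] = movement_violation | simultaneous
    df["exclusion_reason"] = reasons
    return df


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie correction and a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 pairs for Kendall's tau")
    res = stats.kendalltau(x, y, variant="b", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _subset(records: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset not in SUBSETS:
        raise InvalidInputError(f"subset must be one of {SUBSETS}")
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    if subset != "all":
        df = df[df["condition"] == subset]
    return df


def correlate_markers(
    records: pd.DataFrame,
    marker: str,
    rating: str,
    subset: str = "all",
) -> tuple[float, float, int]:
    """Kendall tau-b between one timing marker and one mean rating.

    ``marker`` in {fluctuation, narration, collapse}; ``rating`` in
    {quality, agency}; ``subset`` in {all, movement, non_movement}.
    Excluded trials never enter the correlation.
    """
    try:
        mcol, rcol = MARKER_COLUMNS[marker], RATING_COLUMNS[rating]
    except KeyError as exc:
        raise InvalidInputError(f"unknown marker or rating: {exc}") from None
    df = _subset(records, subset).dropna(subset=[mcol, rcol])
    if len(df) < 3:
        raise InsufficientDataError(
            f"only {len(df)} included trials in subset {subset!r}; need >= 3"
        )
    tau, p = kendall_tau(df[mcol], df[rcol])
    return tau, p, len(df)


def correlation_table(records: pd.DataFrame) -> pd.DataFrame:
    """All marker x rating x subset Kendall correlations as a tidy table."""
    rows = []
    for rating in RATING_COLUMNS:
        for subset in SUBSETS:
            for marker in MARKER_COLUMNS:
                tau, p, n = correlate_markers(records, marker, rating, subset)
                rows.append(
                    {"rating": rating, "subset": subset, "marker": marker,
                     "tau": tau, "p": p, "n": n}
                )
    return pd.DataFrame(rows)


def exclusion_table(records: pd.DataFrame) -> pd.DataFrame:
    """The excluded trials with their reasons."""
    if "excluded" not in records.columns:
        raise InvalidInputError("run apply_exclusions first")
    cols = [c for c in ("duo", "trial", "condition", "exclusion_reason") if c in records.columns]
    return records.loc[records["excluded"].astype(bool), cols].reset_index(drop=True)
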