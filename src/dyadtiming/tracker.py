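"""Sequential Bayesian tracking of the three latent IOI-class durations.

The dyad is modelled as maintaining one latent belief per IOI class (SHORT,
MID, LONG) about that class's current duration.  Beliefs live in the
log2(duration) domain so that proportional timing errors are symmetric and
the natural residual is log2(measured / predicted).  Initial beliefs come
from k-means clustering (k=3) of the IOIs in the first 15 s of a
performance; thereafter each incoming IOI is assigned to the nearest class
belief, tested for a collapse gap, scored against the class's predicted
duration, and folded into that class's belief via a conjugate normal-mean
update over a trailing 15-s evidence window.  Because each class tracks its
own duration, the procedure follows gradual tempo changes without estimating
a global tempo.

The estimator :class:`IOIClassTracker` is scikit-learn styled: ``fit`` runs
the full sequential pass and exposes the per-IOI trace and final class
states as fitted attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .exceptions import InsufficientDataError, InvalidInputError
from .ingest import RelativeIOISeries
from .score import IOIClass

__all__ = [
    "TrackerConfig",
    "ClassState",
    "TrackerTrace",
    "IOIClassTracker",
    "init_classes",
    "classify_ioi",
    "update_class",
    "prediction_error",
    "detect_collapse",
    "track_performance",
]


@dataclass
class TrackerConfig:
    """Tunable parameters of the tracker (defaults follow the study design)."""

    n_classes: int = 3
    init_window_s: float = 15.0
    evidence_window_s: float = 15.0
    collapse_sd_mult: float = 2.0
    sd_floor: float = 0.02          # log2 units
    prior_strength: float = 5.0     # pseudo-count blending prior and window mean
    adapt: bool = True              # False freezes beliefs at their init values
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 3:
            raise InvalidInputError("the tracker models exactly 3 IOI classes")
        if not (self.init_window_s > 0 and self.evidence_window_s > 0):
            raise InvalidInputError("windows must be positive")
        if not self.collapse_sd_mult > 0:
            raise InvalidInputError("collapse_sd_mult must be positive")
        if not self.sd_floor > 0:
            raise InvalidInputError("sd_floor must be positive")
        if self.prior_strength < 0:
            raise InvalidInputError("prior_strength must be non-negative")


@dataclass
class ClassState:
    """Belief about one IOI class: mean and spread of log2(duration in s)."""

    label: IOIClass
    mu: float                       # mean of belief, log2 seconds
    sd: float                       # spread of belief, log2 units
    window: list[tuple[float, float]] = field(default_factory=list)  # (t, log2 dur)

    @property
    def predicted_duration(self) -> float:
        """Predicted IOI duration in seconds, 2**mu."""
        return float(2.0 ** self.mu)


@dataclass
class TrackerTrace:
    """Per-IOI record of the sequential pass (one row per scored IOI)."""

    start_time: np.ndarray
    duration: np.ndarray
    assigned_class: np.ndarray      # IOIClass values
    predicted_duration: np.ndarray
    log2_error: np.ndarray          # NaN for collapse records
    ms_error: np.ndarray            # NaN for collapse records
    is_collapse: np.ndarray
    snapshot_mu: np.ndarray         # (n, 3): class means after each step

    @property
    def n_iois(self) -> int:
        return self.start_time.size

    @property
    def n_collapses(self) -> int:
        return int(self.is_collapse.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start_time": self.start_time,
                "duration": self.duration,
                "assigned_class": [IOIClass(c).label for c in self.assigned_class],
                "predicted_duration": self.predicted_duration,
                "log2_error": self.log2_error,
                "ms_error": self.ms_error,
                "is_collapse": self.is_collapse.astype(int),
                "mu_short": self.snapshot_mu[:, 0],
                "mu_mid": self.snapshot_mu[:, 1],
                "mu_long": self.snapshot_mu[:, 2],
            }
        )


def detect_collapse(
    duration: float, state: ClassState, collapse_sd_mult: float = 2.0
) -> bool:
    """True iff the IOI is a collapse gap under its assigned class belief.

    A collapse is an abnormally *long* interval — a breakdown gap where
    onsets were expected — so the test is one-sided and only applies when
    the nearest belief is the LONG class: log2(duration) must exceed the
    LONG mean by strictly more than ``collapse_sd_mult`` standard deviations.
    Short outliers are handled upstream by the simultaneity flag.
    """
    if not duration > 0:
        raise InvalidInputError("duration must be positive")
    if state.label is not IOIClass.LONG:
        return False
    return np.log2(duration) > state.mu + collapse_sd_mult * state.sd


def classify_ioi(duration: float, states: Sequence[ClassState]) -> IOIClass:
    """Assign an IOI to the class whose belief mean is nearest in log2 space.

    Ties break deterministically toward the shorter class.
    """
    if not duration > 0:
        raise InvalidInputError("duration must be positive")
    x = np.log2(duration)
    ordered = sorted(states, key=lambda s: s.label)
    dists = [abs(x - s.mu) for s in ordered]
    return ordered[int(np.argmin(dists))].label


def prediction_error(duration: float, predicted: float) -> tuple[float, float]:
    """Proportional and absolute timing error of one IOI.

    Returns ``(log2(duration/predicted), 1000*(duration - predicted))`` —
    the symmetric log-ratio error and the same deviation in milliseconds.
    """
    if not (duration > 0 and predicted > 0):
        raise InvalidInputError("duration and prediction must be positive")
    return float(np.log2(duration / predicted)), float(1000.0 * (duration - predicted))


def update_class(
    state: ClassState,
    new_log2_duration: float,
    now: float,
    cfg: TrackerConfig,
) -> ClassState:
    """Fold one observation into a class belief (conjugate normal-mean update).

    Evidence entries older than ``evidence_window_s`` are evicted, the new
    value appended, and the posterior mean blends the prior mean with the
    window mean using ``prior_strength`` pseudo-counts:

        mu_post = (k * mu_prior + n * mean(window)) / (k + n)

    The spread is the window sample SD, floored at ``sd_floor``.
    """
    window = [
        (t, x) for t, x in state.window if t >= now - cfg.evidence_window_s
    ]
    window.append((now, float(new_log2_duration)))
    values = np.array([x for _, x in window])
    n = values.size
    k = cfg.prior_strength
    mu = (k * state.mu + n * values.mean()) / (k + n)
    sd = float(values.std(ddof=1)) if n >= 2 else 0.0
    return ClassState(state.label, float(mu), max(sd, cfg.sd_floor), window)


def _ratio_fallback_states(log2_durations: np.ndarray, cfg: TrackerConfig) -> list[ClassState]:
    """Degenerate-clustering fallback: 1:2:3 ratios anchored at the median IOI."""
    median = float(np.median(2.0 ** log2_durations))
    centers = np.log2(median / 2.0 * np.array([1.0, 2.0, 3.0]))
    return [
        ClassState(label, float(c), cfg.sd_floor)
        for label, c in zip(IOIClass, centers)
    ]


def init_classes(
    series: RelativeIOISeries, cfg: TrackerConfig | None = None
) -> list[ClassState]:
    """Initialize the three class beliefs by k-means on the first 15 s.

    k-means (k=3, fixed seed) runs on the log2 durations of all IOIs that
    complete within ``init_window_s`` of the first onset.  Cluster centers
    map to SHORT/MID/LONG by ascending mean; each spread is the cluster
    sample SD floored at ``sd_floor``.  Degenerate clusterings (fewer than 3
    distinct values, or an empty cluster) fall back to exact 1:2:3 ratio
    centers anchored at the median init-window IOI, with a warning.
    """
    cfg = cfg or TrackerConfig()
    t0 = series.times[0]
    mask = series.end_times <= t0 + cfg.init_window_s
    durations = series.durations[mask]
    if durations.size < cfg.n_classes:
        raise InsufficientDataError(
            f"need at least {cfg.n_classes} IOIs in the first "
            f"{cfg.init_window_s:g} s, got {durations.size}"
        )
    x = np.log2(durations)
    if np.unique(x).size < cfg.n_classes:
        warnings.warn(
            "degenerate init window (fewer than 3 distinct IOI durations); "
            "falling back to 1:2:3 ratio centers at the median IOI",
            stacklevel=2,
        )
        return _ratio_fallback_states(x, cfg)
    km = KMeans(n_clusters=cfg.n_classes, n_init=10, random_state=cfg.rng_seed)
    labels = km.fit_predict(x.reshape(-1, 1))
    states: list[ClassState] = []
    order = np.argsort(km.cluster_centers_.ravel())
    for label, cluster in zip(IOIClass, order):
        members = x[labels == cluster]
        if members.size == 0:
            warnings.warn(
                "empty k-means cluster in init window; falling back to "
                "1:2:3 ratio centers at the median IOI",
                stacklevel=2,
            )
            return _ratio_fallback_states(x, cfg)
        sd = float(members.std(ddof=1)) if members.size >= 2 else 0.0
        states.append(
            ClassState(label, float(members.mean()), max(sd, cfg.sd_floor))
        )
    return states


def _enforce_order(states: list[ClassState]) -> list[ClassState]:
    """Keep class means strictly ordered SHORT < MID < LONG; re-sort on violation."""
    mus = [s.mu for s in sorted(states, key=lambda s: s.label)]
    if all(a < b for a, b in zip(mus, mus[1:])):
        return states
    warnings.warn("class means lost their ordering; re-sorting labels", stacklevel=2)
    by_mu = sorted(states, key=lambda s: s.mu)
    return [replace(s, label=label) for label, s in zip(IOIClass, by_mu)]


class IOIClassTracker(BaseEstimator):
    """Sequential Bayesian tracker of the three IOI-class duration beliefs.

    Parameters mirror :class:`TrackerConfig`.  ``fit(X)`` accepts a
    :class:`~dyadtiming.ingest.RelativeIOISeries` (or a 1-D array of merged
    onset times) and runs the full sequential pass.

    Attributes (after ``fit``)
    --------------------------
    init_states_ : list of ClassState
        Beliefs produced by the k-means initialization.
    class_states_ : list of ClassState
        Beliefs after the final update.
    trace_ : TrackerTrace
        Per-IOI record of assignment, prediction, error and collapse flag
        for every IOI after the init window.
    init_assigned_ : list of IOIClass
        Retrospective classification of the (unscored) init-window IOIs
        under the initial beliefs, used to anchor score following.
    """

    def __init__(
        self,
        init_window_s: float = 15.0,
        evidence_window_s: float = 15.0,
        collapse_sd_mult: float = 2.0,
        sd_floor: float = 0.02,
        prior_strength: float = 5.0,
        adapt: bool = True,
        random_state: int = 0,
    ) -> None:
        self.init_window_s = init_window_s
        self.evidence_window_s = evidence_window_s
        self.collapse_sd_mult = collapse_sd_mult
        self.sd_floor = sd_floor
        self.prior_strength = prior_strength
        self.adapt = adapt
        self.random_state = random_state

    def _config(self) -> TrackerConfig:
        return TrackerConfig(
            init_window_s=self.init_window_s,
            evidence_window_s=self.evidence_window_s,
            collapse_sd_mult=self.collapse_sd_mult,
            sd_floor=self.sd_floor,
            prior_strength=self.prior_strength,
            adapt=self.adapt,
            rng_seed=self.random_state,
        )

    @staticmethod
    def _as_series(X) -> RelativeIOISeries:
        if isinstance(X, RelativeIOISeries):
            return X
        times = np.asarray(X, dtype=float).ravel()
        return RelativeIOISeries(times, np.array(["?"] * times.size, dtype=object))

    def fit(self, X, y=None) -> "IOIClassTracker":
        """Run k-means initialization plus the full sequential pass over X."""
        series = self._as_series(X)
        cfg = self._config()
        states = init_classes(series, cfg)
        self.init_states_ = [replace(s, window=list(s.window)) for s in states]

        t0 = series.times[0]
        init_mask = series.end_times <= t0 + cfg.init_window_s
        self.init_assigned_ = [
            classify_ioi(d, self.init_states_) for d in series.durations[init_mask]
        ]

        scored = ~init_mask
        starts = series.start_times[scored]
        ends = series.end_times[scored]
        durations = series.durations[scored]

        n = durations.size
        rec_assigned = np.empty(n, dtype=int)
        rec_pred = np.empty(n)
        rec_log2 = np.full(n, np.nan)
        rec_ms = np.full(n, np.nan)
        rec_collapse = np.zeros(n, dtype=bool)
        snapshots = np.empty((n, 3))

        by_label = {s.label: s for s in states}
        for i in range(n):
            d = durations[i]
            label = classify_ioi(d, list(by_label.values()))
            state = by_label[label]
            rec_assigned[i] = int(label)
            rec_pred[i] = state.predicted_duration
            if detect_collapse(d, state, cfg.collapse_sd_mult):
                # Gap: record it, keep it out of every evidence window.
                rec_collapse[i] = True
            else:
                rec_log2[i], rec_ms[i] = prediction_error(d, state.predicted_duration)
                if cfg.adapt:
                    by_label[label] = update_class(state, np.log2(d), ends[i], cfg)
                    ordered = _enforce_order(list(by_label.values()))
                    by_label = {s.label: s for s in ordered}
            snapshots[i] = [by_label[c].mu for c in IOIClass]

        self.class_states_ = sorted(by_label.values(), key=lambda s: s.label)
        self.trace_ = TrackerTrace(
            start_time=starts,
            duration=durations,
            assigned_class=rec_assigned,
            predicted_duration=rec_pred,
            log2_error=rec_log2,
            ms_error=rec_ms,
            is_collapse=rec_collapse,
            snapshot_mu=snapshots,
        )
        self.n_iois_ = n
        return self

    def transform(self, X=None) -> TrackerTrace:
        """Return the fitted per-IOI trace (``fit`` must have been called)."""
        if not hasattr(self, "trace_"):
            raise InvalidInputError("tracker is not fitted; call fit(X) first")
        return self.trace_


def track_performance(
    series: RelativeIOISeries, config: TrackerConfig | None = None, **overrides
) -> TrackerTrace:
    """Functional wrapper: run :class:`IOIClassTracker` and return its trace."""
    cfg = config or TrackerConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    tracker = IOIClassTracker(
        init_window_s=cfg.init_window_s,
        evidence_window_s=cfg.evidence_window_s,
        collapse_sd_mult=cfg.collapse_sd_mult,
        sd_floor=cfg.sd_floor,
        prior_strength=cfg.prior_strength,
        adapt=cfg.adapt,
        random_state=cfg.rng_seed,
    )
    return tracker.fit(series).trace_
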