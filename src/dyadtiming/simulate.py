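"""Synthetic dyad-performance generator with known ground truth.

The study's participant data is not bundled, so this module emulates it:
two interleaved onset streams realizing the three IOI classes (ratio 1:2:3)
with tempo drift, multiplicative log2 timing jitter, omission and
substitution errors, multi-second breakdown gaps, periodic vs noise-only
force-plate traces, and slider-style quality annotations.  Every injected
event is recorded in a :class:`SimTruth` so parameter recovery and
detection completeness can be tested exactly.

Defaults describe a plausible 2-minute trial: 19 repeats of the 16-note toy
score at 120 bpm (303 IOIs, close to the ~319 theoretical IOIs of a 2-min
performance), mild jitter and sparse errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .exceptions import InvalidInputError
from .ingest import AnnotationSeries, OnsetSeries
from .movement import SensorSeries
from .score import IOIClass, ScoreSpec, class_durations_at_tempo, expected_class_sequence, toy_score

__all__ = [
    "SimConfig",
    "SimTruth",
    "TrialData",
    "render_performance",
    "render_sensor",
    "render_annotation",
    "simulate_trial",
    "render_cohort",
]


@dataclass
class SimConfig:
    """Generative parameters of one simulated trial."""

    score: ScoreSpec | None = None          # None → bundled toy score
    n_repeats: int = 19
    tempo_bpm: float = 120.0
    tempo_drift: tuple = ("none",)          # ("none",) | ("linear", bpm_per_min) | ("random_walk", sigma_bpm)
    jitter_sigma_log2: float = 0.05
    p_omit: float = 0.02
    p_substitute: float = 0.03
    p_collapse: float = 0.01
    n_collapse_events: int | None = None    # exact gap count overriding p_collapse
    gap_range_s: tuple[float, float] = (2.0, 8.0)
    collapse_settle_s: float = 20.0         # gaps only after this much performance
    sensor_fs: float = 20.0
    sensor_duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_omit", "p_substitute", "p_collapse"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1], got {p}")
        if self.jitter_sigma_log2 < 0:
            raise InvalidInputError("jitter_sigma_log2 must be non-negative")
        if not (0 < self.gap_range_s[0] <= self.gap_range_s[1]):
            raise InvalidInputError("gap_range_s must be positive and ordered")
        if self.n_repeats < 1:
            raise InvalidInputError("n_repeats must be >= 1")
        if not self.tempo_bpm > 0:
            raise InvalidInputError("tempo_bpm must be positive")
        if self.tempo_drift[0] not in ("none", "linear", "random_walk"):
            raise InvalidInputError(f"unknown tempo_drift kind {self.tempo_drift[0]!r}")

    @property
    def resolved_score(self) -> ScoreSpec:
        return self.score if self.score is not None else toy_score()


@dataclass
class SimTruth:
    """Ground truth of a rendered performance."""

    expected_classes: list[IOIClass]        # scheduled IOI classes (terminal dropped)
    performed_classes: list[IOIClass]       # after substitutions
    events: list[dict]                      # {"kind","ioi_index",...} per injection
    tempo_track: np.ndarray                 # bpm at each scheduled IOI
    n_scheduled_iois: int

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e["kind"] == kind)

    @property
    def n_omissions(self) -> int:
        return self.count("omission")

    @property
    def n_substitutions(self) -> int:
        return self.count("substitution")

    @property
    def n_collapses(self) -> int:
        return self.count("collapse")

    def to_json(self) -> str:
        return json.dumps(
            {
                "expected_classes": [c.label for c in self.expected_classes],
                "performed_classes": [c.label for c in self.performed_classes],
                "events": self.events,
                "tempo_track": [round(float(t), 9) for t in self.tempo_track],
                "n_scheduled_iois": self.n_scheduled_iois,
            },
            sort_keys=True,
        )


def render_performance(cfg: SimConfig) -> tuple[OnsetSeries, OnsetSeries, SimTruth]:
    """Render one dyad performance: two onset streams plus ground truth.

    The expected class sequence is walked note by note; each IOI draws its
    duration from the current tempo's nominal class duration times
    ``2**N(0, jitter^2)``.  Substitutions swap the class for a uniformly
    different one, omissions delete an interior onset (merging two IOIs),
    and collapse gaps lengthen an IOI by U(gap_range) seconds.  Onsets are
    attributed to singers by the score's part column.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    score = cfg.resolved_score
    notes = score.notes * cfg.n_repeats
    expected = expected_class_sequence(score, cfg.n_repeats, drop_terminal=True)
    n = len(expected)

    # Substitutions.
    performed = list(expected)
    events: list[dict] = []
    sub_mask = rng.random(n) < cfg.p_substitute
    for i in np.flatnonzero(sub_mask):
        choices = [c for c in IOIClass if c != expected[i]]
        performed[i] = choices[rng.integers(len(choices))]
        events.append(
            {"kind": "substitution", "ioi_index": int(i),
             "from": expected[i].label, "to": performed[i].label}
        )

    # Tempo track over scheduled IOIs.
    kind = cfg.tempo_drift[0]
    tempos = np.empty(n)
    if kind == "random_walk":
        sigma = float(cfg.tempo_drift[1])
        tempos = np.clip(cfg.tempo_bpm + np.cumsum(rng.normal(0, sigma, n)), 20.0, None)
    elif kind == "linear":
        rate = float(cfg.tempo_drift[1])
        t_nominal = 0.0
        for i in range(n):
            tempos[i] = cfg.tempo_bpm + rate * (t_nominal / 60.0)
            t_nominal += performed[i].units * 30.0 / tempos[i]
    else:
        tempos[:] = cfg.tempo_bpm

    # Jittered durations.
    jitter = rng.normal(0.0, cfg.jitter_sigma_log2, size=n) if cfg.jitter_sigma_log2 else np.zeros(n)
    durations = np.array(
        [performed[i].units * 30.0 / tempos[i] for i in range(n)]
    ) * 2.0 ** jitter

    # Collapse gaps: only at IOIs starting after the settle period so every
    # gap lands in the tracker's scored region.
    nominal_starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    eligible = np.flatnonzero(nominal_starts >= cfg.collapse_settle_s)
    if cfg.n_collapse_events is not None:
        if cfg.n_collapse_events > eligible.size:
            raise InvalidInputError("n_collapse_events exceeds eligible IOIs")
        gap_idx = np.sort(rng.choice(eligible, size=cfg.n_collapse_events, replace=False))
    else:
        gap_idx = eligible[rng.random(eligible.size) < cfg.p_collapse]
    for i in gap_idx:
        gap = rng.uniform(*cfg.gap_range_s)
        durations[i] += gap
        events.append({"kind": "collapse", "ioi_index": int(i), "gap_s": float(gap)})

    # Omissions: delete interior onsets (never the first or last, never two
    # adjacent, never inside a collapse gap's delimiting pair).
    omit_candidates = rng.random(max(n - 1, 0)) < cfg.p_omit  # onset k = 1..n-1
    gap_onsets = set(int(i) for i in gap_idx) | set(int(i) + 1 for i in gap_idx)
    omitted: list[int] = []
    for k in np.flatnonzero(omit_candidates):
        onset = int(k) + 1  # onsets 1..n-1 are interior (onset n is the last note's)
        if onset in gap_onsets:
            continue
        if omitted and onset == omitted[-1] + 1:
            continue
        omitted.append(onset)
        events.append({"kind": "omission", "ioi_index": onset - 1,
                       "merged_classes": [expected[onset - 1].label, expected[onset].label]})

    onset_times = np.concatenate([[0.0], np.cumsum(durations)])  # one per note
    keep = np.ones(onset_times.size, dtype=bool)
    keep[omitted] = False

    parts = score.part_ids
    if len(parts) != 2:
        raise InvalidInputError("render_performance needs a two-part score")
    note_parts = np.array([nt.part for nt in notes], dtype=object)
    times_a = onset_times[keep & (note_parts == parts[0])]
    times_b = onset_times[keep & (note_parts == parts[1])]

    events.sort(key=lambda e: (e["ioi_index"], e["kind"]))
    truth = SimTruth(
        expected_classes=expected,
        performed_classes=performed,
        events=events,
        tempo_track=tempos,
        n_scheduled_iois=n,
    )
    return (
        OnsetSeries(parts[0], times_a),
        OnsetSeries(parts[1], times_b),
        truth,
    )


def render_sensor(
    moving: bool,
    sway_freq: float = 1.5,
    amplitude: float = 40.0,
    fs: float = 20.0,
    duration_s: float = 60.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    plate_id: str = "plate",
) -> SensorSeries:
    """Synthesize one force plate: sinusoidal sway plus noise, or noise only.

    Moving plates carry a sinusoid at ``sway_freq`` (plus a small second
    harmonic) on the channel gains (1.0, 0.7, 0.5, 0.3); all channels are
    quantized to integers around the MIDI midpoint 64 and clipped to
    [0, 127].
    """
    if moving and not (0.25 <= sway_freq <= 5.0):
        raise InvalidInputError("sway_freq must lie in [0.25, 5] Hz when moving")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    if moving:
        sway = amplitude * np.sin(2 * np.pi * sway_freq * t)
        sway = sway + 0.15 * amplitude * np.sin(2 * np.pi * 2 * sway_freq * t)
    else:
        sway = np.zeros(n)
    gains = np.array([1.0, 0.7, 0.5, 0.3])
    channels = 64.0 + sway[:, None] * gains[None, :] + rng.normal(0, noise_sd, (n, 4))
    channels = np.clip(np.rint(channels), 0, 127)
    return SensorSeries(plate_id, channels, fs)


def render_annotation(
    error_density_track: np.ndarray,
    seed: int = 0,
    ceiling: float = 115.0,
    slope: float = 40.0,
    noise_sd: float = 5.0,
) -> tuple[AnnotationSeries, AnnotationSeries]:
    """Two raters' slider traces: quality decreasing affinely in error density.

    The density track (any length, non-negative) is resampled to the
    1000-sample slider format; each rater's trace is
    ``ceiling - slope * density + N(0, noise_sd)``, clipped to [0, 127],
    with the first sample forced to the slider's neutral start value 64.
    """
    density = np.asarray(error_density_track, dtype=float).ravel()
    if density.size == 0 or (density < 0).any():
        raise InvalidInputError("error density track must be non-empty and non-negative")
    x_old = np.linspace(0, 1, density.size) if density.size > 1 else np.array([0.0])
    x_new = np.linspace(0, 1, 1000)
    density = np.interp(x_new, x_old, density)
    rng = np.random.default_rng(seed)
    out = []
    for rater in ("a", "b"):
        q = ceiling - slope * density + rng.normal(0, noise_sd, 1000)
        q = np.clip(np.rint(q), 0, 127)
        q[0] = 64
        out.append(AnnotationSeries(rater, q))
    return out[0], out[1]


@dataclass
class TrialData:
    """Everything one simulated trial produces."""

    onsets_a: OnsetSeries
    onsets_b: OnsetSeries
    truth: SimTruth
    sensor_a: SensorSeries
    sensor_b: SensorSeries
    annotation_a: AnnotationSeries
    annotation_b: AnnotationSeries
    agency_a: int
    agency_b: int
    condition: str


def _error_density_track(truth: SimTruth, cfg: SimConfig, bin_s: float = 2.0) -> np.ndarray:
    """Local injected-error density over nominal performance time (for annotation)."""
    nominal = np.array(
        [c.units * 30.0 / t for c, t in zip(truth.performed_classes, truth.tempo_track)]
    )
    starts = np.concatenate([[0.0], np.cumsum(nominal)[:-1]])
    total = float(nominal.sum())
    n_bins = max(int(np.ceil(total / bin_s)), 1)
    density = np.full(n_bins, cfg.jitter_sigma_log2 * 4.0)
    weight = {"substitution": 0.5, "omission": 0.5, "collapse": 1.0}
    for e in truth.events:
        b = min(int(starts[e["ioi_index"]] // bin_s), n_bins - 1)
        density[b] += weight[e["kind"]]
    return density


def simulate_trial(
    cfg: SimConfig, condition: str = "movement", moving: bool | None = None
) -> TrialData:
    """Render a full trial: onsets, sensors, annotations and agency ratings.

    ``moving`` defaults to the instructed condition; pass it explicitly to
    emulate instruction violations (movement during a non-movement trial).
    Quality annotations decrease with the injected error density and agency
    ratings decrease with the overall injected error rate, giving the
    simulated cohort the monotone marker-rating links used in validation.
    """
    if moving is None:
        moving = condition == "movement"
    onsets_a, onsets_b, truth = render_performance(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    sensor_a = render_sensor(
        moving, sway_freq=float(rng.uniform(0.5, 3.0)), fs=cfg.sensor_fs,
        duration_s=cfg.sensor_duration_s, seed=int(rng.integers(2**31)), plate_id="A",
    )
    sensor_b = render_sensor(
        moving, sway_freq=float(rng.uniform(0.5, 3.0)), fs=cfg.sensor_fs,
        duration_s=cfg.sensor_duration_s, seed=int(rng.integers(2**31)), plate_id="B",
    )
    density = _error_density_track(truth, cfg)
    ann_a, ann_b = render_annotation(density, seed=int(rng.integers(2**31)))
    err_rate = len(truth.events) / truth.n_scheduled_iois + cfg.jitter_sigma_log2
    agency = []
    for _ in range(2):
        a = int(np.clip(round(5.0 - 12.0 * err_rate + rng.normal(0, 0.5)), 0, 6))
        agency.append(a)
    return TrialData(
        onsets_a, onsets_b, truth, sensor_a, sensor_b, ann_a, ann_b,
        agency[0], agency[1], condition,
    )


def render_cohort(
    n_duos: int = 10,
    trials_per_duo: int = 4,
    seed: int = 0,
    base: SimConfig | None = None,
    p_movement_violation: float = 0.0,
) -> list[tuple[dict, TrialData]]:
    """Simulate a cohort of duos spanning a range of skill levels.

    Duo skill s in [0, 1] scales jitter and error probabilities; conditions
    alternate movement / non_movement within each duo.  With
    ``p_movement_violation`` a non-movement trial is rendered moving (for
    exclusion-rule testing).  Returns ``(meta_dict, TrialData)`` pairs.
    """
    base = base or SimConfig()
    rng = np.random.default_rng(seed)
    skills = np.linspace(0.0, 1.0, n_duos)
    out: list[tuple[dict, TrialData]] = []
    for d, s in enumerate(skills):
        for t in range(trials_per_duo):
            condition = "movement" if t % 2 == 0 else "non_movement"
            moving = condition == "movement"
            if condition == "non_movement" and rng.random() < p_movement_violation:
                moving = True
            cfg = replace(
                base,
                jitter_sigma_log2=0.02 + 0.08 * s,
                p_substitute=0.01 + 0.15 * s,
                p_omit=0.01 + 0.04 * s,
                p_collapse=0.005 + 0.02 * s,
                n_collapse_events=None,
                seed=int(rng.integers(2**31)),
            )
            meta = {
                "duo": f"duo{d:02d}",
                "trial": t,
                "condition": condition,
                "expert_group": "expert" if s < 0.5 else "non_expert",
                "skill": float(s),
            }
            out.append((meta, simulate_trial(cfg, condition, moving=moving)))
    return out
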