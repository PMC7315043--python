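"""End-to-end analysis convenience: simulated or ingested trial → marker row.

Glues the modules together the way the CLI does: merge onsets, flag
simultaneity, run the Bayesian tracker, reduce to the three markers, assess
movement, and average the two raters' annotations into per-trial scalars.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import flag_simultaneous, mean_annotation, merge_onsets
from .metrics import summarize_trace
from .movement import WaveletMovementClassifier
from .score import expected_class_sequence
from .simulate import SimConfig, TrialData
from .tracker import IOIClassTracker, TrackerConfig

__all__ = ["analyze_trial", "analyze_cohort"]


def analyze_trial(
    trial: TrialData,
    cfg: SimConfig,
    tracker_config: TrackerConfig | None = None,
    movement_classifier: WaveletMovementClassifier | None = None,
    min_valid_ioi: float | None = None,
) -> dict:
    """Compute every per-trial quantity for one (simulated) trial."""
    tcfg = tracker_config or TrackerConfig()
    clf = movement_classifier or WaveletMovementClassifier().fit()
    series = merge_onsets(trial.onsets_a, trial.onsets_b)
    if min_valid_ioi is None:
        # 50% of the tempo-nominal SHORT duration
        min_valid_ioi = 0.5 * (30.0 / cfg.tempo_bpm)
    _, verdict, frac = flag_simultaneous(series, min_valid_ioi)

    tracker = IOIClassTracker(
        init_window_s=tcfg.init_window_s,
        evidence_window_s=tcfg.evidence_window_s,
        collapse_sd_mult=tcfg.collapse_sd_mult,
        sd_floor=tcfg.sd_floor,
        prior_strength=tcfg.prior_strength,
        adapt=tcfg.adapt,
        random_state=tcfg.rng_seed,
    ).fit(series)
    expected = expected_class_sequence(cfg.resolved_score, cfg.n_repeats)
    summary = summarize_trace(tracker.trace_, expected, prefix_classes=tracker.init_assigned_)

    movement = clf.summarize((trial.sensor_a, trial.sensor_b))
    _, quality_mean = mean_annotation(trial.annotation_a, trial.annotation_b)

    row = summary.to_dict()
    row.update(
        simultaneous_fraction=frac,
        simultaneity_verdict=verdict,
        movement_magnitude=movement.couple_magnitude,
        moving=movement.moving,
        quality_mean=quality_mean,
        agency_mean=(trial.agency_a + trial.agency_b) / 2.0,
        condition=trial.condition,
    )
    return row


def analyze_cohort(
    cohort: list[tuple[dict, TrialData]],
    base: SimConfig | None = None,
    tracker_config: TrackerConfig | None = None,
    movement_classifier: WaveletMovementClassifier | None = None,
) -> pd.DataFrame:
    """Per-trial marker table for a simulated cohort (one row per trial)."""
    base = base or SimConfig()
    clf = movement_classifier or WaveletMovementClassifier().fit()
    rows = []
    for meta, trial in cohort:
        row = dict(meta)
        row.update(analyze_trial(trial, base, tracker_config, clf))
        rows.append(row)
    return pd.DataFrame(rows)
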