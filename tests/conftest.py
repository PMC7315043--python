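import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dyadtiming as dt
from dyadtiming.simulate import SimConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy():
    return dt.toy_score()


def make_series(durations, start=0.0, sources=None):
    """Build a RelativeIOISeries directly from IOI durations."""
    durations = np.asarray(durations, dtype=float)
    times = np.concatenate([[start], start + np.cumsum(durations)])
    if sources is None:
        sources = ["A" if i % 2 == 0 else "B" for i in range(times.size)]
    return dt.RelativeIOISeries(times, np.array(sources, dtype=object))


def run_sim_trial(seed=0, tracker_kwargs=None, **sim_kwargs):
    """Simulate one trial and run the full tracker + metrics reduction."""
    cfg = SimConfig(seed=seed, **sim_kwargs)
    a, b, truth = dt.render_performance(cfg)
    series = dt.merge_onsets(a, b)
    tracker = dt.IOIClassTracker(**(tracker_kwargs or {})).fit(series)
    expected = dt.expected_class_sequence(cfg.resolved_score, cfg.n_repeats)
    summary = dt.summarize_trace(
        tracker.trace_, expected, prefix_classes=tracker.init_assigned_
    )
    return summary, truth, tracker


@pytest.fixture
def clean_trial():
    return run_sim_trial(
        seed=0, jitter_sigma_log2=0.0, p_omit=0.0, p_substitute=0.0, p_collapse=0.0
    )
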