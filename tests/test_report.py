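import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dyadtiming as dt


def brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    concordant = discordant = 0
    for i, j in itertools.combinations(range(n), 2):
        s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        concordant += s > 0
        discordant += s < 0
    n0 = n * (n - 1) / 2
    tx = sum(t * (t - 1) / 2 for t in pd.Series(x).value_counts())
    ty = sum(t * (t - 1) / 2 for t in pd.Series(y).value_counts())
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (concordant - discordant) / denom


def records_frame(n=24, seed=0, quality_fn=None, agency_fn=None):
    rng = np.random.default_rng(seed)
    fluct = rng.uniform(0.02, 0.3, n)
    narr = 100 - 150 * fluct + rng.normal(0, 2, n)
    coll = 30 * fluct + rng.normal(0, 0.5, n)
    quality = quality_fn(fluct) if quality_fn else 110 - 200 * fluct
    agency = agency_fn(fluct, rng) if agency_fn else np.clip(5 - 10 * fluct, 0, 6)
    return pd.DataFrame(
        {
            "duo": [f"d{i//4}" for i in range(n)],
            "trial": [i % 4 for i in range(n)],
            "condition": ["movement", "non_movement"] * (n // 2),
            "fluctuation_rmse": fluct,
            "narration_pct": np.clip(narr, 0, 100),
            "collapse_pct": np.clip(coll, 0, 100),
            "quality_mean": quality,
            "agency_mean": agency,
            "moving": [c == "movement" for c in ["movement", "non_movement"] * (n // 2)],
            "simultaneous_fraction": np.zeros(n),
        }
    )


class TestKendallTau:
    def test_perfect_concordance(self):
        tau, _ = dt.kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        tau, _ = dt.kendall_tau([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_hand_counted_example(self):
        # pairs of [1,2,3,4] vs [1,3,2,4]: 5 concordant, 1 discordant of 6
        tau, _ = dt.kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(2 / 3)

    def test_too_short_rejected(self):
        with pytest.raises(dt.InsufficientDataError):
            dt.kendall_tau([1, 2], [1, 2])

    def test_agrees_with_brute_force_pair_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            if rng.random() < 0.5:  # heavily tied Likert-like vectors
                x = rng.integers(0, 7, n).astype(float)
                y = rng.integers(0, 7, n).astype(float)
            else:
                x = rng.normal(size=n)
                y = rng.normal(size=n)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            tau, _ = dt.kendall_tau(x, y)
            assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)

    @given(st.integers(0, 1000))
    def test_tau_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 10).astype(float)
        y = rng.integers(0, 4, 10).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            return
        tau, p = dt.kendall_tau(x, y)
        assert -1.0 <= tau <= 1.0 and 0.0 <= p <= 1.0


class TestExclusions:
    def test_movement_in_still_trial_excluded(self):
        df = records_frame()
        df.loc[1, "moving"] = True  # a non_movement row
        out = dt.apply_exclusions(df)
        assert out.loc[1, "excluded"]
        assert out.loc[1, "exclusion_reason"] == "movement_in_still"
        assert not out.loc[0, "excluded"]  # moving in a movement trial is fine

    def test_simultaneous_singing_excluded(self):
        df = records_frame()
        df.loc[2, "simultaneous_fraction"] = 0.3
        out = dt.apply_exclusions(df, simultaneity_limit=0.10)
        assert out.loc[2, "excluded"]
        assert out.loc[2, "exclusion_reason"] == "simultaneous_singing"

    def test_idempotent(self):
        df = records_frame()
        df.loc[1, "moving"] = True
        once = dt.apply_exclusions(df)
        twice = dt.apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_exclusion_table(self):
        df = records_frame()
        df.loc[1, "moving"] = True
        out = dt.exclusion_table(dt.apply_exclusions(df))
        assert len(out) == 1 and out.loc[0, "exclusion_reason"] == "movement_in_still"


class TestCorrelateMarkers:
    def test_noise_free_monotone_links(self):
        df = dt.apply_exclusions(records_frame())
        tau, p, n = dt.correlate_markers(df, "fluctuation", "quality")
        assert tau == pytest.approx(-1.0)
        tau, _, _ = dt.correlate_markers(df, "narration", "quality")
        assert tau > 0.8
        tau, _, _ = dt.correlate_markers(df, "collapse", "quality")
        assert tau < -0.8

    def test_independent_rating_is_null(self):
        taus, ps = [], []
        for seed in range(20):
            df = dt.apply_exclusions(
                records_frame(
                    n=100, seed=seed,
                    agency_fn=lambda f, rng: rng.integers(0, 7, f.size).astype(float),
                )
            )
            tau, p, _ = dt.correlate_markers(df, "fluctuation", "agency")
            taus.append(abs(tau))
            ps.append(p)
        assert np.mean(taus) < 0.1
        assert np.mean(np.array(ps) > 0.05) >= 0.8

    def test_subsets_and_table_shape(self):
        df = dt.apply_exclusions(records_frame())
        table = dt.correlation_table(df)
        assert len(table) == 18  # 3 markers x 2 ratings x 3 subsets
        assert set(table["subset"]) == {"all", "movement", "non_movement"}

    def test_insufficient_records(self):
        df = dt.apply_exclusions(records_frame(n=4))
        df["excluded"] = [False, False, True, True]
        with pytest.raises(dt.InsufficientDataError):
            dt.correlate_markers(df, "fluctuation", "quality")

    def test_excluded_trials_never_enter(self):
        df = dt.apply_exclusions(records_frame())
        df2 = df.copy()
        # corrupt an excluded row: result must not change
        df2.loc[1, "moving"] = True
        df2 = dt.apply_exclusions(df2)
        df2.loc[1, "quality_mean"] = -999
        tau1, _, n1 = dt.correlate_markers(df.drop(index=[1]), "fluctuation", "quality")
        tau2, _, n2 = dt.correlate_markers(df2, "fluctuation", "quality")
        assert tau1 == pytest.approx(tau2) and n1 == n2
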