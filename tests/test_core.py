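"""Unit and property tests for univariate threshold detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ufa import (
    Dataset,
    DegenerateVariableError,
    UfaConfig,
    compute_baseline,
    detect_thresholds,
    find_optimal_threshold,
    generate_candidates,
    z_statistic,
)

from oracles import naive_scan, naive_z


class TestComputeBaseline:
    def test_linear_interpolation_percentiles_and_iqr_counts(self):
        x = np.arange(1, 101, dtype=float)
        y = (x <= 30).astype(float)
        b = compute_baseline(x, y)
        assert b.p25 == pytest.approx(25.75)
        assert b.p75 == pytest.approx(75.25)
        assert b.n_iqr == 50  # integers 26..75 inclusive
        assert b.p_iqr == pytest.approx(5 / 50)

    def test_constant_variable_degenerate_spread(self):
        x = np.full(10, 3.0)
        y = np.array([1, 0, 1, 0, 0, 0, 0, 0, 1, 1], dtype=float)
        b = compute_baseline(x, y)
        assert b.p25 == b.p75 == 3.0
        assert b.n_iqr == 10
        assert b.p_iqr == pytest.approx(y.mean())

    def test_all_zero_outcome(self):
        x = np.arange(20.0)
        b = compute_baseline(x, np.zeros(20))
        assert b.p_iqr == 0.0

    def test_missing_pairs_dropped(self):
        x = np.concatenate([np.arange(1, 101.0), [np.nan] * 30])
        y = np.concatenate([(np.arange(1, 101.0) <= 30), np.ones(30)])
        b = compute_baseline(x, y)
        assert b.n_iqr == 50
        assert b.p_iqr == pytest.approx(0.10)

    @pytest.mark.parametrize("x", [np.full(5, np.nan), np.array([1.0, 2.0, np.nan])])
    def test_degenerate_columns_raise(self, x):
        with pytest.raises(DegenerateVariableError):
            compute_baseline(x, np.zeros(len(x)))


class TestGenerateCandidates:
    def test_grid_construction_with_trimming(self):
        x = np.arange(0, 101, dtype=float)
        cuts = generate_candidates(x, "below")
        # trimmed minimum is the 6th lowest value (5), median 50
        assert len(cuts) == 49
        assert cuts[0] == pytest.approx(5 + 0.9)
        assert cuts[-1] == pytest.approx(50 - 0.9)
        assert np.allclose(np.diff(cuts), 0.9)
        assert np.all((cuts > 5) & (cuts < 50))

    def test_too_few_values_gives_empty_grid(self):
        x = np.array([1.0, 2.0, 3.0, 100.0, 101.0, 102.0, 103.0])
        assert generate_candidates(x, "below").size == 0  # 6th lowest >= median side range collapses
        x2 = np.arange(5.0)
        assert generate_candidates(x2, "below").size == 0

    def test_symmetric_data_mirror_grids(self):
        x = np.concatenate([-np.arange(1, 201.0), np.arange(1, 201.0)])
        below = generate_candidates(x, "below")
        above = generate_candidates(x, "above")
        assert np.allclose(below, -above[::-1])

    def test_heavy_ties_at_extremum(self):
        # many duplicated minima: trimming by order statistic still leaves
        # a well-defined span from the 6th lowest value
        x = np.concatenate([np.zeros(20), np.arange(1, 81.0)])
        cuts = generate_candidates(x, "below")
        assert cuts.size == 49
        assert cuts[0] > 0.0


class TestZStatistic:
    def test_closed_form_example(self):
        expected = 0.3 / math.sqrt(0.24 * 0.03)
        assert z_statistic(0.6, 50, 0.3, 100) == pytest.approx(expected, abs=1e-12)

    @given(
        p=st.floats(0.0, 1.0),
        n1=st.integers(1, 1000),
        n2=st.integers(1, 1000),
    )
    def test_zero_exactly_at_equal_rates(self, p, n1, n2):
        assert z_statistic(p, n1, p, n2) == 0.0

    @given(
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
        n1=st.integers(1, 500),
        n2=st.integers(1, 500),
    )
    def test_antisymmetry_under_group_swap(self, p1, p2, n1, n2):
        z_fwd = z_statistic(p1, n1, p2, n2)
        z_rev = z_statistic(p2, n2, p1, n1)
        assert z_fwd == pytest.approx(-z_rev, abs=1e-12)

    def test_zero_pooled_variance_is_no_evidence(self):
        assert z_statistic(0.0, 50, 0.0, 100) == 0.0
        assert z_statistic(1.0, 50, 1.0, 100) == 0.0

    def test_requires_nonempty_groups(self):
        with pytest.raises(ValueError):
            z_statistic(0.5, 0, 0.5, 10)


class TestFindOptimalThreshold:
    def test_planted_step_recovered_near_cut(self, planted_dataset):
        data, truth = planted_dataset
        x = data.X["v1"].to_numpy()
        res = find_optimal_threshold(x, data.y.to_numpy(), "below", variable="v1")
        cuts = generate_candidates(x, "below")
        spacing = cuts[1] - cuts[0]
        assert res is not None
        assert res.direction == "high_risk"
        assert res.significant
        assert abs(res.cut - truth[0].cut) <= spacing
        # cross-check the selected optimum against the brute-force scan
        cut, z, n_out, p_out = naive_scan(x, data.y.to_numpy(), "below")
        assert res.cut == cut
        assert res.z == pytest.approx(z, abs=1e-12)

    def test_selected_z_is_argmax_over_manual_candidates(self, planted_dataset):
        data, _ = planted_dataset
        x = data.X["v1"].to_numpy()
        y = data.y.to_numpy()
        res = find_optimal_threshold(x, y, "below", variable="v1")
        manual = []
        baseline = compute_baseline(x, y)
        for cut in generate_candidates(x, "below"):
            tail = x < cut
            if tail.sum() >= 1:
                manual.append(
                    z_statistic(y[tail].mean(), int(tail.sum()),
                                baseline.p_iqr, baseline.n_iqr)
                )
        assert abs(res.z) == pytest.approx(max(abs(z) for z in manual), abs=1e-12)

    def test_constant_outcome_yields_nothing(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=200)
        assert find_optimal_threshold(x, np.ones(200), "below") is None
        assert find_optimal_threshold(x, np.zeros(200), "above") is None

    def test_null_data_rarely_significant(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=500)
            y = rng.binomial(1, 0.3, size=500).astype(float)
            res = find_optimal_threshold(x, y, "below")
            hits += bool(res is not None and res.significant)
        assert hits <= 10  # well below half despite the multiplicity of the scan

    def test_tie_break_prefers_support(self):
        # a wide data gap below the median puts several candidates in a
        # region where the tail composition (hence Z) is identical; the
        # cut closest to the median (largest support) must win
        x = np.concatenate([np.arange(10.0), [49.0, 50.0], np.arange(51.0, 90.0)])
        rng = np.random.default_rng(3)
        y = rng.binomial(1, np.where(x < 10, 0.9, 0.2)).astype(float)
        res = find_optimal_threshold(x, y, "below")
        cuts = generate_candidates(x, "below")
        tied = []
        baseline = compute_baseline(x, y)
        for cut in cuts:
            tail = x < cut
            if tail.sum() >= 1:
                z = z_statistic(y[tail].mean(), int(tail.sum()),
                                baseline.p_iqr, baseline.n_iqr)
                tied.append((cut, z))
        best = max(abs(z) for _, z in tied)
        winners = [c for c, z in tied if abs(z) == best]
        assert len(winners) > 1  # the gap really creates a tie
        assert res.cut == max(winners)

    def test_abs_z_monotone_in_planted_effect(self):
        rng = np.random.default_rng(42)
        n = 4000
        x = rng.uniform(size=n)
        u = rng.uniform(size=n)  # shared noise: same draws at every delta
        zs = []
        for delta in [0.1, 0.2, 0.3, 0.4, 0.5]:
            p = np.where(x < 0.2, 0.2 + delta, 0.2)
            y = (u < p).astype(float)
            res = find_optimal_threshold(x, y, "below")
            zs.append(abs(res.z))
        assert all(b >= a for a, b in zip(zs, zs[1:]))


class TestDetectThresholds:
    def test_deterministic_and_quiet_on_noise(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({f"n{i}": rng.uniform(size=200) for i in range(10)})
        y = pd.Series(rng.binomial(1, 0.3, size=200))
        data = Dataset(X, y)
        ts1 = detect_thresholds(data)
        ts2 = detect_thresholds(data)
        assert ts1.labels == ts2.labels
        assert len(ts1) <= 4

    def test_two_sided_planted_effects_found(self, two_sided_dataset):
        data, truth = two_sided_dataset
        ts = detect_thresholds(data)
        found = {(t.variable, t.side, t.direction) for t in ts}
        assert ("a", "below", "high_risk") in found
        assert ("a", "above", "low_risk") in found
        assert ("b", "below", "high_risk") in found
        assert ("b", "above", "low_risk") in found
        assert len([t for t in ts if t.variable in ("a", "b")]) == 4

    def test_missing_values_do_not_mask_a_strong_effect(self, planted_dataset):
        data, truth = planted_dataset
        rng = np.random.default_rng(2)
        x = data.X["v1"].to_numpy().copy()
        x[rng.random(x.size) < 0.4] = np.nan
        data.X["v1"] = x
        ts = detect_thresholds(data)
        hits = [t for t in ts if t.variable == "v1" and t.side == "below"]
        assert len(hits) == 1
        assert hits[0].direction == "high_risk"

    def test_missing_data_locality(self, planted_dataset):
        # detection for one variable must depend only on rows where that
        # variable is observed
        data, _ = planted_dataset
        rng = np.random.default_rng(9)
        miss = rng.random(data.n_obs) < 0.3
        X = data.X.copy()
        X.loc[miss, "noise1"] = np.nan
        with_missing = Dataset(X, data.y)
        full = detect_thresholds(data)
        masked = detect_thresholds(with_missing)
        for_v1 = lambda ts: [(t.cut, t.z) for t in ts if t.variable == "v1"]
        assert for_v1(full) == for_v1(masked)

    def test_all_missing_variable_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"v": rng.uniform(size=50), "dead": np.full(50, np.nan)})
        y = pd.Series(rng.binomial(1, 0.5, size=50))
        with caplog.at_level("WARNING"):
            ts = detect_thresholds(Dataset(X, y))
        assert any("dead" in r.message for r in caplog.records)
        assert all(t.variable != "dead" for t in ts)

    def test_at_most_two_thresholds_per_variable(self, two_sided_dataset):
        data, _ = two_sided_dataset
        ts = detect_thresholds(data)
        per_var = pd.Series([t.variable for t in ts]).value_counts()
        assert (per_var <= 2).all()

    def test_bonferroni_is_stricter(self, two_sided_dataset):
        data, _ = two_sided_dataset
        plain = detect_thresholds(data, UfaConfig())
        corrected = detect_thresholds(data, UfaConfig(bonferroni=True))
        assert set(corrected.labels) <= set(plain.labels)


class TestContinuousTarget:
    def test_continuous_target_uses_group_means(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(size=3000)
        # graded severity score in [0,1], elevated in the low tail
        y = np.clip(np.where(x < 0.2, 0.8, 0.2) + rng.normal(0, 0.05, 3000), 0, 1)
        data = Dataset(pd.DataFrame({"v": x}), pd.Series(y), continuous_target=True)
        ts = detect_thresholds(data)
        below = [t for t in ts if t.side == "below"]
        assert below and below[0].direction == "high_risk"
        assert abs(below[0].cut - 0.2) < 0.05

    def test_binary_contract_enforced_by_default(self):
        X = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.raises(Exception):
            Dataset(X, pd.Series([0.5, 0.2, 1.0]))


@pytest.mark.parametrize("seed", range(10))
def test_scan_matches_bruteforce_oracle_random_data(seed):
    """Optimised scan == naive recomputation, on messy random inputs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(50, 400))
    x = rng.normal(size=n)
    x[rng.random(n) < 0.1] = np.nan
    y = rng.binomial(1, 0.4, size=n).astype(float)
    for side in ("below", "above"):
        mine = find_optimal_threshold(x, y, side)
        ref = naive_scan(x, y, side)
        if ref is None:
            assert mine is None
            continue
        assert mine is not None
        assert mine.cut == ref[0]
        assert mine.z == pytest.approx(ref[1], abs=1e-12)
        assert mine.n_out == ref[2]
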