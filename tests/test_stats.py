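"""Exact and approximate test statistics, and the bootstrap correction."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from hrdscape.stats import (
    bootstrap_compare, chi_square_test, comparisons_to_frame, mann_whitney_u,
    summarize_groups,
)


def enumeration_p(x, y):
    """Two-sided Mann-Whitney p by enumerating every labelling (no ties)."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    nm = len(x) * len(y)
    lo, hi = min(u_obs, nm - u_obs), max(u_obs, nm - u_obs)
    extreme = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = sum(1 for a in xs for b in ys if a > b)
        total += 1
        if u <= lo or u >= hi:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)=20 labellings

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_large_separation_tiny_p(self):
        _, p = mann_whitney_u(list(range(1, 31)), list(range(31, 61)))
        assert p < 1e-9

    def test_matches_enumeration_for_all_small_partitions(self):
        rng = np.random.default_rng(12)
        for n in range(1, 6):
            for m in range(n, 11 - n):
                vals = rng.permutation(np.arange(1.0, n + m + 1))
                x, y = vals[:n], vals[n:]
                _, p = mann_whitney_u(x, y)
                assert p == pytest.approx(enumeration_p(x, y)), (n, m)

    def test_cross_check_against_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            _, p = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_cross_check_against_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.integers(0, 4, size=25).astype(float)
            y = rng.integers(0, 4, size=30).astype(float)
            _, p = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_u([], [1.0])


class TestChiSquare:
    def test_balanced_table_statistic_zero(self):
        stat, p, df = chi_square_test([[10, 10], [10, 10]])
        assert stat == 0 and p == pytest.approx(1.0) and df == 1

    def test_diagonal_table_hand_computed(self):
        stat, p, df = chi_square_test([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0) and df == 1

    def test_2x3_table_df(self):
        _, _, df = chi_square_test([[5, 6, 7], [8, 9, 10]])
        assert df == 2

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 5]])


class TestBootstrap:
    def test_single_iteration_equals_one_subsampled_test(self):
        rng = np.random.default_rng(42)
        pool = np.arange(100.0)
        carriers = [5.0, 50.0, 95.0]
        res = bootstrap_compare(carriers, pool, n_controls=30, iters=1,
                                rng=np.random.default_rng(7))
        # reproduce the single subsample with the same stream
        rng2 = np.random.default_rng(7)
        keys = rng2.random((1, pool.size))
        idx = np.argpartition(keys, 29, axis=1)[:, :30]
        _, p = mann_whitney_u(carriers, pool[idx[0]])
        assert res.p_corrected == pytest.approx(p)

    def test_reproducible_for_fixed_seed(self):
        pool = np.random.default_rng(0).normal(size=200)
        x = [0.1, 0.5, 0.9]
        a = bootstrap_compare(x, pool, iters=50, seed=3)
        b = bootstrap_compare(x, pool, iters=50, seed=3)
        assert np.array_equal(a.p_iterations, b.p_iterations)

    def test_pool_smaller_than_controls_is_error(self):
        with pytest.raises(ValueError, match="pool"):
            bootstrap_compare([1.0], np.arange(10.0), n_controls=30, seed=0)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_compare([1.0], np.arange(50.0))

    def test_total_separation_gives_minimal_exact_p(self):
        """All 9 carriers above the whole pool: corrected p equals the
        minimal exact two-sided p for sizes (9, 30)."""
        pool = np.arange(500, dtype=float)
        carriers = np.arange(1000, 1009, dtype=float)
        from math import comb
        p_min = 2 * 1 / comb(39, 9)
        res = bootstrap_compare(carriers, pool, seed=5, iters=100)
        assert res.p_corrected == pytest.approx(p_min)

    def test_exact_path_matches_per_iteration_mann_whitney(self):
        rng = np.random.default_rng(8)
        pool = rng.normal(size=80)
        carriers = rng.normal(size=6)
        res = bootstrap_compare(carriers, pool, n_controls=20, iters=10, seed=9)
        # recompute each iteration independently through mann_whitney_u
        rng2 = np.random.default_rng(9)
        keys = rng2.random((10, pool.size))
        idx = np.argpartition(keys, 19, axis=1)[:, :20]
        expected = [mann_whitney_u(carriers, pool[i])[1] for i in idx]
        assert np.allclose(res.p_iterations, expected)


class TestSummaries:
    def _labels(self):
        import pandas as pd
        rows = []
        for i, (grp, st) in enumerate(
                [("PALB2_germline", "biallelic")] * 3
                + [("non_carrier", ".")] * 40):
            rows.append({"sample_id": f"S{i}", "carrier_group": grp,
                         "allelic_status": st})
        return pd.DataFrame(rows)

    def test_stratum_summaries_and_partition(self):
        labels = self._labels()
        values = {f"S{i}": float(100 + i) for i in range(3)}
        values.update({f"S{i}": float(i) for i in range(3, 43)})
        comps = summarize_groups(values, labels, "metric", seed=1, iters=20)
        (c,) = comps
        assert c.stratum == "PALB2_biallelic"
        assert c.n_group == 3 and c.n_reference == 40
        assert c.group_summary == pytest.approx(101.0)
        assert c.p_bootstrap is not None and c.p_bootstrap < 0.05

    def test_empty_stratum_omitted(self):
        labels = self._labels()
        values = {r: 1.0 for r in labels["sample_id"]}
        comps = summarize_groups(values, labels, "metric", seed=1, iters=10)
        strata = {c.stratum for c in comps}
        assert "BRCA1_biallelic" not in strata

    def test_frame_round_trips_columns(self):
        labels = self._labels()
        values = {r: float(i) for i, r in enumerate(labels["sample_id"])}
        comps = summarize_groups(values, labels, "m", seed=0, iters=10)
        frame = comparisons_to_frame(comps)
        assert {"metric", "stratum", "p_raw", "p_bootstrap"} <= set(frame.columns)
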