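"""Constrained clustering, broken-stick significance and zone statistics."""

import numpy as np
import pytest
from scipy.special import comb

from silutil import (
    broken_stick_expected,
    coniss_cluster,
    significant_zones,
    zone_difference_test,
    zone_stats,
)

# ---------------------------------------------------------------- oracles


def _pooled_ss(block):
    v = np.asarray(block, float)
    return float(np.sum((v - v.mean()) ** 2))


def brute_force_coniss(x):
    """Greedy constrained agglomeration recomputing pooled SS from scratch.

    Independent of the package's O(1) Ward-identity updates: every
    candidate increase is evaluated as SS(A+B) - SS(A) - SS(B) on the raw
    blocks.  Ties break toward the highest index, matching the package's
    oldest-pair rule for ascending ages.
    """
    blocks = [[float(v)] for v in x]
    increments = []
    while len(blocks) > 1:
        incs = [
            _pooled_ss(blocks[i] + blocks[i + 1])
            - _pooled_ss(blocks[i])
            - _pooled_ss(blocks[i + 1])
            for i in range(len(blocks) - 1)
        ]
        best = min(incs)
        j = max(i for i, v in enumerate(incs) if v == best)
        blocks[j] = blocks[j] + blocks[j + 1]
        del blocks[j + 1]
        increments.append(best)
    return np.array(increments)


def exact_rank_sum_p(a, b):
    """Two-sided Mann-Whitney p by exhaustive enumeration of U."""
    import itertools

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        grp = pooled[list(combo)]
        rest = np.delete(pooled, list(combo))
        us.append(sum(1 for x in grp for y in rest if x > y))
    us = np.asarray(us, float)
    mean_u = len(a) * len(b) / 2
    return np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)


# ---------------------------------------------------------------- CONISS


class TestConiss:
    def test_step_series_first_boundary_at_the_step(self):
        vals = np.array([1, 1, 1, 9, 9, 9], float)
        res = coniss_cluster(vals, np.arange(6.0) + 1)
        assert res.boundary_indices[2] == (3,)

    def test_agglomeration_contract(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, 17)
        res = coniss_cluster(vals, np.arange(17.0))
        assert len(res.merge_history) == 16
        assert np.all(res.increments >= 0)

    def test_merges_only_adjacent_blocks(self):
        rng = np.random.default_rng(4)
        res = coniss_cluster(rng.uniform(0, 1, 12), np.arange(12.0))
        for (l0, l1), (r0, r1), _ in res.merge_history:
            assert l1 == r0  # strictly adjacent half-open ranges

    def test_dispersion_conservation(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, 40)
        res = coniss_cluster(vals, np.arange(40.0))
        total = _pooled_ss(np.sqrt(vals))
        assert res.total_dispersion == pytest.approx(total, rel=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_merge_choices_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        vals = rng.uniform(0, 1, n)
        res = coniss_cluster(vals, np.arange(float(n)), transform="none")
        oracle = brute_force_coniss(vals)
        assert res.increments == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            coniss_cluster([1, 2], [0, 1])
        with pytest.raises(ValueError, match="strictly increasing"):
            coniss_cluster([1, 2, 3], [0, 2, 1])
        with pytest.raises(ValueError, match="non-negative"):
            coniss_cluster([1, -2, 3], [0, 1, 2], transform="sqrt")
        with pytest.raises(ValueError, match="transform"):
            coniss_cluster([1, 2, 3], [0, 1, 2], transform="log")


# ---------------------------------------------------------------- broken stick


class TestBrokenStick:
    def test_single_zone(self):
        assert broken_stick_expected(1) == pytest.approx([1.0])

    def test_two_zone_expectations_exact(self):
        assert broken_stick_expected(2).tolist() == [0.75, 0.25]

    @pytest.mark.parametrize("n", [1, 2, 3, 7, 50])
    def test_sums_to_one_and_decreasing(self, n):
        pr = broken_stick_expected(n)
        assert pr.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(pr) <= 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            broken_stick_expected(0)

    def test_table_columns_both_sum_to_one(self):
        rng = np.random.default_rng(11)
        res = coniss_cluster(rng.uniform(0, 1, 30), np.arange(30.0))
        table = res.broken_stick_table
        assert table["observed_proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["expected_pr"].sum() == pytest.approx(1.0, abs=1e-9)


class TestSignificance:
    def test_two_level_step_with_noise_gives_two_zones(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([
            0.34 + rng.normal(0, 0.02, 25),
            0.48 + rng.normal(0, 0.02, 25),
        ])
        res = coniss_cluster(np.clip(vals, 0, 1), np.arange(50.0))
        assert res.n_significant == 2
        assert len(res.zones) == 2

    def test_white_noise_mostly_one_zone(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            vals = rng.uniform(0.2, 0.8, 50)
            res = coniss_cluster(vals, np.arange(50.0))
            hits += res.n_significant == 1
        assert hits > 100  # majority of replicates

    def test_zones_partition_the_series(self):
        rng = np.random.default_rng(12)
        res = coniss_cluster(rng.uniform(0, 1, 30), np.arange(30.0))
        covered = sorted(i for z in res.zones for i in z.sample_indices)
        assert covered == list(range(30))
        assert res.n_significant >= 1


# ---------------------------------------------------------------- zone stats


class TestZoneStats:
    def test_single_sample_zone(self):
        res = coniss_cluster([1.0, 1.0, 9.0], [0.0, 1.0, 2.0])
        # force a partition: use the 2-zone candidate regardless of significance
        from silutil.zonation import _partition_from_starts

        zones = _partition_from_starts(np.array([0.0, 1.0, 2.0]),
                                       res.boundary_indices[2])
        stats = zone_stats([1.0, 1.0, 9.0], zones)
        single = stats[stats["n"] == 1].iloc[0]
        assert single["median"] == 9.0
        assert single["q3"] - single["q1"] == 0.0

    def test_type7_quantiles(self):
        from silutil.zonation import Zone

        zone = Zone("Zone 1", (0.0, 3.0), (0, 1, 2, 3))
        stats = zone_stats([10, 20, 30, 40], [zone])
        row = stats.iloc[0]
        assert row["median"] == 25.0
        assert row["q1"] == 17.5  # linear interpolation between order stats
        assert row["q3"] == 32.5

    def test_empty_zone_rejected(self):
        from silutil.zonation import Zone

        with pytest.raises(ValueError, match="no samples"):
            zone_stats([1.0, 2.0], [Zone("Zone 1", (0, 0), ())])


# ---------------------------------------------------------------- rank-sum test


class TestZoneDifference:
    def test_identical_zones_give_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            assert zone_difference_test([1, 1, 1], [1, 1, 1]) == 1.0

    def test_complete_separation_matches_enumeration_oracle(self):
        a = list(range(1, 9))
        b = list(range(101, 109))
        p = zone_difference_test(a, b)
        # smallest achievable two-sided exact p for n=8,8
        assert p == pytest.approx(2 / comb(16, 8), rel=1e-9)
        assert p == pytest.approx(exact_rank_sum_p(a, b), rel=1e-9)

    def test_small_sample_exact_matches_enumeration(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.8, 1, 7)
        assert zone_difference_test(a, b) == pytest.approx(
            exact_rank_sum_p(a, b), rel=1e-9
        )

    def test_empty_zone_rejected(self):
        with pytest.raises(ValueError):
            zone_difference_test([], [1.0])
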