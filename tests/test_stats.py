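"""Permutation inference: ANOVA, paired t, Holm, cluster tests, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beatpipe.stats import (
    channel_adjacency,
    cluster_permutation,
    edge_adjacency,
    edge_pairs,
    holm,
    neurophenomenological_contrast,
    perm_paired_t,
    perm_rm_anova,
    rank_conditions,
)


class TestHolm:
    def test_all_rejected_when_each_step_passes(self):
        reject, _ = holm([0.01, 0.02, 0.04], alpha=0.05)
        assert reject.all()

    def test_sequential_stop_rejects_none(self):
        reject, _ = holm([0.03, 0.2], alpha=0.05)
        assert not reject.any()

    def test_single_pvalue_plain_alpha(self):
        reject, p_adj = holm([0.04], alpha=0.05)
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_sequential_definition(self, pvals):
        """Cross-check against the step-down rule written out directly."""
        pvals = np.asarray(pvals)
        reject, p_adj = holm(pvals, alpha=0.05)
        m = len(pvals)
        order = np.argsort(pvals)
        expected_reject = np.zeros(m, dtype=bool)
        for k, idx in enumerate(order):
            if all(pvals[order[j]] <= 0.05 / (m - j) for j in range(k + 1)):
                expected_reject[idx] = True
        np.testing.assert_array_equal(reject, expected_reject)
        running = 0.0
        for k, idx in enumerate(order):
            running = max(running, min(1.0, (m - k) * pvals[idx]))
            assert p_adj[idx] == pytest.approx(running)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm([0.5, 1.2])


class TestPairedT:
    def test_identical_vectors_give_p_one(self, rng):
        a = rng.standard_normal(8)
        with pytest.warns(UserWarning):
            res = perm_paired_t(a, a.copy(), n_perm=200, seed=0)
        assert res.observed_stat == 0.0 and res.p == 1.0

    def test_huge_shift_hits_resolution_floor(self, rng):
        a = rng.standard_normal(16)
        res = perm_paired_t(a + 100.0, a, n_perm=500, seed=1)
        assert res.p == pytest.approx(1 / 500)

    def test_seeded_runs_are_bit_identical(self, rng):
        a, b = rng.standard_normal((2, 10))
        r1 = perm_paired_t(a, b, n_perm=300, seed=42)
        r2 = perm_paired_t(a, b, n_perm=300, seed=42)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)

    def test_power_for_one_sd_shift_matches_oracle(self):
        """n=16, d=1: closed-form paired-t power ~ 0.96; demand >= 0.9."""
        rng = np.random.default_rng(77)
        hits = 0
        reps = 200
        for _ in range(reps):
            b = rng.standard_normal(16)
            a = b + 1.0 + rng.standard_normal(16)  # difference ~ N(1, 1)
            if perm_paired_t(a, b, n_perm=200, seed=int(rng.integers(2**31))).p <= 0.05:
                hits += 1
        assert hits / reps >= 0.9

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            perm_paired_t(np.ones(2), np.zeros(2))


class TestRmAnova:
    def test_constant_rows_give_p_one(self):
        scores = np.tile([[1.0, 1.0, 1.0, 1.0, 1.0]], (8, 1))
        with pytest.warns(UserWarning):
            res = perm_rm_anova(scores, "one_way", n_perm=100, seed=0)
        assert res.p == 1.0

    def test_large_shift_detected(self, rng):
        scores = rng.standard_normal((16, 5))
        scores[:, 2] += 5.0
        res = perm_rm_anova(scores, "one_way", n_perm=500, seed=3)
        assert res.p <= 0.05

    def test_null_type_one_rate_near_nominal(self):
        """Rejection (p <= 0.05) on null Gaussian data stays near 5%."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 120
        for _ in range(reps):
            scores = rng.standard_normal((8, 5))
            if perm_rm_anova(scores, "one_way", n_perm=100, seed=int(rng.integers(2**31))).p <= 0.05:
                hits += 1
        rate = hits / reps
        margin = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= margin + 1 / 100  # + estimator granularity

    def test_factorial_effects_localized(self, rng):
        """A pure factor-A shift drives the A main effect, not B."""
        scores = rng.standard_normal((16, 4)) * 0.5
        scores[:, 2:] += 4.0  # columns ordered (A1B1, A1B2, A2B1, A2B2)
        res = perm_rm_anova(scores, "factorial_2x2", n_perm=500, seed=5)
        assert res["factor_a"].p <= 0.01
        assert res["factor_b"].p > 0.05

    def test_factorial_interaction_detected(self, rng):
        scores = rng.standard_normal((16, 4)) * 0.5
        scores[:, 3] += 4.0  # only A2B2 shifted: interaction present
        res = perm_rm_anova(scores, "factorial_2x2", n_perm=500, seed=6)
        assert res["interaction"].p <= 0.01

    def test_missing_cells_rejected(self):
        scores = np.ones((4, 4))
        scores[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            perm_rm_anova(scores, "factorial_2x2")

    def test_ci_is_central_null_interval(self, rng):
        res = perm_rm_anova(rng.standard_normal((8, 5)), "one_way", n_perm=400, seed=9)
        lo, hi = res.ci
        inside = np.mean((res.null_distribution >= lo) & (res.null_distribution <= hi))
        assert inside == pytest.approx(0.95, abs=0.02)


@pytest.fixture(scope="module")
def grid_adjacency():
    """4x4 electrode grid with Delaunay adjacency."""
    xs, ys = np.meshgrid(np.arange(4.0), np.arange(4.0))
    positions = np.column_stack([xs.ravel(), ys.ravel()])
    return positions, channel_adjacency(positions, max_distance=1.5)


class TestClusterPermutation:
    def test_identical_maps_yield_no_clusters(self, grid_adjacency, rng):
        _, adj = grid_adjacency
        maps = rng.standard_normal((8, 2, 16))
        assert cluster_permutation(maps, maps.copy(), adj, n_perm=100, seed=0) == []

    def test_planted_electrodes_recovered_as_one_cluster(self, grid_adjacency):
        """Six adjacent electrodes shifted in one of seven bands come back
        as a single significant positive cluster. (The z-scoring step caps
        attainable z at sqrt((n-k)/k) for k of n shifted points, so the
        planted fraction must be small, as it is at real map sizes.)"""
        _, adj = grid_adjacency
        rng = np.random.default_rng(21)
        planted = [0, 1, 2, 4, 5, 6]  # adjacent block in band 1
        maps_a = rng.standard_normal((10, 7, 16)) * 0.3
        maps_b = rng.standard_normal((10, 7, 16)) * 0.3
        maps_a[:, 1, planted] += 5.0
        clusters = cluster_permutation(maps_a, maps_b, adj, n_perm=200, seed=2)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.polarity == "positive" and c.p <= 0.05 and c.band == 1
        assert sorted(u for _, u in c.members) == planted

    def test_rescaling_all_maps_leaves_result_unchanged(self, grid_adjacency):
        _, adj = grid_adjacency
        rng = np.random.default_rng(31)
        maps_a = rng.standard_normal((8, 2, 16))
        maps_a[:, 0, :4] += 4.0
        maps_b = rng.standard_normal((8, 2, 16))
        c1 = cluster_permutation(maps_a, maps_b, adj, n_perm=200, seed=4)
        c2 = cluster_permutation(100.0 * maps_a, 100.0 * maps_b, adj, n_perm=200, seed=4)
        assert len(c1) == len(c2)
        for a, b in zip(c1, c2):
            assert a.members == b.members and a.p == b.p
            assert a.mass == pytest.approx(b.mass / 100.0 if False else b.mass, rel=1e-9)

    def test_familywise_false_positive_rate_controlled(self, grid_adjacency):
        """Null maps: any-cluster rate over replicates stays below nominal."""
        _, adj = grid_adjacency
        rng = np.random.default_rng(41)
        fps = 0
        reps = 40
        for _ in range(reps):
            maps_a = rng.standard_normal((8, 3, 16))
            maps_b = rng.standard_normal((8, 3, 16))
            if cluster_permutation(maps_a, maps_b, adj, n_perm=100, seed=int(rng.integers(2**31))):
                fps += 1
        assert fps / reps <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps)

    def test_detection_rate_monotone_in_effect_size(self, grid_adjacency):
        _, adj = grid_adjacency
        rng = np.random.default_rng(51)
        rates = []
        for effect in (0.0, 2.0, 6.0):
            hits = 0
            for _ in range(15):
                maps = rng.standard_normal((10, 6, 16))
                maps[:, 0, [5, 6, 9, 10]] += effect
                if cluster_permutation(maps, None, adj, n_perm=100, seed=int(rng.integers(2**31))):
                    hits += 1
            rates.append(hits / 15)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[0] <= 0.1 and rates[2] >= 0.8

    def test_edge_adjacency_links_pairs_sharing_an_electrode(self):
        pairs = edge_pairs(4)
        adj = edge_adjacency(pairs)
        i = pairs.index((0, 1))
        j = pairs.index((1, 3))
        k = pairs.index((2, 3))
        assert adj[i, j] and not adj[i, k]
        assert adj.shape == (6, 6) and not adj.diagonal().any()

    def test_mismatched_adjacency_rejected(self, grid_adjacency, rng):
        _, adj = grid_adjacency
        with pytest.raises(ValueError):
            cluster_permutation(rng.standard_normal((6, 1, 5)), None, adj)


class TestAdjacency:
    def test_delaunay_leaves_no_orphans(self, rng):
        positions = rng.standard_normal((20, 2))
        adj = channel_adjacency(positions)
        assert np.all(adj.sum(axis=0) >= 1)
        np.testing.assert_array_equal(adj, adj.T)
        assert not adj.diagonal().any()

    def test_layout_adjacency_is_usable(self):
        from beatpipe.layout import channel_layout, scalp_channels

        names, xy = channel_layout(16)
        adj = channel_adjacency(xy[scalp_channels(names)])
        assert np.all(adj.sum(axis=0) >= 1)


def _ratings(values_by_condition, n_subjects):
    rows = []
    for s in range(n_subjects):
        for c, v in values_by_condition.items():
            rows.append(
                {"subject": s, "condition": c, "mental_relaxation": v, "absorption_depth": v}
            )
    return pd.DataFrame(rows)


class TestNeurophenomenology:
    CONDS = ["binaural_theta", "binaural_gamma", "monaural_theta", "monaural_gamma"]

    def test_tied_ratings_use_presentation_order(self):
        ratings = _ratings({c: 50.0 for c in self.CONDS}, 1)
        ranked = rank_conditions(ratings, 0, "mental_relaxation")
        assert ranked == self.CONDS  # ties keep table order

    def test_rating_coupled_effect_recovered(self, grid_adjacency):
        """Maps whose strength tracks ratings surface as a contrast cluster."""
        _, adj = grid_adjacency
        rng = np.random.default_rng(61)
        n_subj, planted = 10, [0, 1, 4, 5]
        strengths = {c: v for c, v in zip(self.CONDS, (0.0, 0.0, 4.0, 4.0))}
        maps = {
            c: rng.standard_normal((n_subj, 6, 16)) * 0.5 for c in self.CONDS
        }
        for c, v in strengths.items():
            maps[c][:, 0, planted] += v
        ratings = _ratings({c: 20.0 + 10.0 * strengths[c] for c in self.CONDS}, n_subj)
        contrast, clusters = neurophenomenological_contrast(
            maps, ratings, "mental_relaxation", adj, n_perm=200, seed=7
        )
        assert contrast.shape == (n_subj, 6, 16)
        assert len(clusters) == 1
        assert sorted(u for _, u in clusters[0].members) == planted
        assert clusters[0].polarity == "positive" and clusters[0].p <= 0.05

    def test_ratings_independent_of_maps_rarely_fire(self, grid_adjacency):
        _, adj = grid_adjacency
        rng = np.random.default_rng(71)
        fps = 0
        reps = 25
        for _ in range(reps):
            maps = {c: rng.standard_normal((8, 1, 16)) for c in self.CONDS}
            vals = dict(zip(self.CONDS, rng.uniform(0, 100, 4)))
            _, clusters = neurophenomenological_contrast(
                maps, _ratings(vals, 8), "absorption_depth", adj,
                n_perm=100, seed=int(rng.integers(2**31)),
            )
            fps += bool(clusters)
        assert fps / reps <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps)

    def test_fewer_than_four_conditions_rejected(self, grid_adjacency, rng):
        _, adj = grid_adjacency
        maps = {c: rng.standard_normal((4, 1, 16)) for c in self.CONDS[:3]}
        with pytest.raises(ValueError):
            neurophenomenological_contrast(
                maps, _ratings({c: 1.0 for c in self.CONDS[:3]}, 4),
                "mental_relaxation", adj,
            )
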