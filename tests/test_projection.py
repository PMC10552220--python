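"""Log expression, seeding, candidate selection, and the simplex solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasproj import (
    compute_log_expression,
    correlate_query_atlas,
    project_all,
    project_expression,
    select_candidates,
    solve_mixture_weights,
)
from atlasproj.projection import CandidateSet, compute_log_expression as _cle


def _grid_search_simplex(a, b, step=0.01):
    """Exhaustive simplex search oracle: min ||a @ w - b|| on a weight grid."""
    best = math.inf
    n = round(1.0 / step)
    for i in range(n + 1):
        for j in range(n + 1 - i):
            w = np.array([i, j, n - i - j]) / n
            obj = np.linalg.norm(a @ w - b)
            if obj < best:
                best = obj
    return best


class TestLogExpression:
    def test_zero_count_floor(self):
        prof = compute_log_expression(np.array([[0, 10]]), epsilon=1e-5)
        assert prof.log2e[0, 0] == pytest.approx(np.log2(1e-5), abs=1e-12)

    def test_single_expressed_gene(self):
        prof = compute_log_expression(np.array([[100, 0]]), epsilon=1e-5)
        assert prof.log2e[0, 0] == pytest.approx(np.log2(1 + 1e-5), abs=1e-12)
        assert prof.log2e[0, 0] == pytest.approx(1.4427e-5, rel=1e-3)

    def test_matches_scalar_reference(self, rng):
        umis = rng.integers(0, 50, size=(5, 4))
        umis[:, 0] += 1  # no zero rows
        prof = compute_log_expression(umis, epsilon=1e-5)
        for i in range(5):
            total = sum(umis[i])
            for g in range(4):
                expected = math.log2(1e-5 + umis[i, g] / total)
                assert prof.log2e[i, g] == pytest.approx(expected, abs=1e-12)

    def test_zero_umi_metacell_named(self):
        with pytest.raises(ValueError, match="mc1"):
            compute_log_expression(np.array([[1, 1], [0, 0]]), metacell_names=["mc0", "mc1"])

    def test_totals_over_common_genes_only(self):
        # totals are computed over the provided (common) columns, nothing else
        prof = compute_log_expression(np.array([[10, 30]]))
        assert prof.totals[0] == 40
        np.testing.assert_allclose(prof.fractions.sum(axis=1), 1.0)


class TestCorrelation:
    def test_identical_vectors_give_one(self, rng):
        e = rng.normal(size=(3, 20))
        c = correlate_query_atlas(e, e, np.ones(20, dtype=bool))
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)

    def test_sign_flip_gives_minus_one(self, rng):
        a = rng.normal(size=(1, 20))
        q = -a  # mean-centered sign flip => correlation -1
        c = correlate_query_atlas(q, a, np.ones(20, dtype=bool))
        assert c[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_scalar_pearson(self, rng):
        q = rng.normal(size=(3, 3))
        a = rng.normal(size=(3, 3))
        c = correlate_query_atlas(q, a, np.ones(3, dtype=bool))
        for i in range(3):
            for j in range(3):
                x, y = q[i], a[j]
                xc, yc = x - x.mean(), y - y.mean()
                expected = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
                assert c[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gives_zero_not_nan(self, rng):
        q = np.ones((1, 10))
        a = rng.normal(size=(2, 10))
        c = correlate_query_atlas(q, a, np.ones(10, dtype=bool))
        assert np.all(c == 0.0)

    def test_requires_two_masked_genes(self, rng):
        mask = np.zeros(10, dtype=bool)
        mask[0] = True
        with pytest.raises(ValueError):
            correlate_query_atlas(rng.normal(size=(1, 10)), rng.normal(size=(1, 10)), mask)


class TestCandidateSelection:
    def test_tiny_atlas_takes_everything(self, rng):
        e_a = rng.normal(size=(5, 30))
        cand = select_candidates(2, e_a, np.ones(30, dtype=bool))
        assert sorted(cand.members.tolist()) == [0, 1, 2, 3, 4]
        assert cand.members[0] == 2  # the anchor is closest to itself

    def test_cap_at_fifty_when_all_close(self, rng):
        base = rng.normal(size=60)
        e_a = base[None, :] + rng.uniform(-0.5, 0.5, size=(60, 60))
        cand = select_candidates(0, e_a, np.ones(60, dtype=bool))
        assert len(cand.members) == 50

    def test_distance_gate_for_extras(self):
        # 12 metacells: ranks 11-12 are at distance 3 (>= 2), so they are cut
        e_a = np.zeros((12, 4))
        e_a[:, 0] = np.concatenate([np.linspace(0, 1, 10), [3.0, 3.0]])
        cand = select_candidates(0, e_a, np.ones(4, dtype=bool))
        assert len(cand.members) == 10
        assert set(cand.members.tolist()) == set(range(10))
        # lowering the far pair below the gate admits them
        e_a[10:, 0] = 1.5
        cand = select_candidates(0, e_a, np.ones(4, dtype=bool))
        assert len(cand.members) == 12

    def test_ties_break_toward_lower_index(self):
        # 14 equidistant metacells at exactly the gate distance (not < 2):
        # only the closest 10 enter, and the tie resolves to lower indices
        e_a = np.zeros((15, 3))
        e_a[1:, 0] = 2.0
        cand = select_candidates(0, e_a, np.ones(3, dtype=bool))
        assert cand.members.tolist() == list(range(10))


class TestMixtureSolver:
    def _candidates(self, k):
        return CandidateSet(anchor=0, members=np.arange(k), distances=np.zeros(k))

    def test_exact_candidate_recovered(self, rng):
        e_a = rng.normal(size=(4, 25))
        w = solve_mixture_weights(e_a[2], self._candidates(4), e_a, np.ones(25, dtype=bool))
        np.testing.assert_allclose(w, [0, 0, 1, 0], atol=1e-6)

    def test_midpoint_recovered(self, rng):
        e_a = rng.normal(size=(2, 25))
        query = e_a.mean(axis=0)
        w = solve_mixture_weights(query, self._candidates(2), e_a, np.ones(25, dtype=bool))
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)

    def test_simplex_feasibility(self, rng):
        for _ in range(20):
            e_a = rng.normal(size=(8, 30))
            query = rng.normal(size=30)
            w = solve_mixture_weights(query, self._candidates(8), e_a, np.ones(30, dtype=bool))
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((w == 0) | (w >= 1e-5))

    def test_never_worse_than_anchor_only(self, rng):
        for _ in range(20):
            e_a = rng.normal(size=(6, 30))
            query = rng.normal(size=30)
            cand = self._candidates(6)
            w = solve_mixture_weights(query, cand, e_a, np.ones(30, dtype=bool))
            obj = np.linalg.norm(w @ e_a - query)
            anchor_obj = np.linalg.norm(e_a[0] - query)
            assert obj <= anchor_obj + 1e-9

    def test_matches_grid_search_oracle(self, rng):
        # noiseless combinations on the 0.01 grid: the exhaustive search finds
        # the exact optimum, and the solver must match it
        mask = np.ones(20, dtype=bool)
        for _ in range(10):
            e_a = rng.normal(scale=3.0, size=(3, 20))
            true_w = rng.integers(0, 101, size=3).astype(float)
            true_w = np.round(true_w / true_w.sum(), 2)
            true_w[0] += 1.0 - true_w.sum()  # exact grid point summing to 1
            query = true_w @ e_a
            w = solve_mixture_weights(query, self._candidates(3), e_a, mask)
            solver_obj = np.linalg.norm(w @ e_a - query)
            grid_obj = _grid_search_simplex(e_a.T, query)
            assert abs(solver_obj - grid_obj) <= 1e-4

    def test_noisy_problems_beat_grid(self, rng):
        mask = np.ones(20, dtype=bool)
        for _ in range(5):
            e_a = rng.normal(size=(3, 20))
            query = rng.normal(size=20)
            w = solve_mixture_weights(query, self._candidates(3), e_a, mask)
            solver_obj = np.linalg.norm(w @ e_a - query)
            assert solver_obj <= _grid_search_simplex(e_a.T, query) + 1e-4


class TestProjection:
    def test_single_weight_is_identity(self, rng):
        e_a = rng.normal(size=(4, 10))
        e_p = project_expression(np.array([1.0]), np.array([2]), e_a)
        np.testing.assert_array_equal(e_p, e_a[2])

    def test_half_half_is_mean(self, rng):
        e_a = rng.normal(size=(2, 10))
        e_p = project_expression(np.array([0.5, 0.5]), np.array([0, 1]), e_a)
        np.testing.assert_allclose(e_p, e_a.mean(axis=0), atol=1e-12)

    def test_matches_scalar_weighted_mean(self, rng):
        e_a = rng.normal(size=(4, 6))
        w = rng.dirichlet(np.ones(4))
        e_p = project_expression(w, np.arange(4), e_a)
        for g in range(6):
            expected = sum(w[k] * e_a[k, g] for k in range(4))
            assert e_p[g] == pytest.approx(expected, abs=1e-12)

    def test_self_projection_recovers_self(self, small_atlas):
        prof = _cle(small_atlas.umis.astype(float))
        feat = np.array([g in small_atlas.masks.feature for g in small_atlas.gene_names])
        state = project_all(prof.log2e, prof.log2e, feat)
        n = small_atlas.n_metacells
        np.testing.assert_array_equal(state.anchors, np.arange(n))
        self_weights = state.weights[np.arange(n), np.arange(n)]
        assert np.all(self_weights > 0.99)

    def test_deterministic_bit_identical(self, small_atlas, small_query):
        query, _ = small_query
        qp = _cle(query.umis.astype(float))
        ap_ = _cle(small_atlas.umis.astype(float))
        feat = np.array([g in small_atlas.masks.feature for g in small_atlas.gene_names])
        s1 = project_all(qp.log2e, ap_.log2e, feat)
        s2 = project_all(qp.log2e, ap_.log2e, feat)
        assert np.array_equal(s1.weights, s2.weights)
        assert np.array_equal(s1.e_p, s2.e_p)

    def test_projection_within_candidate_hull(self, small_atlas, small_query):
        query, _ = small_query
        qp = _cle(query.umis.astype(float))
        ap_ = _cle(small_atlas.umis.astype(float))
        feat = np.array([g in small_atlas.masks.feature for g in small_atlas.gene_names])
        state = project_all(qp.log2e, ap_.log2e, feat)
        for i in range(query.n_metacells):
            members = state.candidates[i]
            lo = ap_.log2e[members].min(axis=0) - 1e-9
            hi = ap_.log2e[members].max(axis=0) + 1e-9
            assert np.all(state.e_p[i] >= lo) and np.all(state.e_p[i] <= hi)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_solver_simplex_invariants_property(seed):
    """For arbitrary problems the solution stays on the cleaned simplex."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 7))
    e_a = rng.normal(size=(k, 15))
    query = rng.normal(size=15)
    cand = CandidateSet(anchor=0, members=np.arange(k), distances=np.zeros(k))
    w = solve_mixture_weights(query, cand, e_a, np.ones(15, dtype=bool))
    assert w.shape == (k,)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(w >= 0)
    assert np.all((w == 0) | (w >= 1e-5))
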