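"""Multiplicative correction, range filtering, deviations, and type skew."""

import numpy as np
import pytest

from atlasproj import ProjectionConfig
from atlasproj.adjustment import (
    assign_types,
    compute_deviation,
    detect_type_skew,
    estimate_corrections,
    range_filter,
)


def _constant_ratio_case(ratio, fit_noise=0.0, rng=None):
    """Query/projection pair where the projection is `ratio` x the query fraction."""
    rng = rng or np.random.default_rng(0)
    n_mc, n_genes = 30, 5
    query = rng.uniform(1e-4, 1e-2, size=(n_mc, n_genes))
    projected = query * ratio
    if fit_noise:
        projected *= np.exp(rng.normal(0, fit_noise, size=projected.shape))
    e_q = np.log2(1e-5 + query)
    e_p = np.log2(1e-5 + projected)
    return query, projected, e_q, e_p


class TestEstimateCorrections:
    def test_constant_double_ratio_corrected(self):
        query, projected, e_q, e_p = _constant_ratio_case(2.0)
        state = estimate_corrections(query, projected, e_q, e_p, np.ones(5, dtype=bool))
        np.testing.assert_allclose(state.factor, 2.0, rtol=1e-9)
        assert state.corrected_mask.all()
        np.testing.assert_allclose(state.corrected_fractions, 2.0 * query)

    def test_low_fit_blocks_correction(self, rng):
        # projection uncorrelated with the query: fit well below 0.8
        query = rng.uniform(1e-4, 1e-2, size=(30, 5))
        projected = rng.permutation(query) * 2.0
        e_q = np.log2(1e-5 + query)
        e_p = np.log2(1e-5 + projected)
        state = estimate_corrections(query, projected, e_q, e_p, np.ones(5, dtype=bool))
        blocked = state.fit <= 0.8
        assert blocked.any()
        np.testing.assert_array_equal(state.factor[blocked], 1.0)

    def test_small_fold_blocks_correction(self):
        # perfectly correlated but only a 1.10x shift: below the 1.15 gate
        query, projected, e_q, e_p = _constant_ratio_case(1.10)
        state = estimate_corrections(query, projected, e_q, e_p, np.ones(5, dtype=bool))
        assert (state.fit > 0.95).all()
        np.testing.assert_array_equal(state.factor, 1.0)
        assert not state.corrected_mask.any()

    def test_ineligible_genes_never_corrected(self):
        query, projected, e_q, e_p = _constant_ratio_case(2.0)
        eligible = np.array([True, True, False, True, False])
        state = estimate_corrections(query, projected, e_q, e_p, eligible)
        np.testing.assert_array_equal(state.factor[~eligible], 1.0)
        np.testing.assert_allclose(state.factor[eligible], 2.0)

    def test_zero_expression_gene_factor_one(self):
        query, projected, e_q, e_p = _constant_ratio_case(2.0)
        query[:, 0] = 0.0
        state = estimate_corrections(query, projected, e_q, e_p, np.ones(5, dtype=bool))
        assert state.factor[0] == 1.0

    def test_correction_neutral_after_applying(self):
        # re-estimating on corrected data yields factors within the gate
        query, projected, e_q, e_p = _constant_ratio_case(2.0)
        state = estimate_corrections(query, projected, e_q, e_p, np.ones(5, dtype=bool))
        corrected = state.corrected_fractions
        e_c = np.log2(1e-5 + corrected)
        second = estimate_corrections(corrected, projected, e_c, e_p, np.ones(5, dtype=bool))
        assert not second.corrected_mask.any()
        assert np.all(np.abs(np.log(second.factor)) <= np.log(1.15) + 1e-12)


class TestRangeFilter:
    def _state(self, e_q, e_p):
        n = e_q.shape[1]
        return range_filter(e_q, e_p, np.ones(n, dtype=bool), np.zeros(n, dtype=bool))

    def test_identical_distributions_kept(self, rng):
        e = rng.normal(size=(50, 4))
        state = self._state(e, e)
        assert state.kept_mask.all()

    def test_shifted_range_filtered(self):
        # query range [0, 10], projected range [6, 20]: shared 4 < 5 -> dropped
        e_q = np.linspace(0, 10, 101)[:, None]
        e_p = np.linspace(6, 20, 101)[:, None]
        state = range_filter(
            e_q, e_p, np.ones(1, dtype=bool), np.zeros(1, dtype=bool), quantiles=(0.0, 1.0)
        )
        assert not state.kept_mask[0]

    def test_exactly_half_shared_kept(self):
        # shared range exactly 50% of the query range: strict "less than" keeps it
        e_q = np.linspace(0, 10, 101)[:, None]
        e_p = np.linspace(5, 15, 101)[:, None]
        state = range_filter(
            e_q, e_p, np.ones(1, dtype=bool), np.zeros(1, dtype=bool), quantiles=(0.0, 1.0)
        )
        assert state.kept_mask[0]

    def test_zero_query_range_kept(self):
        e_q = np.full((20, 1), 3.0)
        e_p = np.linspace(-5, 5, 20)[:, None]
        state = self._state(e_q, e_p)
        assert state.kept_mask[0]

    def test_exempt_genes_survive(self):
        e_q = np.linspace(0, 10, 101)[:, None]
        e_p = np.linspace(100, 110, 101)[:, None]
        state = range_filter(e_q, e_p, np.ones(1, dtype=bool), np.ones(1, dtype=bool))
        assert state.kept_mask[0]


class TestDeviation:
    def test_sixteen_fold_flagged(self):
        q = np.array([[16e-4]])
        p = np.array([[1e-4]])
        state = compute_deviation(q, p, np.array([100_000.0]))
        assert abs(state.lfold[0, 0]) > 3
        assert state.delta[0, 0]

    def test_identity_no_deviation(self, rng):
        q = rng.uniform(1e-4, 1e-2, size=(3, 4))
        state = compute_deviation(q, q, np.full(3, 50_000.0))
        np.testing.assert_array_equal(state.lfold, 0.0)
        assert not state.delta.any()

    def test_low_umi_evidence_suppressed(self):
        # |lfold| ~ 5 but the two profiles carry only ~30 summed UMIs
        q = np.array([[32e-5]])
        p = np.array([[1e-5]])
        state = compute_deviation(q, p, np.array([90_000.0]), min_umis=40)
        assert abs(state.lfold[0, 0]) > 3
        assert state.profile_umis[0, 0] < 40
        assert not state.delta[0, 0]

    def test_excluded_genes_never_evidence(self):
        q = np.array([[16e-4, 16e-4]])
        p = np.array([[1e-4, 1e-4]])
        state = compute_deviation(
            q, p, np.array([100_000.0]), excluded=np.array([False, True])
        )
        assert state.delta[0, 0] and not state.delta[0, 1]

    def test_delta_implies_both_gates(self, rng):
        q = rng.uniform(0, 1e-2, size=(10, 20))
        p = rng.uniform(0, 1e-2, size=(10, 20))
        state = compute_deviation(q, p, rng.uniform(1e4, 1e5, size=10))
        assert np.all(~state.delta | state.umi_ok)
        assert np.all(~state.delta | (np.abs(state.lfold) > 3))


class TestAssignTypes:
    def test_unanimous_type(self):
        w = np.array([[0.5, 0.5, 0.0]])
        assert assign_types(w, ["T-cell", "T-cell", "B-cell"]) == ["T-cell"]

    def test_majority_wins(self):
        w = np.array([[0.6, 0.4]])
        assert assign_types(w, ["A", "B"]) == ["A"]
        w = np.array([[0.4, 0.6]])
        assert assign_types(w, ["A", "B"]) == ["B"]

    def test_tie_goes_lexicographic(self):
        w = np.array([[0.5, 0.5]])
        assert assign_types(w, ["zeta", "alpha"]) == ["alpha"]


class TestTypeSkew:
    def _deviation(self, delta):
        delta = np.asarray(delta, dtype=bool)
        from atlasproj.adjustment import DeviationState

        return DeviationState(
            lfold=np.zeros(delta.shape),
            delta=delta,
            umi_ok=np.ones(delta.shape, dtype=bool),
            profile_umis=np.full(delta.shape, 100.0),
        )

    def test_three_of_four_skewed(self):
        delta = [[1], [1], [1], [0]]
        state = detect_type_skew(self._deviation(delta), ["t"] * 4, {"t": np.ones(1, dtype=bool)})
        assert state.skew["t"][0] == pytest.approx(0.75)
        assert state.skewed_genes["t"][0]

    def test_exactly_half_not_skewed(self):
        delta = [[1], [1], [0], [0]]
        state = detect_type_skew(self._deviation(delta), ["t"] * 4, {"t": np.ones(1, dtype=bool)})
        assert state.skew["t"][0] == pytest.approx(0.5)
        assert not state.skewed_genes["t"][0]

    def test_per_type_means_match_manual(self, rng):
        delta = rng.random((12, 6)) < 0.4
        types = ["a"] * 5 + ["b"] * 7
        fitted = {t: np.ones(6, dtype=bool) for t in "ab"}
        state = detect_type_skew(self._deviation(delta), types, fitted)
        np.testing.assert_allclose(state.skew["a"], delta[:5].mean(axis=0))
        np.testing.assert_allclose(state.skew["b"], delta[5:].mean(axis=0))

    def test_essential_genes_protected(self):
        delta = [[1, 1]] * 4
        protected = {"t": np.array([True, False])}
        state = detect_type_skew(
            self._deviation(delta),
            ["t"] * 4,
            {"t": np.ones(2, dtype=bool)},
            protected_by_type=protected,
        )
        assert not state.skewed_genes["t"][0]  # essential: stays fitted
        assert state.skewed_genes["t"][1]

    def test_unfitted_genes_not_skewed(self):
        delta = [[1, 1]] * 4
        fitted = {"t": np.array([True, False])}
        state = detect_type_skew(self._deviation(delta), ["t"] * 4, fitted)
        assert state.skewed_genes["t"][0]
        assert not state.skewed_genes["t"][1]


class TestConfig:
    def test_dotted_keys_map(self):
        cfg = ProjectionConfig.from_mapping(
            {"correction.enabled": True, "deviation.max_lfold": 2.0, "epsilon": 1e-4}
        )
        assert cfg.correct_genes and cfg.max_lfold == 2.0 and cfg.epsilon == 1e-4

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            ProjectionConfig.from_mapping({"no_such_key": 1})

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ProjectionConfig(epsilon=0.0)
        with pytest.raises(ValueError):
            ProjectionConfig(range_quantiles=(0.9, 0.1))
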