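"""Scoring transforms, triplet scoring, permutation nulls, comparator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from ceradys import (
    CohortParams,
    ScoringConfig,
    ScoringContext,
    edge_score,
    fisher_z,
    generate_cohort,
    node_score,
    permutation_pvalues,
    score_candidates,
    tail_transform,
    traditional_method,
    triplet_score,
)
from ceradys.cerna import CandidateConfig, find_candidates
from ceradys.dysregulation import _rowwise_corr


class TestTailTransform:
    def test_zero_maps_to_clamped_minimum(self):
        out = tail_transform(0.0, clamp_eps=1e-15)
        assert math.isfinite(out)
        assert out < -7  # Phi^-1(1e-15)

    @pytest.mark.parametrize(
        "d,expected,tol",
        [(1.30103, 0.866, 1e-3), (3.8055, 3.63, 5e-3)],
    )
    def test_reference_values(self, d, expected, tol):
        assert tail_transform(d) == pytest.approx(expected, abs=tol)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            tail_transform(-0.1)

    @given(st.floats(0.0, 6.0), st.floats(0.0, 6.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        # strict inside the unclamped region, non-strict at the clamps
        assert tail_transform(lo) <= tail_transform(hi)
        if 0 < lo and hi < 6 and tail_transform(hi) < 7:
            assert tail_transform(lo) < tail_transform(hi)


class TestNodeScore:
    def test_zero_fc_gives_clamped_minimum(self):
        assert node_score(0.5, 0.0) == tail_transform(0.0)

    def test_reference_value(self):
        # D = (-log10 0.01) * 2 = 4; expected value frozen from the
        # quadrature oracle (oracle.node_score(0.01, 2) = 3.832816)
        assert node_score(0.01, 2.0) == pytest.approx(3.832816, abs=1e-5)

    def test_monotone_in_significance(self):
        assert node_score(0.01, 1.0) < node_score(0.001, 1.0)

    def test_monotone_in_fold_change(self):
        assert node_score(0.01, 1.0) < node_score(0.01, 2.0)

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            node_score(1.5, 1.0)
        with pytest.raises(ValueError):
            node_score(0.0, 1.0)


class TestFisherZ:
    def test_matches_atanh_on_grid(self):
        r = np.arange(-0.99, 0.991, 0.01)
        assert np.max(np.abs(fisher_z(r) - np.arctanh(r))) < 1e-12

    def test_odd_function(self):
        assert fisher_z(-0.3) == pytest.approx(-fisher_z(0.3), abs=1e-15)

    def test_reference_value(self):
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_clamps_at_unity(self):
        assert math.isfinite(fisher_z(1.0)) and math.isfinite(fisher_z(-1.0))


class TestEdgeScore:
    def test_identical_states_give_zero_xi(self):
        xi, score = edge_score(0.4, 0.02, 30, 0.4, 0.02, 30)
        assert xi == pytest.approx(0.0, abs=1e-12)
        assert score == tail_transform(0.0)

    def test_reference_value(self):
        xi, score = edge_score(0.5, 0.01, 28, 0.1, 0.6, 28)
        assert xi == pytest.approx(-3.806, abs=2e-3)
        assert score == pytest.approx(3.63, abs=5e-3)

    def test_state_swap_negates_xi_keeps_score(self):
        xi1, s1 = edge_score(0.5, 0.01, 28, 0.1, 0.6, 20)
        xi2, s2 = edge_score(0.1, 0.6, 20, 0.5, 0.01, 28)
        assert xi1 == pytest.approx(-xi2, rel=1e-12)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            edge_score(0.5, 0.01, 3, 0.1, 0.6, 28)


class TestTripletScore:
    def test_equal_weight_is_mean_of_components(self):
        assert triplet_score([1, 1, 1], [2, 2, 2], omega=0.5) == pytest.approx(1.5)

    def test_omega_limits(self):
        assert triplet_score([1, 2, 3], [9, 9, 9], omega=1.0) == pytest.approx(2.0)
        assert triplet_score([1, 2, 3], [9, 9, 9], omega=0.0) == pytest.approx(9.0)

    def test_rejects_wrong_arity(self):
        with pytest.raises(ValueError):
            triplet_score([1, 2], [1, 2, 3])


def test_formulas_match_quadrature_oracle():
    """Implementation agrees with an independent quadrature-based
    transliteration of the score formulas on a randomized grid.

    Points are drawn from the region where a quadrature CDF can resolve
    the tail (|statistic| <~ 5): beyond that both routes saturate into
    the clamp and root-finding on the quadrature CDF loses precision.
    """
    rng = np.random.default_rng(42)
    n_pts = 300
    max_err = 0.0
    for _ in range(n_pts):
        d = rng.uniform(0.0, 3.0)
        max_err = max(max_err, abs(tail_transform(d) - oracle.tail_transform(d)))
        p = 10.0 ** rng.uniform(-2, 0)
        fc = rng.uniform(-2, 2)
        max_err = max(max_err, abs(node_score(p, fc) - oracle.node_score(p, fc)))
        r = rng.uniform(-0.95, 0.95)
        max_err = max(max_err, abs(fisher_z(r) - oracle.fisher_z(r)))
        r1, r2 = rng.uniform(-0.9, 0.9, 2)
        p1, p2 = 10.0 ** rng.uniform(-2, 0, 2)
        n1, n2 = rng.integers(10, 100, 2)
        xi, sc = edge_score(r1, p1, int(n1), r2, p2, int(n2))
        max_err = max(max_err, abs(xi - oracle.edge_xi(r1, p1, int(n1), r2, p2, int(n2))))
        if abs(xi) <= 5.0:
            max_err = max(max_err, abs(sc - oracle.edge_score(r1, p1, int(n1), r2, p2, int(n2))))
        nodes = rng.uniform(-2, 4, 3)
        edges = rng.uniform(-2, 4, 3)
        w = rng.uniform(0, 1)
        max_err = max(
            max_err,
            abs(triplet_score(nodes, edges, w) - oracle.triplet_score(nodes, edges, w)),
        )
    assert max_err < 1e-8


def test_rowwise_corr_matches_scipy():
    from scipy import stats

    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, (20, 15))
    b = rng.normal(0, 1, (20, 15))
    r, p = _rowwise_corr(a, b)
    for i in range(20):
        r_ref, p_ref = stats.pearsonr(a[i], b[i])
        assert r[i] == pytest.approx(r_ref, abs=1e-12)
        assert p[i] == pytest.approx(p_ref, rel=1e-9)


@pytest.fixture(scope="module")
def scored_cohort(default_cohort):
    co = default_cohort
    ctrl = co.control_samples
    cands = find_candidates(
        co.mrna.subset_samples(ctrl),
        co.lncrna.subset_samples(ctrl),
        co.mirna.subset_samples(ctrl),
        co.interactions,
        CandidateConfig(percentile_cut=0),
    )
    ctx = ScoringContext(co.mrna, co.lncrna, co.mirna, ctrl, co.case_samples)
    cfg = ScoringConfig(n_permutations=1000, seed=3)
    scored = score_candidates(cands, ctx, cfg)
    scored = permutation_pvalues(
        scored, (co.lncrna.gene_ids, co.mirna.gene_ids, co.mrna.gene_ids), ctx, cfg
    )
    return co, scored, ctx, cfg


class TestScoreCandidates:
    def test_planted_dysregulated_score_highest(self, scored_cohort):
        co, scored, _, _ = scored_cohort
        truth_dys = {(l, m, r) for l, m, r, d in co.truth.planted_triplets if d}
        ranked = sorted(scored, key=lambda t: t.score, reverse=True)
        top = {t.ids for t in ranked[: len(truth_dys)]}
        assert top == truth_dys

    def test_all_components_finite(self, scored_cohort):
        _, scored, _, _ = scored_cohort
        for t in scored:
            assert all(math.isfinite(v) for v in t.node_scores)
            assert all(math.isfinite(v) for v in t.edge_scores)
            assert math.isfinite(t.score)

    def test_equal_weight_score_is_mean_of_six(self, scored_cohort):
        _, scored, _, _ = scored_cohort
        for t in scored:
            mean6 = np.mean(list(t.node_scores) + list(t.edge_scores))
            assert t.score == pytest.approx(mean6, rel=1e-12)


class TestPermutationPvalues:
    def test_p_is_multiple_of_permutation_unit(self, scored_cohort):
        _, scored, _, cfg = scored_cohort
        for t in scored:
            assert (t.empirical_p * cfg.n_permutations) == pytest.approx(
                round(t.empirical_p * cfg.n_permutations), abs=1e-9
            )

    def test_planted_dysregulated_flagged(self, scored_cohort):
        co, scored, _, _ = scored_cohort
        truth_dys = {(l, m, r) for l, m, r, d in co.truth.planted_triplets if d}
        flagged = {t.ids for t in scored if t.dysregulated}
        assert truth_dys <= flagged

    def test_same_seed_reproduces_pvalues(self, scored_cohort):
        co, scored, ctx, cfg = scored_cohort
        again = permutation_pvalues(
            [t for t in scored],
            (co.lncrna.gene_ids, co.mirna.gene_ids, co.mrna.gene_ids),
            ctx, cfg,
        )
        assert [t.empirical_p for t in again] == [t.empirical_p for t in scored]

    def test_empty_pool_rejected(self, scored_cohort):
        co, scored, ctx, cfg = scored_cohort
        with pytest.raises(ValueError):
            permutation_pvalues(scored, ([], co.mirna.gene_ids, co.mrna.gene_ids), ctx, cfg)


class TestTraditionalMethod:
    def test_recovers_decoupled_sde_triplets(self):
        # large shift ensures all three members are SDE; decoupling breaks
        # the competing link in cases
        co = generate_cohort(CohortParams(delta=2.0, seed=7))
        truth_dys = {(l, m, r) for l, m, r, d in co.truth.planted_triplets if d}
        found = traditional_method(
            co.mrna, co.lncrna, co.mirna,
            co.control_samples, co.case_samples, co.interactions,
        )
        assert truth_dys <= {t.ids for t in found}

    def test_intact_triplets_excluded(self):
        co = generate_cohort(CohortParams(delta=2.0, seed=7))
        intact = {(l, m, r) for l, m, r, d in co.truth.planted_triplets if not d}
        found = {t.ids for t in traditional_method(
            co.mrna, co.lncrna, co.mirna,
            co.control_samples, co.case_samples, co.interactions,
        )}
        # intact triplets keep their positive lncRNA-mRNA correlation in cases
        assert not (intact & found)
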