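import math

import numpy as np
import pytest
from scipy.stats import chi2

from otunet import (
    AssociationMatrix,
    EnsembleParams,
    OtuTable,
    PlantedDesign,
    bh_adjust,
    bootstrap_p,
    brown_merge,
    infer_network,
    select_candidates,
    simulate_null_table,
    simulate_table,
    vote,
)
from otunet.ensemble import EdgeCandidate
from otunet.filters import FilterParams
from otunet.tables_io import ValidationError


class TestEnsembleParams:
    def test_min_support_bounded_by_method_count(self):
        with pytest.raises(ValidationError):
            EnsembleParams(min_support=6)
        with pytest.raises(ValidationError):
            EnsembleParams(min_support=0)

    def test_alpha_in_open_interval(self):
        with pytest.raises(ValidationError):
            EnsembleParams(alpha=0.0)


def _matrix(method, polarity, pair_scores):
    """Build a 4-taxon AssociationMatrix with the given 4 pair scores.

    Scores fill pairs (t0,t1), (t0,t2), (t0,t3), (t1,t2); the remaining two
    pairs are NaN (undefined) so exactly four candidates exist.
    """
    ids = ["t0", "t1", "t2", "t3"]
    scores = np.full((4, 4), np.nan)
    np.fill_diagonal(scores, 1.0 if polarity == "similarity" else 0.0)
    locations = [(0, 1), (0, 2), (0, 3), (1, 2)]
    for (i, j), s in zip(locations, pair_scores):
        scores[i, j] = scores[j, i] = s
    return AssociationMatrix(method, scores, polarity, ids)


class TestSelectCandidates:
    def test_top_and_bottom_split_for_similarity(self):
        mat = _matrix("pearson", "similarity", [0.9, 0.5, -0.2, -0.8])
        cands = select_candidates(mat, top_k=2)
        cop = {c.score for c in cands if c.sign == "copresence"}
        exc = {c.score for c in cands if c.sign == "exclusion"}
        assert cop == {0.9, 0.5} and exc == {-0.2, -0.8}

    def test_dissimilarity_polarity_reversed(self):
        mat = _matrix("bray_curtis", "dissimilarity", [0.05, 0.4, 0.6, 0.95])
        cands = select_candidates(mat, top_k=1)
        cop = [c for c in cands if c.sign == "copresence"]
        exc = [c for c in cands if c.sign == "exclusion"]
        assert cop[0].score == 0.05 and exc[0].score == 0.95

    def test_saturation_when_top_k_exceeds_pairs(self):
        mat = _matrix("spearman", "similarity", [0.9, 0.5, -0.2, -0.8])
        cands = select_candidates(mat, top_k=100)
        # every finite pair appears once per direction class
        assert len(cands) == 8
        assert len({(c.pair, c.sign) for c in cands}) == 8

    def test_nan_scores_never_nominated(self):
        mat = _matrix("pearson", "similarity", [0.9, 0.5, -0.2, -0.8])
        pairs = {c.pair for c in select_candidates(mat, top_k=100)}
        assert ("t1", "t3") not in pairs and ("t2", "t3") not in pairs

    def test_deterministic_tie_break_is_lexicographic(self):
        mat = _matrix("pearson", "similarity", [0.5, 0.5, 0.5, 0.5])
        top = [c for c in select_candidates(mat, top_k=2) if c.sign == "copresence"]
        assert [c.pair for c in top] == [("t0", "t1"), ("t0", "t2")]


def _cand(pair, method, sign, score=0.5):
    return EdgeCandidate(pair, method, score, sign)


class TestVote:
    def test_three_way_support_kept(self):
        cands = [
            _cand(("a", "b"), m, "copresence")
            for m in ("pearson", "spearman", "steinhaus")
        ]
        result = vote(cands, min_support=3)
        assert result == [(("a", "b"), "copresence", frozenset({"pearson", "spearman", "steinhaus"}))]

    def test_two_methods_dropped(self):
        cands = [_cand(("a", "b"), m, "copresence") for m in ("pearson", "spearman")]
        assert vote(cands, min_support=3) == []

    def test_sign_conflict_two_two_dropped(self):
        cands = [
            _cand(("a", "b"), "pearson", "copresence"),
            _cand(("a", "b"), "spearman", "copresence"),
            _cand(("a", "b"), "bray_curtis", "exclusion"),
            _cand(("a", "b"), "kl_sym", "exclusion"),
        ]
        assert vote(cands, min_support=2) == []

    def test_majority_sign_wins(self):
        cands = [
            _cand(("a", "b"), m, "copresence")
            for m in ("pearson", "spearman", "steinhaus")
        ] + [
            _cand(("a", "b"), m, "exclusion") for m in ("bray_curtis", "kl_sym")
        ]
        result = vote(cands, min_support=3)
        assert len(result) == 1 and result[0][1] == "copresence"

    def test_method_counted_once_per_sign(self):
        cands = [
            _cand(("a", "b"), "pearson", "copresence", 0.9),
            _cand(("a", "b"), "pearson", "copresence", 0.8),
        ]
        assert vote(cands, min_support=2) == []


class TestBootstrapP:
    def test_identical_vectors_pearson_limit(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 100, size=40)
        t = OtuTable(["a", "b"], [f"s{i}" for i in range(40)],
                     np.vstack([x, x]))
        res = bootstrap_p(t, ("a", "b"), "pearson", EnsembleParams(seed=4))
        assert res.boot_mean == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_planted_pair_significant(self):
        d = PlantedDesign(
            n_taxa=20, groups=[("placebo", 100)], timepoints=[0, 9],
            depth_mean=5000.0, copresence_pairs=[(3, 4, 1.0)], seed=11,
        )
        table, _, truth = simulate_table(d)
        pair = (truth[0][0], truth[0][1])
        for method in ("pearson", "spearman"):
            res = bootstrap_p(table, pair, method, EnsembleParams(seed=11))
            assert res.p < 0.01

    def test_null_pairs_not_overconfident(self):
        """p-values on independent pairs behave no worse than uniform."""
        table = simulate_null_table(25, 60, 5000, seed=9)
        params = EnsembleParams(seed=9)
        small = 0
        pairs = [(i, j) for i in range(10) for j in range(10, 15)]
        for i, j in pairs[:50]:
            res = bootstrap_p(table, (i, j), "spearman", params)
            if np.isfinite(res.p) and res.p < 0.1:
                small += 1
        assert small <= 10

    def test_determinism(self):
        table = simulate_null_table(10, 30, 2000, seed=3)
        a = bootstrap_p(table, (0, 1), "bray_curtis", EnsembleParams(seed=5))
        b = bootstrap_p(table, (0, 1), "bray_curtis", EnsembleParams(seed=5))
        assert a.p == b.p and a.boot_mean == b.boot_mean


class TestBrownMerge:
    def test_reduces_to_fisher_without_covariance(self):
        p = {"pearson": 0.05, "spearman": 0.05}
        x = -2 * (math.log(0.05) + math.log(0.05))
        expected = chi2.sf(x, 4)
        assert brown_merge(p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0175, abs=2e-4)

    def test_fisher_reduction_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            k = rng.integers(2, 6)
            ps = rng.uniform(1e-6, 1.0, size=k)
            p_map = {f"m{i}": float(v) for i, v in enumerate(ps)}
            fisher = chi2.sf(-2 * np.log(ps).sum(), 2 * k)
            assert brown_merge(p_map) == pytest.approx(fisher, rel=1e-10)

    def test_duplicated_method_collapses_to_single_p(self):
        rng = np.random.default_rng(2)
        pseudo = rng.uniform(0.01, 0.99, size=100)
        for p in (0.3, 0.04, 1e-5):
            merged = brown_merge(
                {"a": p, "b": p}, {"a": pseudo, "b": pseudo.copy()}
            )
            assert merged == pytest.approx(p, rel=1e-9)

    def test_single_p_returned_unchanged(self):
        assert brown_merge({"only": 0.123}) == 0.123

    def test_zero_p_floored(self):
        merged = brown_merge({"a": 0.0, "b": 0.5})
        assert 0.0 < merged < 1e-100


class TestBhAdjust:
    def test_hand_step_up_example(self):
        q, keep = bh_adjust([0.01, 0.02, 0.04, 0.05], alpha=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.05, 0.05])
        assert keep.tolist() == [True, True, False, False]  # strict q < alpha

    def test_single_p_unchanged(self):
        q, keep = bh_adjust([0.03], alpha=0.05)
        assert q[0] == pytest.approx(0.03) and keep[0]

    def test_all_ones(self):
        q, keep = bh_adjust([1.0, 1.0, 1.0], alpha=0.05)
        assert (q == 1.0).all() and not keep.any()

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 20))
            q, _ = bh_adjust(p, alpha=0.05)
            expected = sm.multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_n_total_equals_padding_with_ones(self):
        p = [0.001, 0.01, 0.2]
        q_pad, _ = bh_adjust(p + [1.0] * 7, alpha=0.05)
        q_tot, _ = bh_adjust(p, alpha=0.05, n_total=10)
        np.testing.assert_allclose(q_tot, q_pad[:3])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestInferNetwork:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        d = PlantedDesign(
            n_taxa=20, groups=[("synbiotic", 20)], timepoints=[0, 9],
            depth_mean=5000.0,
            copresence_pairs=[(3, 4, 1.0)], exclusion_pairs=[(6, 7, 1.0)],
            seed=21,
        )
        return simulate_table(d)

    def test_recovers_planted_edges_with_signs(self, planted):
        table, meta, truth = planted
        params = EnsembleParams(top_k=4, n_bootstrap=50, n_permutation=50, seed=21)
        net = infer_network(table, meta, "synbiotic", FilterParams(), params)
        truth_map = {(a, b): s for a, b, s in truth}
        recovered = {e.pair: e.sign for e in net.edges}
        for pair, sign in truth_map.items():
            assert recovered.get(pair) == sign

    def test_deterministic_under_seed(self, planted):
        table, meta, _ = planted
        params = EnsembleParams(top_k=4, n_bootstrap=30, n_permutation=30, seed=8)
        a = infer_network(table, meta, "synbiotic", FilterParams(), params)
        b = infer_network(table, meta, "synbiotic", FilterParams(), params)
        assert a == b

    def test_edge_invariants(self, planted):
        table, meta, _ = planted
        params = EnsembleParams(top_k=4, n_bootstrap=30, n_permutation=30, seed=8)
        net = infer_network(table, meta, "synbiotic", FilterParams(), params)
        for e in net.edges:
            assert len(e.supporting_methods) >= params.min_support
            assert set(e.p_method) == set(e.supporting_methods)
            assert 0.0 <= e.p_brown <= 1.0
            assert e.q_bh >= e.p_brown - 1e-15

    def test_too_few_samples_rejected(self, planted):
        table, meta, _ = planted
        two = table.select_samples(table.sample_ids[:2])
        with pytest.raises(ValidationError):
            infer_network(two, meta, "synbiotic", FilterParams(), EnsembleParams(seed=1))
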