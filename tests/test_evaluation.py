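import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mirflow import (
    AssociationTable,
    ModelParams,
    SimilarityMatrix,
    ab_initio_cv,
    ablation,
    f1_optimal_threshold,
    grid_search,
    hypergeometric_enrichment,
    loocv,
    permutation_experiment,
    permute_layer,
    roc_pr_from_ranks,
)
from mirflow.synthetic import BenchmarkSpec, generate_benchmark

from conftest import EMPTY_SETS

SMALL_SPEC = BenchmarkSpec(n_mirna=20, n_disease=12, n_modules=3, seed=5)
FAST_PARAMS = ModelParams(gamma=10.0)


@pytest.fixture(scope="module")
def small_bench():
    return generate_benchmark(SMALL_SPEC)


class TestRocPr:
    def test_perfect_separation_gives_auc_one(self):
        roc, pr = roc_pr_from_ranks([0.1, 0.2], [0.5, 0.6, 0.9])
        assert roc.auc == pytest.approx(1.0)
        assert pr.auc == pytest.approx(1.0, abs=1e-9)

    def test_roc_endpoints(self):
        roc, _ = roc_pr_from_ranks([0.1, 0.7], [0.3, 0.6])
        assert (roc.points[0] == (0.0, 0.0)).all()
        assert (roc.points[-1] == (1.0, 1.0)).all()
        assert np.all(np.diff(roc.x) >= 0) and np.all(np.diff(roc.y) >= 0)

    def test_auc_equals_mann_whitney_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pos = rng.random(rng.integers(2, 30))
            neg = rng.random(rng.integers(2, 30))
            if rng.random() < 0.3:  # force ties between the groups
                k = min(pos.size, neg.size) // 2
                neg[:k] = pos[:k]
            roc, _ = roc_pr_from_ranks(pos, neg)
            u = mannwhitneyu(-pos, -neg, alternative="two-sided").statistic
            assert roc.auc == pytest.approx(u / (pos.size * neg.size), abs=1e-12)

    def test_same_distribution_gives_half(self):
        rng = np.random.default_rng(7)
        roc, _ = roc_pr_from_ranks(rng.random(10_000), rng.random(10_000))
        assert roc.auc == pytest.approx(0.5, abs=0.02)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_from_ranks([], [0.5])
        with pytest.raises(ValueError):
            roc_pr_from_ranks([0.5], [])


class TestF1Threshold:
    def test_perfect_separation(self):
        cut, f1 = f1_optimal_threshold([0.1, 0.2], [0.5, 0.9])
        assert f1 == pytest.approx(1.0)
        assert 0.2 <= cut < 0.5

    def test_hand_enumerated_example(self):
        cut, f1 = f1_optimal_threshold(
            [0.1, 0.2, 0.3, 0.9], [0.4, 0.6, 0.7, 0.8]
        )
        assert f1 == pytest.approx(6 / 7)
        assert cut == pytest.approx(0.3)

    def test_harmonic_mean_identity(self):
        # 1 of 2 positives and 1 of 2 negatives below the cut:
        # precision = recall = 0.5 -> F1 = 0.5
        pos, neg = [0.1, 0.9], [0.2, 0.95]
        cuts = sorted(set(pos + neg))
        tp = sum(p <= 0.2 for p in pos)
        assert tp == 1
        _, f1 = f1_optimal_threshold(pos, neg)
        assert f1 >= 0.5  # optimum can only improve on the identity cut


class TestLoocv:
    def test_single_association_fold_outcomes(self):
        m = SimilarityMatrix(
            ["m1", "m2"], np.array([[1.0, 0.8], [0.8, 1.0]])
        )
        d = SimilarityMatrix(["d1"], np.array([[1.0]]))
        assoc = AssociationTable.from_pairs([("m1", "d1")])
        params = ModelParams(alpha=0.1, beta=0.1, gamma=1.0)
        result = loocv(assoc, m, d, EMPTY_SETS, EMPTY_SETS, params)
        assert len(result.folds) == 1
        fold = result.folds[0]
        assert fold.n_candidates == 2
        assert fold.rank in (1, 2)
        assert 0.0 < fold.rank_ratio <= 1.0

    def test_fold_count_and_ratio_range(self, small_bench):
        result = loocv(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
        )
        assert len(result.folds) == len(small_bench.assoc)
        assert np.all(result.positives > 0) and np.all(result.positives <= 1)
        assert np.all(result.negatives > 0) and np.all(result.negatives <= 1)

    def test_thresholding_at_one_captures_everything(self, small_bench):
        result = loocv(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
        )
        cut = 1.0
        tpr = np.mean(result.positives <= cut)
        fpr = np.mean(result.negatives <= cut)
        assert tpr == 1.0 and fpr == 1.0

    def test_random_candidate_pool_size(self, small_bench):
        result = loocv(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
            candidate_pool=5, seed=3,
        )
        assert all(f.n_candidates == 6 for f in result.folds)  # pool + held-out

    def test_oversized_pool_rejected(self, small_bench):
        with pytest.raises(ValueError):
            loocv(
                small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
                small_bench.families, small_bench.clusters, FAST_PARAMS,
                candidate_pool=10_000,
            )

    def test_disease_mode_runs_symmetrically(self, small_bench):
        result = loocv(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
            mode="disease",
        )
        assert len(result.folds) == len(small_bench.assoc)
        held = {f.held_out_id for f in result.folds}
        assert held <= set(small_bench.disease_sim.labels)


class TestAbInitio:
    def test_single_association_query_matches_loocv(self):
        # every disease here has exactly one association, so removing "all
        # links of the query" removes exactly the held-out link
        m = SimilarityMatrix(
            ["m1", "m2", "m3"],
            np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]]),
        )
        d = SimilarityMatrix(
            ["d1", "d2"], np.array([[1.0, 0.6], [0.6, 1.0]])
        )
        assoc = AssociationTable.from_pairs([("m1", "d1"), ("m2", "d2")])
        params = ModelParams(alpha=0.1, beta=0.1, gamma=1.0)
        a = loocv(assoc, m, d, EMPTY_SETS, EMPTY_SETS, params)
        b = ab_initio_cv(assoc, m, d, EMPTY_SETS, EMPTY_SETS, params)
        assert [f.rank for f in a.folds] == [f.rank for f in b.folds]
        assert a.auc == pytest.approx(b.auc)

    def test_harder_than_loocv_on_planted_benchmark(self, small_bench):
        lo = loocv(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
        )
        ab = ab_initio_cv(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
        )
        assert ab.auc <= lo.auc + 0.05  # isolated queries cannot do better


class TestPermutation:
    def test_zero_reps_rejected(self, small_bench):
        with pytest.raises(ValueError):
            permutation_experiment(
                small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
                small_bench.families, small_bench.clusters, FAST_PARAMS,
                n_reps=0,
            )

    @pytest.mark.parametrize("layer", ["associations", "mirna_sim", "disease_sim"])
    def test_permutation_preserves_edge_counts(self, small_bench, layer):
        rng = np.random.default_rng(0)
        m, d, a = permute_layer(
            layer, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.assoc, rng,
        )
        assert len(a) == len(small_bench.assoc)
        for original, permuted in ((small_bench.mirna_sim, m),
                                   (small_bench.disease_sim, d)):
            for threshold in (0.1, 0.4, 0.7):
                iu = np.triu_indices(len(original.labels), k=1)
                assert (
                    (permuted.values[iu] >= threshold).sum()
                    == (original.values[iu] >= threshold).sum()
                )

    def test_unknown_layer_rejected(self, small_bench):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            permute_layer(
                "bogus", small_bench.mirna_sim, small_bench.disease_sim,
                small_bench.assoc, rng,
            )


class TestAblation:
    def test_dropping_associations_zeroes_every_fold(self, small_bench):
        result = ablation(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
            drop="associations",
        )
        # with no association edges nothing flows; every fold is a full tie
        # and the midpoint convention maps it to exactly 0.5
        for fold in result.folds:
            assert fold.rank_ratio == pytest.approx(0.5)
        assert result.auc == pytest.approx(0.5)

    def test_dropping_disease_sim_keeps_association_edges(self, small_bench):
        full = loocv(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
        )
        dropped = ablation(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters, FAST_PARAMS,
            drop="disease_sim",
        )
        assert len(dropped.folds) == len(full.folds)

    def test_unknown_layer_rejected(self, small_bench):
        with pytest.raises(ValueError):
            ablation(
                small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
                small_bench.families, small_bench.clusters, FAST_PARAMS,
                drop="bogus",
            )


class TestGridSearch:
    def test_single_point_grid_returns_it(self, small_bench):
        best, table = grid_search(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters,
            grid={"alpha": [0.3]}, base_params=FAST_PARAMS,
        )
        assert best.alpha == 0.3
        assert len(table) == 1

    def test_table_covers_cartesian_product(self, small_bench):
        _, table = grid_search(
            small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
            small_bench.families, small_bench.clusters,
            grid={"alpha": [0.2, 0.5], "beta": [0.3, 0.6]},
            base_params=FAST_PARAMS,
        )
        assert len(table) == 4
        assert set(table.columns) == {"alpha", "beta", "auc"}

    def test_empty_grid_rejected(self, small_bench):
        with pytest.raises(ValueError):
            grid_search(
                small_bench.assoc, small_bench.mirna_sim, small_bench.disease_sim,
                small_bench.families, small_bench.clusters, grid={},
            )


class TestHypergeometric:
    def test_zero_overlap_gives_one(self):
        assert hypergeometric_enrichment(0, 5, 5, 10) == 1.0

    def test_exact_combinatorial_value(self):
        # all 5 draws annotated: C(5,5)*C(5,0)/C(10,5) = 1/252
        assert hypergeometric_enrichment(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            big_n = int(rng.integers(1, 61))
            big_k = int(rng.integers(0, big_n + 1))
            n = int(rng.integers(0, big_n + 1))
            k = int(rng.integers(0, min(n, big_k) + 1))
            expected = sum(
                math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
                for i in range(k, min(n, big_k) + 1)
                if n - i <= big_n - big_k
            ) / math.comb(big_n, n)
            assert hypergeometric_enrichment(k, n, big_k, big_n) == pytest.approx(
                expected, rel=1e-9
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 5, 11, 10)
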