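"""Newick handling, neighbor joining, Faith's PD and Pagel's lambda."""

import numpy as np
import pandas as pd
import pytest

import oracles
from micronet import phylo_metrics as pm
from micronet.synthetic_data import simulate_bm_trait, simulate_yule_tree


class TestNewick:
    def test_parse_simple(self):
        tree = pm.parse_newick("(A:1,B:2);")
        assert sorted(pm.tip_labels(tree)) == ["A", "B"]
        C = pm.shared_path_matrix(tree)
        assert C.at["A", "A"] == 1.0 and C.at["B", "B"] == 2.0

    def test_depths(self):
        tree = pm.parse_newick("((A:1,B:1):0.5,C:2);")
        C = pm.shared_path_matrix(tree)
        assert C.at["C", "C"] == 2.0
        assert C.at["A", "A"] == 1.5
        assert C.at["A", "B"] == 0.5 and C.at["A", "C"] == 0.0

    def test_round_trip_preserves_distances(self):
        tree = simulate_yule_tree(50, seed=42)
        back = pm.parse_newick(pm.write_newick(tree))
        d0 = pm.patristic_distance_matrix(tree)
        d1 = pm.patristic_distance_matrix(back).loc[d0.index, d0.columns]
        np.testing.assert_allclose(d0.to_numpy(), d1.to_numpy(), atol=1e-8)

    def test_malformed_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            pm.parse_newick("((A:1,B:2;")


class TestNeighborJoining:
    def test_three_taxon_exact_solution(self):
        # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> branch lengths a=1, b=2, c=3
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = pm.neighbor_joining(D)
        got = pm.patristic_distance_matrix(tree).loc[list("ABC"), list("ABC")]
        np.testing.assert_allclose(got.to_numpy(), D.to_numpy(), atol=1e-9)

    def test_additive_matrix_recovered_exactly(self):
        gen = pm.parse_newick("((A:1,B:2):0.5,(C:0.7,(D:1.1,E:0.4):0.3):0.9);")
        D = pm.patristic_distance_matrix(gen)
        rec = pm.neighbor_joining(D)
        got = pm.patristic_distance_matrix(rec).loc[D.index, D.columns]
        np.testing.assert_allclose(got.to_numpy(), D.to_numpy(), atol=1e-9)

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        gen = simulate_yule_tree(8, seed=5)
        D = pm.patristic_distance_matrix(gen)
        ours = pm.patristic_distance_matrix(pm.neighbor_joining(D))
        dm = skbio.DistanceMatrix(D.to_numpy(), ids=list(D.index))
        ref_tree = skbio.tree.nj(dm)
        ref = pd.DataFrame(
            [[ref_tree.find(a).distance(ref_tree.find(b)) for b in D.columns] for a in D.index],
            index=D.index, columns=D.columns,
        )
        np.testing.assert_allclose(
            ours.loc[D.index, D.columns].to_numpy(), ref.to_numpy(), atol=1e-6
        )

    def test_equal_distances_give_equal_paths(self):
        n = 5
        labels = [f"t{i}" for i in range(n)]
        D = pd.DataFrame(2.0 * (1 - np.eye(n)), index=labels, columns=labels)
        tree = pm.neighbor_joining(D)
        got = pm.patristic_distance_matrix(tree).loc[labels, labels].to_numpy()
        np.testing.assert_allclose(got[~np.eye(n, dtype=bool)], 2.0, atol=1e-9)

    def test_rejects_asymmetric(self):
        D = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            pm.neighbor_joining(D)


class TestFaithPD:
    def test_examples_on_balanced_tree(self, balanced_tree4):
        assert pm.faith_pd(balanced_tree4, {"A", "C"}) == pytest.approx(4.0)
        assert pm.faith_pd(balanced_tree4, {"A", "B", "C", "D"}) == pytest.approx(6.0)
        assert pm.faith_pd(balanced_tree4, {"A"}) == pytest.approx(2.0)  # rooted PD

    def test_unknown_taxon_lists_missing(self, balanced_tree4):
        with pytest.raises(KeyError, match="Z"):
            pm.faith_pd(balanced_tree4, {"A", "Z"})

    def test_matches_bruteforce_and_monotone(self, rng):
        tree = simulate_yule_tree(16, seed=9)
        tips = pm.tip_labels(tree)
        prev = set()
        last_pd = 0.0
        for t in rng.permutation(tips):
            prev = prev | {str(t)}
            pd_val = pm.faith_pd(tree, prev)
            assert pd_val == pytest.approx(oracles.faith_pd_bruteforce(tree, prev), abs=1e-9)
            assert pd_val >= last_pd - 1e-12
            last_pd = pd_val


class TestPagelsLambda:
    def test_loglik_at_hat_dominates_grid(self):
        tree = simulate_yule_tree(40, seed=11)
        trait = simulate_bm_trait(tree, 0.6, 1.0, seed=12)
        fit = pm.pagels_lambda(tree, trait)
        C = pm.shared_path_matrix(tree).to_numpy()
        y = np.array([trait[t] for t in pm.shared_path_matrix(tree).index])
        for lam in np.linspace(0, 1, 11):
            ll = pm._lambda_loglik(lam, C, y)[0]
            assert fit.loglik_at_hat >= ll - 1e-6
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert fit.loglik_at_hat >= max(fit.loglik_at_0, fit.loglik_at_1) - 1e-6

    def test_permuted_trait_destroys_signal(self):
        lams = []
        for s in range(10):
            tree = simulate_yule_tree(80, seed=300 + s)
            trait = simulate_bm_trait(tree, 1.0, 1.0, seed=400 + s)
            rng = np.random.default_rng(s)
            tips = list(trait)
            vals = rng.permutation([trait[t] for t in tips])
            fit = pm.pagels_lambda(tree, dict(zip(tips, vals)))
            lams.append(fit.lambda_hat)
        assert np.mean(lams) < 0.1

    def test_star_tree_flagged_nonidentifiable(self):
        star = pm.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        fit = pm.pagels_lambda(star, {t: float(i) for i, t in enumerate("ABCDE")})
        assert not fit.identifiable
        assert np.isnan(fit.lambda_hat)

    def test_too_few_tips_error(self, balanced_tree4):
        with pytest.raises(ValueError, match=">= 4 tips"):
            pm.pagels_lambda(balanced_tree4, {"A": 1.0, "B": 2.0})

    def test_lrt_pvalue_in_unit_interval(self):
        tree = simulate_yule_tree(40, seed=21)
        fit = pm.pagels_lambda(tree, simulate_bm_trait(tree, 1.0, 1.0, seed=22))
        assert 0.0 <= pm.lambda_lrt_pvalue(fit) <= 1.0


class TestPrevalence:
    def test_fractions(self, tiny_matrix):
        prev = pm.prevalence(tiny_matrix)
        assert prev == {"a": 1.0, "b": pytest.approx(2 / 3), "c": pytest.approx(1 / 3)}

    def test_empty_stratum_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="empty stratum"):
            pm.prevalence(tiny_matrix, carrier="vole")
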