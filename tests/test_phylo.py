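"""Phylogenetic signal, D-PGLS, and convergence measures."""

import numpy as np
import pytest

from cerebrotype import (PhyloTree, convergence_c_measures, k_mult,
                         pgls_shape_regression, phylo_procrustes_anova,
                         simulate_tree)
from cerebrotype.phylo import (_c_measures_from_states, _inv_sqrt,
                               ancestral_states_bm)


def _star(n):
    tips = ",".join(f"t{i}:1" for i in range(n))
    return PhyloTree.from_newick(f"({tips});")


class TestKmult:
    def test_star_tree_gives_exactly_one(self, rng):
        """With C = I both the observed/Brownian ratio and its expectation
        are 1, so K = 1 identically, whatever the data."""
        tree = _star(10)
        Y = rng.normal(size=(10, 6))
        res = k_mult(Y, tree, species=tree.tip_labels, permutations=19,
                     seed=0)
        assert res.K == pytest.approx(1.0, abs=1e-12)

    def test_brownian_data_centres_on_one(self, rng):
        """BM-evolved traits should average K near 1 over replicates."""
        tree = simulate_tree(30, seed=3)
        species = tree.tip_labels
        C = tree.covariance(species)
        L = np.linalg.cholesky(C)
        ks = []
        for _ in range(60):
            Y = L @ rng.normal(size=(30, 8))
            ks.append(k_mult(Y, tree, species=species, permutations=0
                             if False else 9, seed=1).K)
        assert np.mean(ks) == pytest.approx(1.0, abs=0.1)

    def test_shuffled_tips_lose_signal(self, rng):
        tree = simulate_tree(25, seed=5)
        species = tree.tip_labels
        C = tree.covariance(species)
        L = np.linalg.cholesky(C)
        Y = L @ rng.normal(size=(25, 6))
        strong = k_mult(Y, tree, species=species, permutations=199, seed=2)
        perm = rng.permutation(25)
        weak = k_mult(Y[perm], tree, species=species, permutations=199,
                      seed=2)
        assert strong.p < 0.05
        assert weak.K < strong.K

    def test_seeded_runs_identical(self, rng):
        tree = simulate_tree(12, seed=1)
        Y = rng.normal(size=(12, 4))
        a = k_mult(Y, tree, species=tree.tip_labels, permutations=99, seed=7)
        b = k_mult(Y, tree, species=tree.tip_labels, permutations=99, seed=7)
        assert (a.K, a.p) == (b.K, b.p)

    def test_p_value_bounds(self, rng):
        tree = simulate_tree(10, seed=2)
        Y = rng.normal(size=(10, 3))
        res = k_mult(Y, tree, species=tree.tip_labels, permutations=49,
                     seed=0)
        assert 1 / 50 <= res.p <= 1.0


class TestInvSqrt:
    def test_is_inverse_square_root(self, rng):
        A = rng.normal(size=(6, 6))
        C = A @ A.T + 6 * np.eye(6)
        P = _inv_sqrt(C)
        np.testing.assert_allclose(P @ C @ P, np.eye(6), atol=1e-10)
        np.testing.assert_allclose(P, P.T, atol=1e-12)


class TestDPGLS:
    def test_star_tree_regression_equals_ols(self, rng):
        """On a star tree the GLS transform is the identity, so the fit
        must match an ordinary multivariate least-squares oracle."""
        n, p = 16, 5
        tree = _star(n)
        x = rng.normal(size=n)
        Y = np.outer(x, rng.normal(size=p)) + rng.normal(size=(n, p))
        res = pgls_shape_regression(Y, x, tree, species=tree.tip_labels,
                                    permutations=99, seed=0)
        X = np.column_stack([np.ones(n), x])
        B = np.linalg.lstsq(X, Y, rcond=None)[0]
        sse = np.sum((Y - X @ B) ** 2)
        sst = np.sum((Y - Y.mean(axis=0)) ** 2)
        ss_model = sst - sse
        F = (ss_model / 1) / (sse / (n - 2))
        assert res.SS_effect == pytest.approx(ss_model, rel=1e-8)
        assert res.SS_total == pytest.approx(sst, rel=1e-8)
        assert res.F == pytest.approx(F, rel=1e-8)

    def test_exact_linear_relation_gives_r2_one(self, rng):
        tree = simulate_tree(14, seed=4)
        x = rng.normal(size=14)
        Y = np.outer(x, [1.0, -2.0, 0.5])
        res = pgls_shape_regression(Y, x, tree, species=tree.tip_labels,
                                    permutations=19, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_covariate_rejected(self, rng):
        tree = _star(8)
        Y = rng.normal(size=(8, 3))
        with pytest.raises(ValueError, match="constant"):
            pgls_shape_regression(Y, np.ones(8), tree,
                                  species=tree.tip_labels, permutations=9)

    def test_two_group_star_anova_equals_classical_f(self, rng):
        """Star-tree two-group multivariate ANOVA against the classical
        trace-based F computed longhand."""
        n, p = 18, 4
        tree = _star(n)
        groups = ["A"] * 9 + ["B"] * 9
        Y = rng.normal(size=(n, p))
        Y[9:] += 0.8
        res = phylo_procrustes_anova(Y, groups, tree,
                                     species=tree.tip_labels,
                                     permutations=99, seed=0)
        g = np.asarray(groups)
        within = sum(np.sum((Y[g == lv] - Y[g == lv].mean(axis=0)) ** 2)
                     for lv in "AB")
        total = np.sum((Y - Y.mean(axis=0)) ** 2)
        F = ((total - within) / 1) / (within / (n - 2))
        assert res.F == pytest.approx(F, rel=1e-8)

    def test_single_group_rejected(self, rng):
        tree = _star(6)
        with pytest.raises(ValueError):
            phylo_procrustes_anova(rng.normal(size=(6, 3)), ["A"] * 6,
                                   tree, species=tree.tip_labels,
                                   permutations=9)

    def test_pairwise_matrix_symmetric_in_distance(self, small_bundle):
        from cerebrotype import gpa

        aligned = gpa(small_bundle.landmarks, "cerebellum")
        res = phylo_procrustes_anova(aligned, small_bundle.modes,
                                     small_bundle.tree, permutations=49,
                                     seed=1)
        assert res.pairwise
        for (a, b), (d, p) in res.pairwise.items():
            assert d >= 0
            assert 1 / 50 <= p <= 1.0

    def test_replicate_species_rejected(self, rng):
        from cerebrotype import AlignedShapes

        tree = _star(3)
        coords = rng.normal(size=(4, 5, 3))
        shapes = AlignedShapes(coords, np.ones(4), coords[0],
                               ["a", "b", "c", "d"],
                               ["t0", "t0", "t1", "t2"])
        with pytest.raises(ValueError, match="average"):
            phylo_procrustes_anova(shapes, ["A", "A", "B", "B"], tree,
                                   permutations=9)


class TestAncestralStates:
    def test_two_tip_tree_root_is_weighted_mean(self):
        tree = PhyloTree.from_newick("(A:1,B:3);")
        states = ancestral_states_bm(tree, np.array([[0.0], [4.0]]),
                                     ["A", "B"])
        # harmonic weights 1/1 and 1/3 -> root = (1*0 + 1/3*4)/(4/3) = 1
        assert states[0, 0] == pytest.approx(1.0)

    def test_interpolation_bounds(self, rng):
        tree = simulate_tree(10, seed=9)
        Y = rng.normal(size=(10, 1))
        states = ancestral_states_bm(tree, Y, tree.tip_labels)
        assert states.min() >= Y.min() - 1e-9
        assert states.max() <= Y.max() + 1e-9


class TestConvergence:
    @pytest.fixture()
    def balanced4(self):
        return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")

    def test_hand_enumerated_oracle(self, balanced4):
        """Fixed node states on a 4-tip tree; C1-C4 computed by hand:

        path(A) phenotypes [0.5, 2, 0]; path(C) phenotypes [-0.5, -2, 0];
        Dtip = 1; cross-path distances {1, 2.5, 0.5, 2.5, 4, 2, 0.5, 2, 0}
        -> Dmax = 4; C1 = 0.75; C2 = 3; path change = 3.5 + 3.5 -> C3 =
        3/7; clade change = 2+2+1.5+2+1.5+2 = 11 -> C4 = 3/11.
        """
        tree = balanced4
        et = tree.edge_table()
        states = np.zeros((et.n_nodes, 1))
        states[0] = 0.0
        states[tree.mrca_index("A", "B")] = 2.0
        states[tree.mrca_index("C", "D")] = -2.0
        states[et.tip_index["A"]] = 0.5
        states[et.tip_index["B"]] = 4.0
        states[et.tip_index["C"]] = -0.5
        states[et.tip_index["D"]] = -4.0
        c1, c2, c3, c4, dtip, dmax, _ = _c_measures_from_states(
            tree, states, (et.tip_index["A"], et.tip_index["C"]))
        assert dtip == pytest.approx(1.0)
        assert dmax == pytest.approx(4.0)
        assert c1 == pytest.approx(0.75)
        assert c2 == pytest.approx(3.0)
        assert c3 == pytest.approx(3.0 / 7.0)
        assert c4 == pytest.approx(3.0 / 11.0)

    def test_identical_focal_tips_give_c1_of_one(self, balanced4):
        tree = balanced4
        et = tree.edge_table()
        states = np.zeros((et.n_nodes, 2))
        states[tree.mrca_index("A", "B")] = [3.0, 0.0]
        states[tree.mrca_index("C", "D")] = [-3.0, 0.0]
        states[et.tip_index["A"]] = [1.0, 1.0]
        states[et.tip_index["C"]] = [1.0, 1.0]
        c1, *_ = _c_measures_from_states(
            tree, states, (et.tip_index["A"], et.tip_index["C"]))
        assert c1 == pytest.approx(1.0)

    def test_monotone_divergence_gives_c1_zero(self, balanced4):
        """Tips that keep moving apart have Dmax = Dtip, hence C1 = 0."""
        tree = balanced4
        et = tree.edge_table()
        states = np.zeros((et.n_nodes, 1))
        states[tree.mrca_index("A", "B")] = 1.0
        states[tree.mrca_index("C", "D")] = -1.0
        states[et.tip_index["A"]] = 2.0
        states[et.tip_index["C"]] = -2.0
        c1, c2, *_ = _c_measures_from_states(
            tree, states, (et.tip_index["A"], et.tip_index["C"]))
        assert c1 == pytest.approx(0.0)
        assert c2 == pytest.approx(0.0)

    def test_full_pipeline_on_convergent_data(self, rng):
        """Distant species pulled to the same phenotype should show high
        C1 with a small simulation p."""
        tree = simulate_tree(16, seed=6)
        species = tree.tip_labels
        C = tree.covariance(species)
        L = np.linalg.cholesky(C)
        Y = L @ rng.normal(size=(16, 3))
        # two maximally distant tips forced to converge
        d = np.diag(C)[:, None] + np.diag(C)[None, :] - 2 * C
        i, j = np.unravel_index(np.argmax(d), d.shape)
        Y[j] = Y[i] + 1e-3
        res = convergence_c_measures(Y, tree, [species[i], species[j]],
                                     species=species, n_sim=99, seed=4)
        assert res.C1 > 0.5
        assert res.p1 < 0.1

    def test_needs_two_focal_taxa(self, rng, yule_tree_12):
        Y = rng.normal(size=(12, 2))
        with pytest.raises(ValueError):
            convergence_c_measures(Y, yule_tree_12,
                                   [yule_tree_12.tip_labels[0]], n_sim=9)
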