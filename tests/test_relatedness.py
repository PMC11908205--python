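"""Relatedness matrices: hand-derived values, identities, and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from branchgrm import (
    Pedigree,
    branch_grm_centered,
    branch_grm_uncentered,
    collapse_to_individuals,
    divergence_matrix,
    egrm,
    genotype_grm,
    match_covariance,
    pedigree_kinship,
    trait_covariance_check,
)
from branchgrm.relatedness import RelatednessMatrix, _center, tmrca_matrices
from branchgrm.simulate import drop_mutations

from conftest import make_random_ts


def psd_check(M, tol=1e-9):
    vals = np.linalg.eigvalsh(M)
    assert vals.min() >= -tol * max(vals.max(), 1e-300)


class TestHandExamples:
    def test_two_sample_matrices(self, two_sample_ts):
        assert np.allclose(branch_grm_uncentered(two_sample_ts).values, np.eye(2))
        assert np.allclose(
            branch_grm_centered(two_sample_ts).values, [[0.5, -0.5], [-0.5, 0.5]]
        )
        assert np.allclose(divergence_matrix(two_sample_ts).values, [[0, 2], [2, 0]])
        assert np.allclose(egrm(two_sample_ts).values, [[1, -1], [-1, 1]])

    def test_caterpillar_shared_areas(self, caterpillar_ts):
        C = branch_grm_uncentered(caterpillar_ts).values
        assert np.allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_centered_is_projector_multiple(self):
        from branchgrm import TreeSequence

        star = TreeSequence(
            1.0, [0, 0, 0, 1], [1, 1, 1, 0],
            edge_left=[0] * 3, edge_right=[1] * 3,
            edge_parent=[3] * 3, edge_child=[0, 1, 2],
        )
        B = branch_grm_centered(star).values
        P = np.eye(3) - np.full((3, 3), 1 / 3)
        c = B[0, 0] / P[0, 0]
        assert np.allclose(B, c * P)

    def test_divergence_diagonal_is_zero(self, random_ts_batch):
        for ts in random_ts_batch[:5]:
            assert np.all(np.diag(divergence_matrix(ts).values) == 0)

    def test_disconnected_pair_divergence_errors(self):
        from branchgrm import TreeSequence

        ts = TreeSequence(
            1.0, [0, 0, 0, 0, 1, 1], [1, 1, 1, 1, 0, 0],
            edge_left=[0] * 4, edge_right=[1] * 4,
            edge_parent=[4, 4, 5, 5], edge_child=[0, 1, 2, 3],
        )
        with pytest.raises(ValueError, match="common root"):
            divergence_matrix(ts)
        # uncentered C instead reports zero shared area across subtrees;
        # within a cherry the only shared "branch" is above the root (none)
        C = branch_grm_uncentered(ts).values
        assert C[0, 2] == 0 and C[0, 1] == 0 and C[0, 0] == 1


class TestBranchIdentities:
    @pytest.mark.parametrize("seed", range(10))
    def test_centered_equals_minus_half_pdp(self, seed):
        ts = make_random_ts(seed)
        B = branch_grm_centered(ts).values
        D = divergence_matrix(ts).values
        assert np.linalg.norm(B - (-_center(D) / 2)) <= 1e-9 * np.linalg.norm(B)
        assert np.abs(B.sum(axis=1)).max() <= 1e-9 * np.abs(B).max()

    @pytest.mark.parametrize("seed", range(10))
    def test_root_paths_decompose_into_shared_plus_divergence(self, seed):
        """R_i + R_j = 2 A(i,j) + D(i,j) along the whole genome."""
        ts = make_random_ts(seed)
        C = branch_grm_uncentered(ts).values
        D = divergence_matrix(ts).values
        R = np.diag(C)  # distance to root = area shared of a sample with itself
        lhs = R[:, None] + R[None, :]
        assert np.allclose(lhs, 2 * C + D, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_root_time_equals_shared_length_plus_tmrca(self, seed):
        """Per tree and sample pair at time 0: root time = b(i,j) + t(i,j)."""
        ts = make_random_ts(seed, n=12)
        for tree, Tm in tmrca_matrices(ts):
            nodes, S = tree.sample_paths()
            ell = np.array([tree.branch_length(n) for n in nodes])
            shared = S.T @ (ell[:, None] * S)  # per-pair shared branch length
            root_time = ts.node_time[tree.root_of(int(tree.samples[0]))]
            assert np.allclose(shared + Tm, root_time, atol=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_tmrca_form_of_centered_grm(self, seed):
        """B also equals the span-weighted, doubly centered TMRCA sum."""
        ts = make_random_ts(seed, n=12)
        B = branch_grm_centered(ts).values
        B10 = np.zeros_like(B)
        for tree, Tm in tmrca_matrices(ts):
            B10 += tree.span * (-_center(Tm))
        assert np.linalg.norm(B - B10) <= 1e-9 * np.linalg.norm(B)

    def test_branch_matrices_are_psd(self, random_ts_batch):
        for ts in random_ts_batch[:6]:
            psd_check(branch_grm_uncentered(ts).values)
            psd_check(branch_grm_centered(ts).values)
            psd_check(egrm(ts).values)


class TestEgrm:
    def test_row_sums_vanish(self, random_ts_batch):
        for ts in random_ts_batch[:5]:
            G = egrm(ts).values
            assert np.abs(G.sum(axis=1)).max() <= 1e-9 * np.abs(G).max()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_edge_loop_oracle(self, seed):
        """Slow per-edge loop: descendant sets found by scanning the raw
        parent maps, normalization applied edge by edge."""
        ts = make_random_ts(seed, n=8)
        n = ts.num_samples
        acc = np.zeros((n, n))
        area = 0.0
        for tree in ts.trees():
            for node in range(ts.num_nodes):
                ell = tree.branch_length(node)
                if ell == 0:
                    continue
                ind = np.array(
                    [node in tree.ancestors(int(s)) for s in tree.samples], float
                )
                if ind.sum() == 0:
                    continue
                area += tree.span * ell
                sbar = ind.mean()
                if sbar in (0.0, 1.0):
                    continue
                x = ind - sbar
                acc += tree.span * ell * np.outer(x, x) / (sbar * (1 - sbar))
        assert np.allclose(egrm(ts).values, acc / area, rtol=1e-9)


class TestGenotypeMatrices:
    def test_two_by_two_example(self):
        G = np.array([[1.0, 0.0], [0.0, 0.0]])
        expect = np.array([[0.125, -0.125], [-0.125, 0.125]])
        assert np.allclose(genotype_grm(G).values, expect)
        assert np.allclose(match_covariance(G).values, expect)

    def test_fixed_columns_do_not_contribute(self):
        G = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        lean = genotype_grm(G[:, :1]).values / 3  # only column 0 varies; /n_L
        assert np.allclose(genotype_grm(G).values, lean * 1)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 2, size=(6, 30)).astype(float)
        perm = rng.permutation(6)
        C = genotype_grm(G).values
        assert np.allclose(genotype_grm(G[perm]).values, C[np.ix_(perm, perm)])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.integers(2, 8),
        st.integers(1, 20),
        st.integers(0, 2**31 - 1),
    )
    def test_match_covariance_equals_genotype_grm(self, n, m, seed):
        G = np.random.default_rng(seed).integers(0, 2, size=(n, m)).astype(float)
        assert np.allclose(
            match_covariance(G).values, genotype_grm(G).values, atol=1e-12
        )

    def test_constant_matrix_gives_zero(self):
        G = np.ones((4, 5))
        assert np.allclose(match_covariance(G).values, 0.0)

    def test_match_covariance_rejects_dosages(self):
        with pytest.raises(ValueError, match="binary"):
            match_covariance(np.array([[0.5, 0.0], [1.0, 0.0]]))


class TestCollapse:
    def test_singleton_groups_identity(self):
        M = RelatednessMatrix(np.arange(9.0).reshape(3, 3) + np.arange(9.0).reshape(3, 3).T, "genotype")
        out = collapse_to_individuals(M, np.array([0, 1, 2]))
        assert np.allclose(out.values, M.values)

    def test_diploid_block_mean(self):
        M = RelatednessMatrix(np.eye(4), "uncentered_C")
        out = collapse_to_individuals(M, np.array([0, 0, 1, 1]))
        assert np.allclose(out.values, 0.5 * np.eye(2))

    def test_collapse_commutes_with_centering(self):
        # equal-size groups (e.g. diploids): averaging preserves the
        # zero-row-sum property of the centered matrix
        from conftest import make_random_ts

        ts = make_random_ts(21, n=12)
        groups = np.arange(12) // 2
        out = collapse_to_individuals(branch_grm_centered(ts), groups)
        assert np.abs(out.values.sum(axis=1)).max() <= 1e-9 * np.abs(out.values).max()


class TestPedigreeKinship:
    def test_unrelated_founders(self):
        ped = Pedigree([-1, -1], [-1, -1], [0, 0], [1, 1])
        assert np.allclose(pedigree_kinship(ped).values, 0.5 * np.eye(2))

    def test_siblings_and_parent_offspring(self):
        #       0   1
        #        \ /
        #        2 3   (2, 3 are full siblings)
        ped = Pedigree([-1, -1, 0, 0], [-1, -1, 1, 1], [0, 0, 1, 1], [0, 0, 1, 1])
        theta = pedigree_kinship(ped).values
        assert theta[2, 3] == pytest.approx(0.25)
        assert theta[0, 2] == pytest.approx(0.25)
        assert theta[2, 2] == pytest.approx(0.5)

    def test_first_cousins_match_gene_drop_monte_carlo(self):
        from branchgrm import relationship_panel_pedigree

        ped, pairs = relationship_panel_pedigree()
        a, b = pairs["first_cousin"][0]
        theta = pedigree_kinship(ped).values
        assert theta[a, b] == pytest.approx(1 / 16)
        # single-locus gene-drop oracle, vectorized over replicates
        reps = 100_000
        rng = np.random.default_rng(0)
        n = ped.num_individuals
        copies = np.empty((n, 2, reps), dtype=np.int64)
        next_allele = 0
        for i in ped.topological_order():
            for side, parent in ((0, ped.father[i]), (1, ped.mother[i])):
                if parent == -1:
                    copies[i, side] = next_allele
                    next_allele += 1
                else:
                    pick = rng.integers(2, size=reps)
                    copies[i, side] = copies[parent, pick, np.arange(reps)]
        match = np.zeros(reps)
        for s1 in range(2):
            for s2 in range(2):
                match += (copies[a, s1] == copies[b, s2]) / 4.0
        est = match.mean()
        se = match.std(ddof=1) / np.sqrt(reps)
        assert abs(est - 1 / 16) < 4 * se + 1e-12

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="earlier generation"):
            Pedigree([1, 0], [-1, -1], [0, 0], [1, 1])


class TestTraitCovariance:
    def test_zero_variance_gives_zero(self, caterpillar_ts):
        ts = drop_mutations(caterpillar_ts, 3.0, 1)
        cov, _ = trait_covariance_check(ts, sigma2=0.0, n_reps=10, seed=0)
        assert np.allclose(cov, 0.0)

    def test_site_mode_matches_genotype_grm(self):
        from branchgrm import genotypes_from_mutations

        ts = drop_mutations(make_random_ts(5, n=10), 20.0, 2)
        G = genotypes_from_mutations(ts)
        sigma2 = 0.7
        cov, se = trait_covariance_check(ts, sigma2, n_reps=4000, seed=3)
        theory = sigma2 * G.shape[1] * genotype_grm(G).values
        assert np.all(np.abs(cov - theory) <= 5 * se + 1e-9)

    def test_branch_mode_matches_centered_grm(self):
        ts = make_random_ts(6, n=8)
        B = branch_grm_centered(ts).values
        cov, se = trait_covariance_check(
            ts, sigma2=1.0, n_reps=1500, seed=4, mode="branch", mu=5.0
        )
        assert np.all(np.abs(cov - 5.0 * B) <= 5 * se + 1e-9)

    def test_too_few_replicates_rejected(self, two_sample_ts):
        with pytest.raises(ValueError, match="n_reps"):
            trait_covariance_check(two_sample_ts, 1.0, n_reps=1, seed=0, mode="branch")
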