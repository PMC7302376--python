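"""Assembly core: conflict weights, SDP solve, rounding, consensus."""

from __future__ import annotations

import numpy as np
import pytest

from linkphase.core import (
    Assignment,
    SolverConfig,
    assemble_component,
    brute_force_max_kcut,
    build_conflict_weights,
    clustering_objective,
    consensus_haplotypes,
    greedy_refine,
    round_assignment,
    solve_max_kcut_sdp,
    GAP,
)

from conftest import make_fragment


def random_conflict_matrix(rng, n, values=(-1.0, 0.0, 1.0)):
    A = rng.choice(values, size=(n, n))
    W = np.triu(A, 1)
    W = W + W.T
    np.fill_diagonal(W, -1.0)
    return W


class TestConflictWeights:
    def test_balanced_pair(self):
        f1 = make_fragment([(1, 0), (2, 0)], id="a")
        f2 = make_fragment([(1, 0), (2, 1)], id="b")
        W = build_conflict_weights([f1, f2])
        assert W[0, 1] == 0.0  # 1 matched, 1 mismatched over 2 shared

    def test_identical_fragments(self):
        f1 = make_fragment([(1, 0), (2, 1), (3, 0)], id="a")
        f2 = make_fragment([(1, 0), (2, 1), (3, 0)], id="b")
        W = build_conflict_weights([f1, f2])
        assert W[0, 1] == -1.0

    def test_fully_conflicting(self):
        f1 = make_fragment([(1, 0), (2, 0)], id="a")
        f2 = make_fragment([(1, 1), (2, 1)], id="b")
        W = build_conflict_weights([f1, f2])
        assert W[0, 1] == 1.0

    def test_unshared_pair_zero_diagonal_minus_one(self):
        f1 = make_fragment([(1, 0), (2, 0)], id="a")
        f2 = make_fragment([(5, 0), (6, 0)], id="b")
        W = build_conflict_weights([f1, f2])
        assert W[0, 1] == 0.0
        assert np.all(np.diag(W) == -1.0)
        assert np.all((W >= -1.0) & (W <= 1.0))


class TestSolveMaxKcutSDP:
    def test_two_fragment_closed_form(self):
        W = np.array([[-1.0, 1.0], [1.0, -1.0]])
        st = solve_max_kcut_sdp(W, 2)
        assert st.obj_p == pytest.approx(-4.0, abs=1e-3)
        assert st.X[0, 1] == pytest.approx(-1.0, abs=1e-3)

    def test_three_fragment_symmetric_closed_form(self):
        W = np.full((3, 3), 1.0)
        np.fill_diagonal(W, -1.0)
        st = solve_max_kcut_sdp(W, 3)
        assert st.obj_p == pytest.approx(-6.0, abs=1e-3)
        off = st.X[~np.eye(3, dtype=bool)]
        assert np.allclose(off, -0.5, atol=1e-3)

    def test_zero_matrix(self):
        st = solve_max_kcut_sdp(np.zeros((4, 4)), 2)
        assert st.obj_p == pytest.approx(0.0, abs=1e-9)
        assert st.gap == pytest.approx(0.0, abs=1e-9)

    def test_single_fragment_trivial(self):
        st = solve_max_kcut_sdp(np.array([[-1.0]]), 3)
        assert st.X[0, 0] == 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            solve_max_kcut_sdp(np.array([[0.0, 1.0], [2.0, 0.0]]), 2)
        with pytest.raises(ValueError):
            solve_max_kcut_sdp(np.zeros((2, 2)), 1)

    def test_termination_invariants(self, rng):
        """Reported X is feasible to 1e-6 and the gap is within tolerance."""
        for K in (2, 3, 4):
            n = 12
            A = rng.uniform(-1, 1, size=(n, n))
            W = np.triu(A, 1)
            W = W + W.T
            np.fill_diagonal(W, -1.0)
            st = solve_max_kcut_sdp(W, K)
            b = -1.0 / (K - 1)
            assert abs(st.gap) <= st.gap_tol
            assert np.abs(np.diag(st.X) - 1.0).max() <= 1e-6
            assert (st.X >= b - 1e-6).all()
            assert np.linalg.eigvalsh(st.X)[0] >= -1e-6
            assert np.linalg.eigvalsh(st.Z)[0] >= -1e-8
            assert (st.lam >= 0).all()

    def test_deterministic(self, rng):
        W = random_conflict_matrix(rng, 8)
        a = solve_max_kcut_sdp(W, 3)
        b = solve_max_kcut_sdp(W, 3)
        assert np.array_equal(a.X, b.X)
        assert a.n_iter == b.n_iter

    def test_dual_lower_bounds_brute_force(self, rng):
        """Certified dual objective never exceeds the clustering optimum."""
        for _ in range(15):
            n = int(rng.integers(4, 11))
            K = int(rng.integers(2, 4))
            W = random_conflict_matrix(rng, n)
            st = solve_max_kcut_sdp(W, K)
            _, opt = brute_force_max_kcut(W, K)
            assert st.obj_d <= opt + 1e-9


class TestBruteForce:
    def test_two_fragment_example(self):
        W = np.array([[-1.0, 1.0], [1.0, -1.0]])
        labels, obj = brute_force_max_kcut(W, 2)
        assert obj == -2.0
        assert labels[0] != labels[1]

    def test_all_agreement_single_cluster(self):
        W = np.full((4, 4), -1.0)
        labels, obj = brute_force_max_kcut(W, 3)
        assert len(set(labels.tolist())) == 1
        assert obj == -16.0  # all ordered pairs incl. diagonal

    def test_all_conflict_singletons(self):
        W = np.full((3, 3), 1.0)
        np.fill_diagonal(W, -1.0)
        labels, obj = brute_force_max_kcut(W, 3)
        assert len(set(labels.tolist())) == 3
        assert obj == -3.0

    def test_refuses_large_n(self):
        with pytest.raises(ValueError, match="N <= 12"):
            brute_force_max_kcut(np.zeros((13, 13)), 2)


class TestRounding:
    def test_block_structure_is_respected(self):
        """Fragments with identical X columns always share a label."""
        K = 3
        blocks = [0, 0, 1, 1, 2, 2]
        X = np.array(
            [
                [1.0 if blocks[i] == blocks[j] else -0.5 for j in range(6)]
                for i in range(6)
            ]
        )
        W = -X  # agreeing pairs negative
        st_like = solve_max_kcut_sdp(W, K)
        for seed in range(5):
            a = round_assignment(st_like, restarts=3, rng_seed=seed, refine=False)
            lab = a.labels
            assert lab[0] == lab[1] and lab[2] == lab[3] and lab[4] == lab[5]

    def test_exchangeable_on_identity(self):
        """With X = I every fragment's label is marginally uniform."""
        from linkphase.core import SDPState

        n, K = 4, 2
        X = np.eye(n)
        st = SDPState(
            W=np.zeros((n, n)), K=K, X=X, lam=np.empty(0),
            Z=np.zeros((n, n)), Y=np.zeros((n, n)), mu=1.0, sigma=1.0,
            obj_p=0.0, obj_d=0.0, gap=0.0, gap_tol=0.01, n_iter=1,
            residual=0.0,
        )
        counts = np.zeros(n)
        trials = 400
        for seed in range(trials):
            a = round_assignment(st, restarts=1, rng_seed=seed, refine=False)
            counts += a.labels
        freq = counts / trials
        assert np.abs(freq - 0.5).max() < 0.1

    def test_more_restarts_never_worse(self, rng):
        W = random_conflict_matrix(rng, 8)
        st = solve_max_kcut_sdp(W, 2)
        few = round_assignment(st, restarts=1, rng_seed=7)
        many = round_assignment(st, restarts=50, rng_seed=7)
        assert many.objective <= few.objective

    def test_deterministic_given_seed(self, rng):
        W = random_conflict_matrix(rng, 8)
        st = solve_max_kcut_sdp(W, 3)
        a = round_assignment(st, restarts=20, rng_seed=3)
        b = round_assignment(st, restarts=20, rng_seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_greedy_refine_monotone(self, rng):
        W = random_conflict_matrix(rng, 10)
        labels = rng.integers(0, 3, size=10)
        before = clustering_objective(W, labels, 3)
        refined = greedy_refine(W, labels, 3)
        after = clustering_objective(W, refined, 3)
        assert after <= before


class TestConsensus:
    def test_majority_and_support(self):
        frags = [
            make_fragment([(1, 0), (2, 0)], id="a"),
            make_fragment([(1, 0), (2, 0)], id="b"),
            make_fragment([(1, 1), (2, 0)], id="c"),
        ]
        block = consensus_haplotypes(frags, np.zeros(3, dtype=int), 2)
        assert block.haplotypes[0, 0] == 0  # majority 0,0,1 -> 0
        assert block.support[0, 0] == 2
        assert block.haplotypes[1, 0] == GAP  # empty cluster

    def test_tie_breaks_to_lowest_allele(self):
        frags = [
            make_fragment([(1, 0), (2, 0)], id="a"),
            make_fragment([(1, 1), (2, 0)], id="b"),
        ]
        block = consensus_haplotypes(frags, np.zeros(2, dtype=int), 1)
        assert block.haplotypes[0, 0] == 0

    def test_uncovered_site_is_gap(self):
        frags = [
            make_fragment([(1, 0), (2, 0)], id="a"),
            make_fragment([(5, 1), (6, 1)], id="b"),
        ]
        block = consensus_haplotypes(frags, np.array([0, 1]), 2)
        j5 = block.variant_indices.index(5)
        assert block.haplotypes[0, j5] == GAP
        assert block.haplotypes[1, j5] == 1

    def test_empty_cluster_warns(self):
        frags = [
            make_fragment([(1, 0), (2, 0)], id="a"),
            make_fragment([(1, 0), (2, 0)], id="b"),
        ]
        with pytest.warns(UserWarning, match="empty"):
            block = consensus_haplotypes(frags, np.zeros(2, dtype=int), 3)
        assert np.all(block.haplotypes[2] == GAP)

    def test_label_permutation_equivariance(self, rng):
        from conftest import random_fragment

        frags = [random_fragment(rng, f"f{i}", n_sites=10) for i in range(9)]
        labels = rng.integers(0, 3, size=9)
        perm = np.array([2, 0, 1])
        b1 = consensus_haplotypes(frags, labels, 3)
        b2 = consensus_haplotypes(frags, perm[labels], 3)
        assert b1.mec == b2.mec
        for k in range(3):
            assert np.array_equal(b1.haplotypes[k], b2.haplotypes[perm[k]])


class TestAssembleComponent:
    def test_noiseless_planted_recovery(self):
        """Six error-free fragments, two per haplotype, K=3: exact block."""
        # every haplotype pair mismatches at 4 of 6 sites, so all cross
        # conflict weights are +1/3 and the planted partition is the
        # unique clustering optimum
        haps = np.array(
            [
                [0, 0, 0, 0, 0, 0],
                [1, 1, 1, 1, 0, 0],
                [1, 0, 1, 0, 1, 1],
            ]
        )
        frags = []
        for k in range(3):
            for r in range(2):
                frags.append(
                    make_fragment(
                        [(j + 1, int(haps[k, j])) for j in range(6)],
                        id=f"h{k}r{r}",
                    )
                )
        block = assemble_component(frags, 3, SolverConfig(restarts=20, seed=1))
        assert block.mec == 0
        rows = {tuple(int(a) for a in block.haplotypes[k]) for k in range(3)}
        assert rows == {tuple(int(a) for a in haps[k]) for k in range(3)}

    def test_underdetermined_component_rejected(self):
        frags = [make_fragment([(1, 0), (2, 0)], id="a")]
        with pytest.raises(ValueError, match="underdetermined"):
            assemble_component(frags, 3)

    def test_single_cluster_all_agreement(self):
        frags = [
            make_fragment([(1, 0), (2, 1)], id=f"f{i}") for i in range(3)
        ]
        with pytest.warns(UserWarning):
            block = assemble_component(frags, 2, SolverConfig(restarts=5, seed=0))
        populated = [
            k for k in range(2) if not np.all(block.haplotypes[k] == GAP)
        ]
        assert len(populated) == 1
        assert block.mec == 0

    def test_rounding_recovers_brute_optimum_with_restarts(self, rng):
        """SDP + rounding reaches the exhaustive optimum on small instances."""
        hits = 0
        for _ in range(15):
            n = int(rng.integers(4, 9))
            K = int(rng.integers(2, 4))
            W = random_conflict_matrix(rng, n)
            st = solve_max_kcut_sdp(W, K)
            a = round_assignment(st, restarts=200, rng_seed=11)
            _, opt = brute_force_max_kcut(W, K)
            hits += a.objective <= opt + 1e-9
        assert hits >= 13

    def test_consensus_mec_zero_for_consistent_clusters(self, rng):
        """Noiseless planted fragments give a zero-MEC consensus."""
        haps = rng.integers(0, 2, size=(2, 12))
        frags = []
        for k in range(2):
            for r in range(3):
                lo = int(rng.integers(0, 5))
                hi = int(rng.integers(lo + 2, 13))
                frags.append(
                    make_fragment(
                        [(j + 1, int(haps[k, j])) for j in range(lo, hi)],
                        id=f"h{k}r{r}",
                    )
                )
        labels = np.repeat([0, 1], 3)
        block = consensus_haplotypes(frags, labels, 2)
        assert block.mec == 0
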