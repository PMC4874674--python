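"""GY94 rate matrices, F3X4 frequencies, pruning likelihood, simulation."""

import itertools

import numpy as np
import pytest

from zfselect.codon_model import (
    CODONS,
    CODON_AA,
    MISSING,
    CodonLikelihood,
    build_rate_matrix,
    codons_to_codes,
    f3x4_frequencies,
    mixture_rate_matrices,
    mixture_scale_factor,
    simulate_mixture_alignment,
    transition_probabilities,
)
from zfselect.trees import parse_newick

UNIFORM = np.ones(61) / 61


def _random_pi(seed):
    return np.random.default_rng(seed).dirichlet(np.ones(61) * 4)


class TestFrequencies:
    def test_uniform_composition(self):
        # every sense codon observed once -> not uniform (stop removal skews
        # position frequencies), but balanced nucleotide counts per position
        # do give equal frequencies
        codes = np.arange(61)
        pi = f3x4_frequencies(codes)
        assert pi.sum() == pytest.approx(1.0)

    def test_balanced_nucleotides_give_1_over_61(self):
        # codons chosen so every nucleotide appears equally at each position
        quads = ["AAA", "CCC", "GGG", "TTT"]
        codes = codons_to_codes([c for c in quads for _ in range(5) if c in CODONS])
        pi = f3x4_frequencies(codes)
        assert np.allclose(pi, 1 / 61)

    def test_pseudocount_warning(self):
        codes = codons_to_codes(["AAA", "AAA"])
        with pytest.warns(UserWarning, match="pseudocount"):
            f3x4_frequencies(codes)


class TestRateMatrix:
    @pytest.mark.parametrize("kappa,omega", [(1.0, 1.0), (2.5, 0.3), (5.0, 4.0)])
    def test_generator_identities(self, kappa, omega):
        pi = _random_pi(0)
        q = build_rate_matrix(pi, kappa, omega)
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)  # reversibility
        assert -pi @ np.diag(q) == pytest.approx(1.0)

    def test_kappa_omega_one_single_step_model(self):
        """With kappa=omega=1 and equal frequencies, every single-nucleotide
        exchange has the same rate and multi-nucleotide rates are zero."""
        q = build_rate_matrix(UNIFORM, 1.0, 1.0)
        offdiag = []
        for i, j in itertools.product(range(61), repeat=2):
            if i == j:
                continue
            ndiff = sum(a != b for a, b in zip(CODONS[i], CODONS[j]))
            if ndiff == 1:
                offdiag.append(q[i, j])
            else:
                assert q[i, j] == 0
        assert np.allclose(offdiag, offdiag[0])

    def test_mixture_common_scaling(self):
        pi = _random_pi(1)
        weights, omegas = np.array([0.7, 0.3]), np.array([0.2, 5.0])
        qs = mixture_rate_matrices(pi, 2.0, omegas, weights)
        mean_rate = sum(w * -pi @ np.diag(q) for w, q in zip(weights, qs))
        assert mean_rate == pytest.approx(1.0)
        # the positive class runs faster than average
        assert -pi @ np.diag(qs[1]) > 1.0 > -pi @ np.diag(qs[0])
        assert mixture_scale_factor(pi, 2.0, omegas, weights) > 0

    def test_transition_probabilities(self):
        pi = _random_pi(2)
        q = build_rate_matrix(pi, 2.0, 0.5)
        p1 = transition_probabilities(q, pi, 0.1)
        assert np.allclose(p1.sum(axis=1), 1)
        assert np.allclose(transition_probabilities(q, pi, 0.0), np.eye(61), atol=1e-9)
        # Chapman-Kolmogorov
        p2 = transition_probabilities(q, pi, 0.2)
        assert np.allclose(p1 @ p1, p2, atol=1e-9)


def _enumerate_loglik(tree_spec, codes, taxa, pi, kappa, omega):
    """Brute-force likelihood by summing over all internal-node states."""
    from zfselect.codon_model import TreeIndex

    tree = parse_newick(tree_spec)
    idx = TreeIndex.build(tree, taxa)
    q = mixture_rate_matrices(pi, kappa, [omega], [1.0])[0]
    pmats = {
        nid: transition_probabilities(q, pi, idx.lengths[nid])
        for nid in range(idx.n_nodes)
        if idx.parent[nid] >= 0
    }
    internal = [n for n in range(idx.n_nodes) if idx.children[n]]
    total = 0.0
    for site in range(codes.shape[1]):
        lik = 0.0
        for states in itertools.product(range(61), repeat=len(internal)):
            assign = dict(zip(internal, states))
            for nid, row in idx.leaf_taxon.items():
                assign[nid] = codes[row, site]
            term = 1.0
            root = idx.postorder[-1]
            term *= pi[assign[root]]
            for nid in range(idx.n_nodes):
                if idx.parent[nid] < 0:
                    continue
                child_state = assign[nid]
                parent_state = assign[idx.parent[nid]]
                if child_state == MISSING:
                    term *= 1.0  # marginalized leaf: sum over its states = 1
                else:
                    term *= pmats[nid][parent_state, child_state]
            lik += term
        total += np.log(lik)
    return total


class TestPruning:
    def test_zero_branch_identical_taxa(self):
        tree = parse_newick("(A:0,B:0);")
        codes = np.array([[0, 5, 17], [0, 5, 17]])
        cl = CodonLikelihood(codes, tree, ["A", "B"], pi=UNIFORM)
        assert cl.loglik(2.0, [1.0], [0.5]) == pytest.approx(3 * np.log(1 / 61))

    @pytest.mark.parametrize(
        "newick,taxa",
        [
            ("(A:0.3,B:0.1);", ["A", "B"]),
            ("(A:0.1,B:0.2,C:0.3);", ["A", "B", "C"]),
            ("((A:0.1,B:0.2):0.15,C:0.3,D:0.05);", ["A", "B", "C", "D"]),
        ],
    )
    def test_matches_exhaustive_enumeration(self, newick, taxa):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 61, size=(len(taxa), 2))
        pi = _random_pi(9)
        cl = CodonLikelihood(codes, tree=parse_newick(newick), taxa=taxa, pi=pi)
        got = cl.loglik(2.5, [1.0], [0.7])
        want = _enumerate_loglik(newick, codes, taxa, pi, 2.5, 0.7)
        assert got == pytest.approx(want, abs=1e-8)

    def test_missing_data_marginalization(self):
        """A fully missing taxon contributes nothing: the likelihood equals
        that of the alignment without it (zero-length pendant edge case is
        checked by marginalization against enumeration)."""
        newick = "(A:0.1,B:0.2,C:0.3);"
        taxa = ["A", "B", "C"]
        rng = np.random.default_rng(10)
        codes = rng.integers(0, 61, size=(3, 2))
        codes[2] = MISSING
        pi = _random_pi(11)
        cl = CodonLikelihood(codes, parse_newick(newick), taxa, pi=pi)
        got = cl.loglik(2.0, [1.0], [1.0])
        want = _enumerate_loglik(newick, codes, taxa, pi, 2.0, 1.0)
        assert got == pytest.approx(want, abs=1e-8)

    def test_degenerate_mixture_equals_single_class(self):
        tree = parse_newick("(A:0.1,B:0.2,C:0.3);")
        rng = np.random.default_rng(12)
        codes = rng.integers(0, 61, size=(3, 10))
        cl = CodonLikelihood(codes, tree, ["A", "B", "C"])
        single = cl.loglik(2.0, [1.0], [0.5])
        padded = cl.loglik(2.0, [1.0, 0.0], [0.5, 3.0])
        assert single == pytest.approx(padded, abs=1e-9)

    def test_invariance_leaf_order_and_rooting(self):
        rng = np.random.default_rng(13)
        codes = rng.integers(0, 61, size=(4, 20))
        taxa = ["A", "B", "C", "D"]
        pi = _random_pi(14)
        t1 = parse_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.25):0.1);")
        # same unrooted tree, rooted on the other side, leaves permuted
        t2 = parse_newick("((D:0.25,C:0.15):0.15,B:0.2,A:0.1);")
        l1 = CodonLikelihood(codes, t1, taxa, pi=pi).loglik(2.0, [1.0], [0.8])
        l2 = CodonLikelihood(codes, t2, taxa, pi=pi).loglik(2.0, [1.0], [0.8])
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_weights_must_be_distribution(self):
        tree = parse_newick("(A:0.1,B:0.2);")
        cl = CodonLikelihood(np.zeros((2, 2), dtype=int), tree, ["A", "B"])
        with pytest.raises(ValueError):
            cl.loglik(2.0, [0.5, 0.6], [0.5, 1.0])


class TestSimulation:
    def test_zero_branches_copy_root(self):
        tree = parse_newick("(A:0,B:0,C:0);")
        codes, _ = simulate_mixture_alignment(
            tree, ["A", "B", "C"], UNIFORM, 2.0, [1.0], [1.0], 50,
            np.random.default_rng(0),
        )
        assert (codes[0] == codes[1]).all() and (codes[0] == codes[2]).all()

    def test_long_branch_stationarity(self):
        """After a long branch the leaf distribution is the equilibrium:
        chi-square goodness of fit on one leaf's codon counts."""
        from scipy import stats

        tree = parse_newick("(A:6,B:6);")
        pi = _random_pi(20) * 0.5 + 0.5 / 61  # keep expected counts off zero
        pi /= pi.sum()
        codes, _ = simulate_mixture_alignment(
            tree, ["A", "B"], pi, 2.0, [1.0], [1.0], 8000,
            np.random.default_rng(21),
        )
        counts = np.bincount(codes[0], minlength=61)
        res = stats.chisquare(counts, pi * 8000)
        assert res.pvalue > 1e-3

    def test_class_fraction_concentration(self):
        tree = parse_newick("(A:0.2,B:0.2);")
        _, classes = simulate_mixture_alignment(
            tree, ["A", "B"], UNIFORM, 2.0, [0.6, 0.2, 0.2], [0.1, 1.0, 5.0],
            500, np.random.default_rng(22),
        )
        assert abs((classes == 2).mean() - 0.2) <= 0.05

    def test_no_stop_codons_possible(self):
        # the state space itself excludes stops; all emitted codes are sense
        tree = parse_newick("(A:1,B:1);")
        codes, _ = simulate_mixture_alignment(
            tree, ["A", "B"], UNIFORM, 2.0, [1.0], [2.0], 200,
            np.random.default_rng(23),
        )
        assert codes.min() >= 0 and codes.max() < 61
        assert all(CODON_AA[c] != "*" for c in codes.ravel())
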