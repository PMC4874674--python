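"""Codon alignments, site-model fits, LRTs and BEB classification."""

import numpy as np
import pytest
from scipy import stats

from zfselect.synthetic_data import (
    AlignmentSimConfig,
    ArraySimConfig,
    SpeciesConfig,
    simulate_codon_alignment,
    simulate_population,
    simulate_pseudogene,
)
from zfselect.site_selection import (
    CodonAlignment,
    FitResult,
    beb_classify,
    build_codon_alignment,
    class_distribution,
    codon_p_distances,
    fit_site_model,
    lrt,
    nj_tree,
)
from zfselect.codon_model import MISSING
from zfselect.trees import parse_newick
from zfselect.zf_decompose import segment_array
from conftest import make_amplicon, UNIT_NT

SIX_TAXON_TREE = (
    "((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15,(E:0.3,F:0.3):0.15);"
)


def _arrays(letters, seed=3):
    panel = (SpeciesConfig("sp", 1, {l: 1 / len(letters) for l in letters}),)
    sim = simulate_population(ArraySimConfig(panel=panel, seed=seed))
    return [
        segment_array(seq, f"sp|{letter}", "sp")
        for (_, letter), seq in sorted(sim.allele_seqs.items())
    ]


class TestBuildAlignment:
    def test_equal_unit_counts(self):
        arrays = [
            segment_array(make_amplicon([UNIT_NT] * 6), f"r{i}", "sp")
            for i in range(3)
        ]
        # identical sequences need distinct ids
        for i, a in enumerate(arrays):
            a.record_id = f"r{i}"
        aln = build_codon_alignment(arrays)
        assert aln.n_sites == 28 * 6
        assert (aln.codes != MISSING).all()
        assert aln.site_to_unit_position[0] == (1, 1)
        assert aln.site_to_unit_position[-1] == (6, 28)

    def test_unequal_lengths_carry_missing(self):
        arrays = _arrays(["A", "D", "G"])  # 6, 9, 12 units
        aln = build_codon_alignment(arrays)
        assert aln.n_sites == 28 * 12
        short = aln.taxa.index("sp|A")
        assert (aln.codes[short, 28 * 6 :] == MISSING).all()
        assert (aln.codes[short, : 28 * 6] != MISSING).all()

    def test_strict_mode_rejects_unequal(self):
        arrays = _arrays(["A", "D", "G"])
        with pytest.raises(ValueError, match="unequal unit counts"):
            build_codon_alignment(arrays, strict_equal_length=True)

    def test_stop_codon_is_hard_error(self):
        arrays = _arrays(["A", "B", "C"])
        seq, _ = simulate_pseudogene(arrays[0], stops=[40])
        # rebuild the first array from the edited sequence: the stop lands
        # inside a tandem unit (outside the motif span), so the unit still
        # segments but the alignment must refuse it
        arrays[0] = segment_array(seq, "sp|Astop", "sp")
        with pytest.raises(ValueError, match="stop codon in sp|Astop"):
            build_codon_alignment(arrays)

    def test_helix_positions_from_anchor(self):
        arrays = _arrays(["A", "B", "C"])
        aln = build_codon_alignment(arrays)
        his1 = arrays[0].units[0].anchors[2]  # 24 for the consensus phase
        by_offset = {
            off: aln.helix_positions[i]
            for i, (unit, off) in enumerate(aln.site_to_unit_position)
            if unit == 1
        }
        # k >= 1 sits at his1-(7-k); k <= -1 at his1-(6-k); outside -9..6
        # the label is meaningless and must be None
        for off, k in ((his1 - 15, -9), (his1 - 16, None), (his1 - 1, 6),
                       (his1 - 7, -1), (his1 - 5, 2)):
            assert by_offset[off] == k

    def test_needs_three_arrays(self):
        arrays = _arrays(["A", "B", "C"])[:2]
        with pytest.raises(ValueError):
            build_codon_alignment(arrays)


class TestDistancesAndTree:
    def test_p_distance_range_and_symmetry(self):
        arrays = _arrays(["A", "B", "C", "D"])
        aln = build_codon_alignment(arrays)
        d = codon_p_distances(aln)
        assert np.allclose(d, d.T) and (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0)
        tree = nj_tree(aln)
        assert sorted(tree.leaf_names()) == sorted(aln.taxa)


class TestClassDistribution:
    def test_beta_discretization_normalized_and_mean(self):
        """Category probabilities sum to one; the discretized mean converges
        to p/(p+q) as K grows (K=10 vs K=100 within 0.01)."""
        p, q = 0.4, 1.7
        for K in (10, 100):
            w, om = class_distribution("M7", {"p": p, "q": q}, K)
            assert w.sum() == pytest.approx(1.0)
            assert len(om) == K
        _, om10 = class_distribution("M7", {"p": p, "q": q}, 10)
        _, om100 = class_distribution("M7", {"p": p, "q": q}, 100)
        assert abs(om10.mean() - p / (p + q)) < 0.01
        assert abs(om100.mean() - p / (p + q)) < abs(om10.mean() - p / (p + q)) + 0.01

    def test_m2a_proportions(self):
        w, om = class_distribution(
            "M2a", {"p0": 0.5, "p1": 0.3, "omega0": 0.1, "omega2": 4.0}
        )
        assert w.sum() == pytest.approx(1.0)
        assert om[1] == 1.0 and om[2] > 1

    def test_m8_structure(self):
        w, om = class_distribution(
            "M8", {"p0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 3.0}, 10
        )
        assert len(w) == 11 and w.sum() == pytest.approx(1.0)
        assert om[-1] == 3.0 and (om[:-1] < 1).all()


class TestFit:
    def test_m0_omega_recovery_near_neutral(self):
        """Data simulated under M0 with omega=1 recovers omega within 0.1."""
        aln, _, _ = simulate_codon_alignment(
            AlignmentSimConfig(tree=SIX_TAXON_TREE, model="M0",
                               params={"omega": 1.0}, n_sites=500, seed=31)
        )
        tree = parse_newick(SIX_TAXON_TREE)
        fit = fit_site_model(aln, tree, "M0", n_starts=2, seed=1)
        assert abs(fit.params["omega"] - 1.0) <= 0.1

    def test_embedded_null_guarantees_nesting(self):
        aln, _, _ = simulate_codon_alignment(
            AlignmentSimConfig(tree=SIX_TAXON_TREE, model="M1a",
                               params={"p0": 0.8, "omega0": 0.1},
                               n_sites=100, seed=32)
        )
        tree = parse_newick(SIX_TAXON_TREE)
        f1 = fit_site_model(aln, tree, "M1a", n_starts=1, seed=1, maxfev=200)
        f2 = fit_site_model(aln, tree, "M2a", n_starts=1, seed=1,
                            null_fit=f1, maxfev=60)  # starved on purpose
        assert f2.lnL >= f1.lnL

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            fit_site_model(None, None, "M3")


class TestLRT:
    def _fit(self, model, lnL):
        return FitResult(model=model, params={}, lnL=lnL, kappa=2.0,
                         weights=np.array([1.0]), omegas=np.array([1.0]),
                         converged=True)

    def test_equal_likelihoods(self):
        r = lrt(self._fit("M1a", -100.0), self._fit("M2a", -100.0))
        assert r.two_delta_l == 0 and r.p_value == 1 and r.stars == ""

    def test_chi2_closed_form(self):
        """For df=2 the survival function is exp(-x/2): 2dl=36.304 gives
        p ~ 1.3e-8."""
        r = lrt(self._fit("M7", -100.0), self._fit("M8", -100.0 + 36.304 / 2))
        assert r.two_delta_l == pytest.approx(36.304)
        assert r.p_value == pytest.approx(np.exp(-36.304 / 2), rel=1e-9)
        assert r.p_value == pytest.approx(1.3e-8, rel=0.01)
        assert r.stars == "**"

    def test_significance_stars(self):
        crit05 = stats.chi2.isf(0.05, 2)
        r = lrt(self._fit("M1a", 0.0), self._fit("M2a", (crit05 + 0.1) / 2))
        assert r.stars == "*"

    def test_non_nested_pair(self):
        with pytest.raises(ValueError, match="not nested"):
            lrt(self._fit("M7", -10.0), self._fit("M2a", -5.0))

    def test_worse_alternative_rejected(self):
        with pytest.raises(ValueError, match="refit"):
            lrt(self._fit("M1a", -10.0), self._fit("M2a", -12.0))


class TestBEB:
    def test_refuses_unconverged_fit(self):
        bad = FitResult(model="M2a", params={}, lnL=0.0, kappa=2.0,
                        weights=np.array([1.0]), omegas=np.array([1.0]),
                        converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            beb_classify(None, None, bad)

    def test_requires_positive_selection_model(self):
        bad = FitResult(model="M1a", params={}, lnL=0.0, kappa=2.0,
                        weights=np.array([1.0]), omegas=np.array([1.0]),
                        converged=True)
        with pytest.raises(ValueError, match="M2a or M8"):
            beb_classify(None, None, bad)

    def test_posteriors_are_probabilities(self):
        aln, classes, _ = simulate_codon_alignment(
            AlignmentSimConfig(tree=SIX_TAXON_TREE, model="M2a",
                               params={"p0": 0.6, "p1": 0.2, "omega0": 0.1,
                                       "omega2": 5.0},
                               n_sites=150, seed=33)
        )
        tree = parse_newick(SIX_TAXON_TREE)
        f1 = fit_site_model(aln, tree, "M1a", n_starts=1, seed=1)
        f2 = fit_site_model(aln, tree, "M2a", n_starts=1, seed=1, null_fit=f1)
        sc = beb_classify(aln, tree, f2)
        assert ((sc.p_positive >= 0) & (sc.p_positive <= 1)).all()
        assert (sc.post_mean_omega >= 0).all()
        # direction: truly positive sites get larger posteriors on average
        assert sc.p_positive[classes == 2].mean() > sc.p_positive[classes != 2].mean()
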