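"""GY94 generator, pruning likelihood, branch-site LRT and posteriors."""

import numpy as np
import pytest
from scipy.stats import chi2

from posiselect._codons import CODONS, N_STATES
from posiselect.codon_model import (BranchSiteModel, BranchSiteParams,
                                    CodonRateModel, branch_site_loglik,
                                    build_generator, f3x4_frequencies,
                                    fit_model, lrt, transition_probs,
                                    uniform_pi)
from posiselect.seq_io import CodonAlignment
from posiselect.simulator import SimulationConfig, IndelModel, evolve
from posiselect.trees import SpeciesTree

from _helpers import hand_generator as _hand_generator
from _helpers import series_expm as _series_expm

UNIF = uniform_pi()


class TestGenerator:
    def test_structure_matches_single_step_adjacency(self):
        Q = build_generator(CodonRateModel(1.0, UNIF, 1.0), normalize=False)
        H = _hand_generator(1.0, 1.0, UNIF)
        np.testing.assert_allclose(Q, H, atol=1e-14)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)

    def test_detailed_balance_all_entries(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(N_STATES))
        Q = build_generator(CodonRateModel(2.5, pi, 0.4))
        lhs = pi[:, None] * Q
        np.testing.assert_allclose(lhs, lhs.T, atol=1e-14)

    def test_expected_substitution_rate_is_one_after_scaling(self):
        pi = f3x4_frequencies(CodonAlignment(["a"], ["ATGAAACCCGGG"]))
        Q = build_generator(CodonRateModel(2.0, pi, 0.3))
        # direct summation oracle
        flow = sum(pi[i] * Q[i, j] for i in range(N_STATES)
                   for j in range(N_STATES) if i != j)
        assert flow == pytest.approx(1.0, abs=1e-10)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            CodonRateModel(2.0, np.ones(N_STATES), 1.0)


class TestTransitionProbs:
    def test_t0_is_identity(self):
        Q = build_generator(CodonRateModel(2.0, UNIF, 0.5))
        np.testing.assert_allclose(transition_probs(Q, 0.0), np.eye(N_STATES),
                                   atol=1e-12)

    def test_semigroup_property(self):
        Q = build_generator(CodonRateModel(2.0, UNIF, 0.5))
        P1, P2 = transition_probs(Q, 0.3), transition_probs(Q, 0.7)
        np.testing.assert_allclose(P1 @ P2, transition_probs(Q, 1.0),
                                   atol=1e-8)

    def test_rows_approach_stationary_distribution(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(N_STATES) * 5)
        Q = build_generator(CodonRateModel(2.0, pi, 0.5))
        P = transition_probs(Q, 50.0)
        for row in P[::10]:
            np.testing.assert_allclose(row, pi, atol=2e-5)

    def test_rows_sum_to_one(self):
        Q = build_generator(CodonRateModel(3.0, UNIF, 2.0))
        P = transition_probs(Q, 0.9)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)


class TestLikelihood:
    def test_zero_length_tree_collapses_to_stationary_probability(self):
        aln = CodonAlignment(["A", "B", "C"], ["ATG", "ATG", "ATG"])
        tree = SpeciesTree.from_newick("(A:0,B:0,C:0);")
        ll = branch_site_loglik(aln, tree,
                                BranchSiteParams(0.5, 0.4, 0.1, 2.0),
                                kappa=2.0, pi="uniform", foreground="A")
        assert ll == pytest.approx(np.log(1 / 61), abs=1e-10)

    def test_zero_length_tree_with_conflicting_data_is_minus_inf(self):
        aln = CodonAlignment(["A", "B", "C"], ["ATG", "AAA", "ATG"])
        tree = SpeciesTree.from_newick("(A:0,B:0,C:0);")
        ll = branch_site_loglik(aln, tree,
                                BranchSiteParams(0.5, 0.4, 0.1, 2.0),
                                pi="uniform", foreground="A")
        assert ll == -np.inf

    def test_duplicated_column_doubles_loglik(self):
        tree = SpeciesTree.from_newick("(A:0.1,B:0.2,C:0.15);")
        aln1 = CodonAlignment(["A", "B", "C"], ["ATG", "ATA", "ATG"])
        aln2 = CodonAlignment(["A", "B", "C"],
                              ["ATGATG", "ATAATA", "ATGATG"])
        p = BranchSiteParams(0.6, 0.3, 0.2, 3.0)
        l1 = branch_site_loglik(aln1, tree, p, pi="uniform", foreground="A")
        l2 = branch_site_loglik(aln2, tree, p, pi="uniform", foreground="A")
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_two_taxon_one_codon_matches_series_expansion_oracle(self):
        """Mixture likelihood on the smallest case against an independent
        hand-built generator + Taylor-series matrix exponential."""
        t1, t2 = 0.27, 0.48
        aln = CodonAlignment(["A", "B"], ["ATG", "AAA"])
        tree = SpeciesTree.from_newick(f"(A:{t1},B:{t2});")
        kappa = 2.0
        params = BranchSiteParams(0.55, 0.35, 0.2, 4.0)
        ll = branch_site_loglik(aln, tree, params, kappa=kappa, pi="uniform",
                                foreground="A")
        # oracle
        sA, sB = CODONS.index("ATG"), CODONS.index("AAA")
        probs = params.class_probs()
        omegas = params.class_omegas()
        rates = {}
        for w in {0.2, 1.0, 4.0}:
            Q = _hand_generator(kappa, w, UNIF)
            rates[w] = -(UNIF * np.diag(Q)).sum()
        rho = sum(p * rates[bg] for p, (bg, _) in zip(probs, omegas))
        total = 0.0
        for p, (bg, fg) in zip(probs, omegas):
            Pfg = _series_expm(_hand_generator(kappa, fg, UNIF), t1 / rho)
            Pbg = _series_expm(_hand_generator(kappa, bg, UNIF), t2 / rho)
            like = sum(UNIF[i] * Pfg[i, sA] * Pbg[i, sB]
                       for i in range(N_STATES))
            total += p * like
        assert ll == pytest.approx(np.log(total), abs=1e-8)

    def test_invariant_to_leaf_order_and_rotation(self, small_family,
                                                  nine_taxon_tree):
        aln = small_family.true_alignment
        p = BranchSiteParams(0.7, 0.2, 0.15, 3.0)
        ll = branch_site_loglik(aln, nine_taxon_tree, p, foreground="human")
        perm = list(reversed(range(aln.n_seqs)))
        aln2 = CodonAlignment([aln.species[i] for i in perm],
                              [aln.rows[i] for i in perm])
        ll2 = branch_site_loglik(aln2, nine_taxon_tree, p, foreground="human")
        assert ll == pytest.approx(ll2, rel=1e-10)


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        r = lrt(-100.0, -100.0)
        assert r.statistic == 0 and r.p_value == 1.0

    @pytest.mark.parametrize("stat,p", [(3.841459, 0.05), (6.634897, 0.01)])
    def test_chi2_quantile_pairs(self, stat, p):
        r = lrt(-100.0, -100.0 + stat / 2)
        assert r.p_value == pytest.approx(p, abs=1e-6)
        # cross-check against the distribution function directly
        assert chi2.sf(stat, 1) == pytest.approx(p, abs=1e-6)

    def test_negative_statistic_clamped(self):
        r = lrt(-99.0, -100.0)
        assert r.statistic == 0 and r.p_value == 1.0


class TestFitting:
    def test_m0_recovers_generating_omega(self, nine_taxon_tree):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(
            root_length=1200,
            indel=IndelModel(q=0.0, subst_indel_ratio=1e12))
        from posiselect.simulator import SelectionScheme
        cfg.background_scheme = SelectionScheme(np.array([0.3]),
                                                np.array([1.0]), label="m0")
        fam = evolve(cfg, rng)
        model = BranchSiteModel(fam.true_alignment, nine_taxon_tree,
                                foreground="human")
        kappa, omega, scale, _ = model.fit_m0()
        assert omega == pytest.approx(0.3, rel=0.15)
        assert kappa == pytest.approx(2.0, rel=0.2)
        assert scale == pytest.approx(3.0, rel=0.15)

    def test_nesting_alternative_at_least_null(self, small_family,
                                               nine_taxon_tree):
        res = fit_model(small_family.true_alignment, nine_taxon_tree,
                        foreground="human")
        assert res.lnL1 >= res.lnL0 - 1e-6
        assert 0 <= res.p_value <= 1

    def test_positive_selection_recovered(self, selected_family,
                                          nine_taxon_tree):
        """5% of sites with strong foreground selection: the alternative
        fit should find omega2 > 1 with a clear likelihood gain."""
        res = fit_model(selected_family.true_alignment, nine_taxon_tree,
                        foreground="human")
        assert res.foreground_omega > 1.5
        assert res.statistic > 3.84  # significant at the 5% level


class TestSitePosteriors:
    def test_posteriors_zero_when_no_selected_class(self, small_family,
                                                    nine_taxon_tree):
        model = BranchSiteModel(small_family.true_alignment, nine_taxon_tree,
                                foreground="human")
        params = BranchSiteParams(0.6, 0.4 - 1e-9, 0.2, 2.0)  # p2 ~ 0
        post = model.engine.site_posteriors(params, 2.0, 1.0)
        assert np.all(post < 1e-6)

    def test_posteriors_are_probabilities(self, selected_family,
                                          nine_taxon_tree):
        res = fit_model(selected_family.true_alignment, nine_taxon_tree,
                        foreground="human")
        assert np.all(res.site_posteriors >= 0)
        assert np.all(res.site_posteriors <= 1)
        assert len(res.site_posteriors) == \
            selected_family.true_alignment.n_codons

    def test_strongly_selected_site_flagged(self, nine_taxon_tree):
        """A site with omega 10 on the foreground among omega 0.1 sites is
        picked up with high posterior on a long-branch tree."""
        rng = np.random.default_rng(17)
        from posiselect.simulator import SelectionScheme, SimulationConfig
        scheme = SelectionScheme(np.array([0.1]), np.array([1.0]),
                                 label="custom", fg_fraction=0.04,
                                 fg_omega=10.0)
        background = SelectionScheme(np.array([0.1]), np.array([1.0]),
                                     label="custom")
        tree = nine_taxon_tree.scaled(3.0)  # long branches: strong signal
        cfg = SimulationConfig(tree=tree, root_length=400,
                               indel=IndelModel(q=0.0,
                                                subst_indel_ratio=1e12),
                               background_scheme=background,
                               scheme_per_branch={frozenset(["human"]):
                                                  scheme})
        fam = evolve(cfg, rng)
        res = fit_model(fam.true_alignment, tree, foreground="human")
        true_pos = np.flatnonzero(fam.positive_site)
        assert res.site_posteriors[true_pos].max() > 0.95


def test_results_summary_renders(selected_family, nine_taxon_tree):
    res = fit_model(selected_family.true_alignment, nine_taxon_tree,
                    foreground="human")
    text = res.summary()
    assert "Branch-site test" in text and "foreground omega2" in text
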