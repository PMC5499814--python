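"""Codon alignment, sister-taxon gating, filters, correction, full scan."""

import numpy as np
import pandas as pd
import pytest

from posiselect.codon_model import BranchSiteParams, BranchSiteResults
from posiselect.column_filter import FilterParams, filter_columns
from posiselect.selection_pipeline import (GeneResult, PlausibilityThresholds,
                                           ScanConfig, adjust_pvalues,
                                           codon_align, plausibility_filter,
                                           render_annotation, run_scan,
                                           sister_taxon_check, test_family)
from posiselect.simulator import default_species_tree


def _tx(sp, cds, tid=None, gene=None):
    from posiselect.seq_io import make_transcript
    tx, err = make_transcript(tid or f"{sp}_t", gene or f"{sp}_g", sp, cds)
    assert err is None, err
    return tx


class TestCodonAlign:
    def test_identical_cds_gap_free(self):
        cds = "ATGAAACCCGGGTTT"
        txs = [_tx(sp, cds) for sp in ("a", "b", "c")]
        aln = codon_align(txs)
        assert aln.rows == [cds] * 3

    def test_extra_internal_codon_gives_single_codon_gap(self):
        """Back-threading oracle: the protein alignment has one gap, so the
        codon alignment must show exactly one --- at the same position."""
        base = "ATGAAACCCGGGTTTGAACAT"
        extra = "ATGAAACCCTGGGGGTTTGAACAT"  # +TGG (W) after codon 3
        txs = [_tx("a", extra), _tx("b", base), _tx("c", base)]
        aln = codon_align(txs)
        assert aln.n_codons == 8
        assert aln.row("b")[9:12] == "---" and "---" not in aln.row("a")
        # removing gaps recovers the inputs
        assert aln.row("a").replace("-", "") == extra
        assert aln.row("b").replace("-", "") == base

    def test_fewer_than_three_sequences_rejected(self):
        txs = [_tx("a", "ATGAAA"), _tx("b", "ATGAAA")]
        with pytest.raises(ValueError, match="at least 3"):
            codon_align(txs)
        assert test_family(txs, default_species_tree(), "human") is None


class TestSisterTaxon:
    def test_terminal_branch_with_sister_present(self, nine_taxon_tree):
        assert sister_taxon_check(nine_taxon_tree, "human",
                                  ["human", "chimp", "mouse"])

    def test_terminal_branch_without_sister(self, nine_taxon_tree):
        assert not sister_taxon_check(nine_taxon_tree, "human",
                                      ["human", "mouse", "rat", "dog"])

    def test_internal_branch_with_sister(self, nine_taxon_tree):
        # testing the human+chimp ancestor: gorilla is the sister
        assert sister_taxon_check(nine_taxon_tree, {"human", "chimp"},
                                  ["human", "chimp", "gorilla"])
        assert not sister_taxon_check(nine_taxon_tree, {"human", "chimp"},
                                      ["human", "chimp", "mouse"])

    def test_foreground_absent_is_false(self, nine_taxon_tree):
        assert not sister_taxon_check(nine_taxon_tree, "human",
                                      ["mouse", "rat", "chimp"])


def _result(**kw):
    defaults = dict(gene_id="g", anchor_transcript="t", n_species=6,
                    n_codons_retained=200, anchor_frac_retained=0.9,
                    fit=None)
    defaults.update(kw)
    return GeneResult(**defaults)


def _fit(omega2=2.0, p0=0.7, p1=0.2, posteriors=None, converged=True):
    post = np.asarray(posteriors if posteriors is not None else [0.1] * 50)
    return BranchSiteResults(
        lnL0=-100, lnL1=-98, statistic=4.0, p_value=0.045, kappa=2.0,
        scale=1.0, m0_omega=0.2, params_null=BranchSiteParams(p0, p1, 0.1),
        params_alt=BranchSiteParams(p0, p1, 0.1, omega2),
        site_posteriors=post, converged=converged, n_codons=200,
        foreground=frozenset(["human"]))


class TestPlausibility:
    def test_extreme_omega_flagged(self):
        r = plausibility_filter(_result(fit=_fit(omega2=150.0)))
        assert "omega_extreme" in r.filter_flags
        assert not r.is_psg()

    def test_too_few_columns(self):
        r = plausibility_filter(_result(n_codons_retained=40,
                                        fit=_fit()),
                                PlausibilityThresholds(min_cols=50))
        assert "too_few_columns" in r.filter_flags

    def test_low_anchor_fraction(self):
        r = plausibility_filter(_result(anchor_frac_retained=0.1, fit=_fit()))
        assert "too_few_columns" in r.filter_flags

    def test_too_many_selected_sites(self):
        r = plausibility_filter(_result(
            fit=_fit(p0=0.05, p1=0.05, posteriors=[0.9] * 50)))
        assert "too_many_selected_sites" in r.filter_flags

    def test_nonconvergent_flagged(self):
        r = plausibility_filter(_result(fit=_fit(converged=False)))
        assert "nonconvergent" in r.filter_flags

    def test_clean_result_is_psg_eligible(self):
        r = plausibility_filter(_result(fit=_fit()))
        assert r.filter_flags == set()
        assert r.is_psg(alpha=0.05)


class TestAdjustPvalues:
    def test_bonferroni_hand_value(self):
        out = adjust_pvalues([0.01, 0.5, 0.2, 0.9, 0.03], "bonferroni")
        assert out[0] == pytest.approx(0.05)

    def test_bh_hand_stepup_vector(self):
        # p(i)*n/i = (0.04, 0.04, 0.04, 0.04) after cumulative minimum
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_bh_between_nominal_and_bonferroni(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        bh = adjust_pvalues(p, "bh")
        bonf = adjust_pvalues(p, "bonferroni")
        assert np.all(bh >= p - 1e-12) and np.all(bh <= bonf + 1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm")


from _helpers import toy_groups as _toy_groups


class TestRunScan:
    def test_empty_catalog(self, nine_taxon_tree):
        config = ScanConfig(groups=[], tree=nine_taxon_tree,
                            anchor_species="human", foreground="human")
        table, report = run_scan(config)
        assert len(table) == 0 and report["n_tested"] == 0

    def test_every_assignment_accounted_for(self, nine_taxon_tree):
        groups = _toy_groups()
        config = ScanConfig(groups=groups, tree=nine_taxon_tree,
                            anchor_species="human", foreground="human")
        table, report = run_scan(config)
        skipped = [s for s in report["skipped"]]
        assert len(table) + len(skipped) == report["n_assignments"]
        assert list(table["p"]) == sorted(table["p"])

    def test_thread_count_does_not_change_output(self, nine_taxon_tree):
        groups = _toy_groups()
        cfg1 = ScanConfig(groups=groups, tree=nine_taxon_tree,
                          anchor_species="human", foreground="human",
                          threads=1)
        cfg4 = ScanConfig(groups=_toy_groups(), tree=nine_taxon_tree,
                          anchor_species="human", foreground="human",
                          threads=4)
        t1, _ = run_scan(cfg1)
        t4, _ = run_scan(cfg4)
        pd.testing.assert_frame_equal(t1, t4)
        assert t1.to_csv(sep="\t") == t4.to_csv(sep="\t")


class TestRenderAnnotation:
    def test_records_join_posterior_and_domains(self, nine_taxon_tree):
        groups = _toy_groups(1, seed=3)
        txs = [groups[0].members[sp][0]
               for sp in ("human", "chimp", "mouse", "dog")]
        aln = codon_align(txs)
        mask = filter_columns(aln, FilterParams(min_block=2))
        result = test_family(txs, nine_taxon_tree, "human",
                             filter_params=FilterParams(min_block=2),
                             thresholds=PlausibilityThresholds(min_cols=5))
        domains = [(1, 10, "DomainX")]
        df, html = render_annotation(result, aln, mask, "human", domains)
        assert {"anchor_pos", "anchor_aa", "tested", "posterior",
                "domains"} <= set(df.columns)
        in_dom = df[df.anchor_pos <= 10]
        assert (in_dom.domains == "DomainX").all()
        # anchor positions map bijectively onto non-gap anchor columns
        assert list(df.anchor_pos) == list(range(1, len(df) + 1))
        assert df.alignment_column.is_unique
        assert "<html>" in html and "DomainX" not in html  # html shows MSA
        tested = df[df.tested]
        assert tested.posterior.notna().all()
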