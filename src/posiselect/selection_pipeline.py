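"""End-to-end scan for positively selected genes on a chosen branch.

For every isoform assignment: build the codon alignment (translate → align →
back-thread), remove unreliable columns, require a sister-taxon species,
run the branch-site likelihood-ratio test, apply plausibility filters and
multiple-testing correction, and emit a ranked result table.  A gene counts
as a PSG when its nominal p ≤ α and no plausibility filter fired.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._codons import codons_of, translate_codon
from .align import backthread_codons, progressive_protein_msa
from .codon_model import BranchSiteModel, BranchSiteResults
from .column_filter import ColumnMask, FilterParams, filter_columns
from .isoform_selection import (FilterThresholds, IsoformAssignment,
                                filter_divergent, select_isoforms)
from .seq_io import CodonAlignment, OrthologGroup, Transcript
from .trees import SpeciesTree

__all__ = [
    "PlausibilityThresholds", "GeneResult", "ScanConfig",
    "codon_align", "sister_taxon_check", "plausibility_filter",
    "adjust_pvalues", "run_scan", "test_family", "render_annotation",
]


@dataclass
class PlausibilityThresholds:
    """Cutoffs for discarding implausible branch-site results."""

    min_cols: int = 50            #: minimum retained codon columns
    min_anchor_frac: float = 0.2  #: minimum retained fraction of anchor codons
    min_seqs: int = 3
    omega_cap: float = 100.0      #: foreground ω at/above this is implausible
    max_p2: float = 0.8           #: maximum estimated p2a+p2b
    max_selected_frac: float = 0.6  #: max fraction of sites with posterior>0.5


@dataclass
class GeneResult:
    """Outcome of the branch-site test for one isoform assignment."""

    gene_id: str
    anchor_transcript: str
    n_species: int
    n_codons_retained: int
    anchor_frac_retained: float
    fit: Optional[BranchSiteResults]
    filter_flags: set = field(default_factory=set)
    p_bonferroni: float = np.nan
    p_bh: float = np.nan
    #: (anchor codon position 1-based, anchor amino acid, posterior)
    selected_sites: list = field(default_factory=list)

    @property
    def p_value(self) -> float:
        return self.fit.p_value if self.fit is not None else np.nan

    @property
    def foreground_omega(self) -> float:
        return self.fit.foreground_omega if self.fit is not None else np.nan

    def is_psg(self, alpha: float = 0.05) -> bool:
        return (self.fit is not None and not self.filter_flags
                and self.p_value <= alpha)


# ---------------------------------------------------------------------------
# individual steps


def codon_align(assignment_or_transcripts, aligner=None) -> CodonAlignment:
    """Codon-level alignment of one-transcript-per-species sets.

    Proteins are aligned progressively and each residue is threaded back to
    its source codon.  `aligner` may replace the internal protein MSA with
    any callable `list[str] -> list[str]` (adapter seam for external tools).
    """
    txs = _as_transcripts(assignment_or_transcripts)
    if len(txs) < 3:
        raise ValueError("need at least 3 sequences for the selection test")
    proteins = [_protein(t) for t in txs]
    msa = (aligner or progressive_protein_msa)(proteins)
    return backthread_codons(msa, [t.cds for t in txs],
                             [t.species for t in txs],
                             [t.transcript_id for t in txs])


def _as_transcripts(obj) -> list[Transcript]:
    if isinstance(obj, IsoformAssignment):
        return obj.all_transcripts()
    return list(obj)


def _protein(t: Transcript) -> str:
    if t.protein:
        return t.protein
    return "".join(translate_codon(c) for c in codons_of(t.cds))


def sister_taxon_check(tree: SpeciesTree, foreground, species_in_msa) -> bool:
    """True iff at least one MSA species belongs to the sister clade of the
    tested branch; localises selection to the branch of interest."""
    species = frozenset(species_in_msa)
    fg = frozenset([foreground]) if isinstance(foreground, str) \
        else frozenset(foreground)
    if not fg & species:
        return False
    t = tree.copy()
    t.set_foreground(fg)
    return bool(t.sister_species() & species)


def plausibility_filter(result: GeneResult,
                        thresholds: Optional[PlausibilityThresholds] = None
                        ) -> GeneResult:
    """Attach implausibility flags; flags are additive and a flagged result
    is never counted as a PSG."""
    th = thresholds or PlausibilityThresholds()
    flags = result.filter_flags
    if (result.n_codons_retained < th.min_cols
            or result.anchor_frac_retained < th.min_anchor_frac):
        flags.add("too_few_columns")
    if result.n_species < th.min_seqs:
        flags.add("too_few_sequences")
    fit = result.fit
    if fit is not None:
        if fit.foreground_omega >= th.omega_cap:
            flags.add("omega_extreme")
        pa = fit.params_alt
        if pa is not None:
            frac_sites = float((fit.site_posteriors > 0.5).mean()) \
                if len(fit.site_posteriors) else 0.0
            if pa.p2a + pa.p2b > th.max_p2 or frac_sites > th.max_selected_frac:
                flags.add("too_many_selected_sites")
        if not fit.converged:
            flags.add("nonconvergent")
    return result


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Bonferroni or Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown method {method!r}")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
    return multipletests(p, method=sm_method)[1]


# ---------------------------------------------------------------------------
# per-gene driver


def test_family(transcripts: Iterable[Transcript], tree: SpeciesTree,
                foreground, anchor_species: Optional[str] = None,
                filter_params: Optional[FilterParams] = None,
                thresholds: Optional[PlausibilityThresholds] = None,
                gene_id: Optional[str] = None,
                aligner=None) -> Optional[GeneResult]:
    """Align, filter and branch-site-test one one-transcript-per-species set.

    Returns None when the set has fewer than 3 sequences (skipped, as in the
    scan report); otherwise a GeneResult, possibly flagged.
    """
    txs = list(transcripts)
    if len(txs) < 3:
        return None
    fg = frozenset([foreground]) if isinstance(foreground, str) \
        else frozenset(foreground)
    if anchor_species is None:
        anchor_species = sorted(fg)[0]
    species = [t.species for t in txs]
    if anchor_species not in species:
        anchor_species = species[0]
    anchor_tx = txs[species.index(anchor_species)]
    gid = gene_id or anchor_tx.gene_id
    result = GeneResult(gene_id=gid, anchor_transcript=anchor_tx.transcript_id,
                        n_species=len(txs), n_codons_retained=0,
                        anchor_frac_retained=0.0, fit=None)

    if not sister_taxon_check(tree, fg, species):
        result.filter_flags.add("no_sister_taxon")
        return result

    aln = codon_align(txs, aligner=aligner)
    mask = filter_columns(aln, filter_params)
    n_anchor = len(anchor_tx)
    result.n_codons_retained = mask.n_kept
    result.anchor_frac_retained = mask.n_kept / n_anchor if n_anchor else 0.0

    th = thresholds or PlausibilityThresholds()
    if mask.n_kept >= max(th.min_cols, 1):
        masked = aln.subset_columns(mask.keep)
        model = BranchSiteModel(masked, tree, foreground=fg)
        fit = model.fit()
        result.fit = fit
        # map selected sites back to anchor codon coordinates
        anchor_map = aln.anchor_codon_map(anchor_species)
        kept_cols = np.flatnonzero(mask.keep)
        anchor_prot = _protein(anchor_tx)
        for local_col in fit.selected_sites:
            col = kept_cols[local_col]
            pos = int(anchor_map[col])
            if pos > 0:
                result.selected_sites.append(
                    (pos, anchor_prot[pos - 1],
                     float(fit.site_posteriors[local_col])))
    return plausibility_filter(result, th)


test_family.__test__ = False  # not a pytest case despite the name


# ---------------------------------------------------------------------------
# genome-scale scan


@dataclass
class ScanConfig:
    groups: list[OrthologGroup]
    tree: SpeciesTree
    anchor_species: str
    foreground: object  # species name or leaf set
    alpha: float = 0.05
    isoform_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    filter_params: FilterParams = field(default_factory=FilterParams)
    plausibility: PlausibilityThresholds = field(default_factory=PlausibilityThresholds)
    threads: int = 1
    aligner: Optional[object] = None


def run_scan(config: ScanConfig):
    """Scan all ortholog groups; returns (ranked DataFrame, report dict).

    Every input assignment is accounted for: tested, skipped (with reason)
    or filtered (with flags).  Output is deterministic and independent of
    the thread count (results are merged in gene order).
    """
    tasks = []
    report = {"skipped": [], "n_assignments": 0}
    for group in sorted(config.groups, key=lambda g: g.group_id):
        if config.anchor_species not in group.members:
            report["skipped"].append((group.group_id, "*", "no_anchor_species"))
            continue
        assignments = select_isoforms(group, config.anchor_species)
        for assignment in assignments:
            report["n_assignments"] += 1
            reduced, removals = filter_divergent(assignment,
                                                 config.isoform_thresholds)
            txs = reduced.all_transcripts()
            key = (group.group_id, reduced.anchor.transcript_id)
            if len(txs) < 3:
                report["skipped"].append(
                    (key[0], key[1], "fewer_than_3_sequences"))
                continue
            tasks.append((key, txs))

    def run_one(task):
        (gid, anchor_tid), txs = task
        res = test_family(
            txs, config.tree, config.foreground,
            anchor_species=config.anchor_species,
            filter_params=config.filter_params,
            thresholds=config.plausibility,
            gene_id=gid, aligner=config.aligner)
        return (gid, anchor_tid), res

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = dict(pool.map(run_one, tasks))
    else:
        results = dict(map(run_one, tasks))

    ordered = sorted(results.items())
    rows = []
    tested = [(key, r) for key, r in ordered if r is not None
              and r.fit is not None]
    pvals = [r.p_value for _, r in tested]
    if pvals:
        bonf = adjust_pvalues(pvals, "bonferroni")
        bh = adjust_pvalues(pvals, "bh")
        for (key, r), pb, ph in zip(tested, bonf, bh):
            r.p_bonferroni = float(pb)
            r.p_bh = float(ph)
    for (gid, anchor_tid), r in ordered:
        if r is None:
            report["skipped"].append((gid, anchor_tid, "fewer_than_3_sequences"))
            continue
        fit = r.fit
        rows.append({
            "gene": gid,
            "transcript": r.anchor_transcript,
            "n_species": r.n_species,
            "codons_retained": r.n_codons_retained,
            "frac_anchor_retained": round(r.anchor_frac_retained, 4),
            "lnL0": fit.lnL0 if fit else np.nan,
            "lnL1": fit.lnL1 if fit else np.nan,
            "lrt_stat": fit.statistic if fit else np.nan,
            "p": r.p_value,
            "p_bonf": r.p_bonferroni,
            "p_bh": r.p_bh,
            "fg_omega": r.foreground_omega,
            "n_sites_p95": len(r.selected_sites),
            "sites": ";".join(f"{p}{aa}:{post:.3f}"
                              for p, aa, post in r.selected_sites),
            "flags": ",".join(sorted(r.filter_flags)),
            "psg": r.is_psg(config.alpha),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["p", "gene"], na_position="last",
                                  kind="mergesort").reset_index(drop=True)
    report["n_tested"] = len(tested)
    report["n_psg"] = int(table["psg"].sum()) if len(table) else 0
    return table, report


# ---------------------------------------------------------------------------
# annotation rendering


def render_annotation(result: GeneResult, alignment: CodonAlignment,
                      mask: ColumnMask, anchor_species: str,
                      domains=None) -> tuple[pd.DataFrame, str]:
    """Per-anchor-residue annotation (TSV-ready DataFrame + HTML view).

    Columns: anchor position/amino acid, alignment column, tested flag
    (inside a kept block), posterior where tested, overlapping domains.
    """
    domains = domains or []
    anchor_map = alignment.anchor_codon_map(anchor_species)
    kept_cols = np.flatnonzero(mask.keep)
    col_to_local = {int(c): i for i, c in enumerate(kept_cols)}
    post = result.fit.site_posteriors if result.fit is not None else None
    anchor_row = alignment.row(anchor_species)
    records = []
    for col in range(alignment.n_codons):
        pos = int(anchor_map[col])
        if pos == 0:
            continue
        codon = anchor_row[3 * col: 3 * col + 3]
        tested = bool(mask.keep[col])
        posterior = np.nan
        if tested and post is not None and col in col_to_local:
            posterior = float(post[col_to_local[col]])
        labels = [lab for s, e, lab in domains if s <= pos <= e]
        records.append({
            "anchor_pos": pos,
            "anchor_aa": translate_codon(codon),
            "alignment_column": col + 1,
            "tested": tested,
            "posterior": posterior,
            "selected": tested and posterior > result.fit.posterior_threshold
            if result.fit is not None and not np.isnan(posterior) else False,
            "domains": ";".join(labels),
        })
    df = pd.DataFrame(records)
    html = _annotation_html(result, alignment, mask, df, anchor_species)
    return df, html


def _annotation_html(result, alignment, mask, df, anchor_species) -> str:
    sel_cols = {int(r.alignment_column) - 1 for r in df.itertuples()
                if r.selected}
    lines = ["<html><head><style>",
             ".kept{background:#d8f0d8}.sel{background:#f0b0b0;font-weight:bold}",
             "pre{font-family:monospace}</style></head><body>",
             f"<h2>{result.gene_id} — branch-site annotation</h2>",
             f"<p>p = {result.p_value:.4g}; foreground &omega; = "
             f"{result.foreground_omega:.3g}; flags: "
             f"{', '.join(sorted(result.filter_flags)) or 'none'}</p>", "<pre>"]
    width = 60
    for start in range(0, alignment.n_codons, width):
        stop = min(start + width, alignment.n_codons)
        for sp, row in zip(alignment.species, alignment.rows):
            cells = []
            for col in range(start, stop):
                aa = translate_codon(row[3 * col: 3 * col + 3]) \
                    if row[3 * col: 3 * col + 3] != "---" else "-"
                cls = "sel" if col in sel_cols else (
                    "kept" if mask.keep[col] else "")
                cells.append(f'<span class="{cls}">{aa}</span>' if cls else aa)
            lines.append(f"{sp:>12} {''.join(cells)}")
        lines.append("")
    lines.append("</pre></body></html>")
    return "\n".join(lines)
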