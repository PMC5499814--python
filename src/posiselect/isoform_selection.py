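"""Anchor-based isoform selection and divergence filtering.

For every isoform of a chosen anchor species, the most similar isoform of
each other species is picked from a protein MSA computed once over *all*
isoforms of the ortholog group — one isoform assignment per anchor isoform.
Similarity is the fraction of identical residues over MSA columns where
both sequences are non-gap, which is robust to alternative exons.

Divergent sequences are then removed in two stages: sequences below an
anchor-similarity threshold are dropped outright; afterwards, while any
remaining non-anchor sequence violates the pairwise threshold against
another, the sequence with the most violations is removed (ties broken by
the lowest anchor similarity), recounting after every removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import pairwise_identity, progressive_protein_msa
from .seq_io import OrthologGroup, Transcript

__all__ = ["IsoformAssignment", "FilterThresholds", "select_isoforms",
           "filter_divergent", "progressive_protein_msa"]


@dataclass
class FilterThresholds:
    """Similarity thresholds of the two-stage divergence filter."""

    theta_anchor: float = 0.5
    theta_pair: float = 0.5

    def __post_init__(self):
        if not (0 <= self.theta_anchor <= 1 and 0 <= self.theta_pair <= 1):
            raise ValueError("thresholds must be in [0, 1]")


@dataclass
class IsoformAssignment:
    """One transcript per species, anchored on one anchor-species isoform."""

    anchor: Transcript
    chosen: dict[str, Transcript] = field(default_factory=dict)
    similarity_to_anchor: dict[str, float] = field(default_factory=dict)
    pairwise_similarity: dict[frozenset, float] = field(default_factory=dict)

    def species(self) -> list[str]:
        return [self.anchor.species] + sorted(self.chosen)

    def all_transcripts(self) -> list[Transcript]:
        return [self.anchor] + [self.chosen[s] for s in sorted(self.chosen)]

    def __len__(self) -> int:
        return 1 + len(self.chosen)


def select_isoforms(group: OrthologGroup, anchor_species: str,
                    aligner=None) -> list[IsoformAssignment]:
    """One IsoformAssignment per anchor isoform of the group.

    Raises ValueError if the anchor species is absent (callers report and
    skip such groups).
    """
    if anchor_species not in group.members:
        raise ValueError(
            f"group {group.group_id} has no {anchor_species} member")
    txs = sorted(group.transcripts(), key=lambda t: t.key)
    if len(txs) == 1:
        only = txs[0]
        return [IsoformAssignment(anchor=only)]
    proteins = [t.protein for t in txs]
    msa = (aligner or progressive_protein_msa)(proteins)
    rows = {t.key: row for t, row in zip(txs, msa)}

    assignments = []
    anchors = sorted(group.members[anchor_species], key=lambda t: t.key)
    other_species = sorted(s for s in group.members if s != anchor_species)
    for anchor in anchors:
        a = IsoformAssignment(anchor=anchor)
        arow = rows[anchor.key]
        for sp in other_species:
            best = None
            for tx in sorted(group.members[sp], key=lambda t: t.key):
                ident = pairwise_identity(arow, rows[tx.key])
                if best is None or ident > best[0] + 1e-12:
                    best = (ident, tx)
            a.chosen[sp] = best[1]
            a.similarity_to_anchor[sp] = best[0]
        chosen_sp = sorted(a.chosen)
        for i, s1 in enumerate(chosen_sp):
            for s2 in chosen_sp[i + 1:]:
                a.pairwise_similarity[frozenset((s1, s2))] = pairwise_identity(
                    rows[a.chosen[s1].key], rows[a.chosen[s2].key])
        assignments.append(a)
    return assignments


def filter_divergent(assignment: IsoformAssignment,
                     thresholds: Optional[FilterThresholds] = None
                     ) -> tuple[IsoformAssignment, list[dict]]:
    """Two-stage divergence filter; returns (reduced assignment, removal log).

    The anchor is never removed and the output is a subset of the input.
    """
    th = thresholds or FilterThresholds()
    log: list[dict] = []
    keep = dict(assignment.chosen)

    for sp in sorted(keep):
        sim = assignment.similarity_to_anchor.get(sp, 0.0)
        if sim < th.theta_anchor:
            log.append({"species": sp, "transcript": keep[sp].transcript_id,
                        "reason": "below_anchor_threshold",
                        "similarity": sim, "violations": 0})
            del keep[sp]

    while True:
        violations = {sp: 0 for sp in keep}
        for pair, sim in assignment.pairwise_similarity.items():
            s1, s2 = sorted(pair)
            if s1 in keep and s2 in keep and sim < th.theta_pair:
                violations[s1] += 1
                violations[s2] += 1
        worst = max(violations.values(), default=0)
        if worst == 0:
            break
        # most violations first; ties → lowest anchor similarity, then name
        victim = min(
            (sp for sp, v in violations.items() if v == worst),
            key=lambda sp: (assignment.similarity_to_anchor.get(sp, 0.0), sp))
        log.append({"species": victim,
                    "transcript": keep[victim].transcript_id,
                    "reason": "pairwise_violations",
                    "similarity": assignment.similarity_to_anchor.get(victim, 0.0),
                    "violations": worst})
        del keep[victim]

    reduced = IsoformAssignment(
        anchor=assignment.anchor,
        chosen=keep,
        similarity_to_anchor={s: assignment.similarity_to_anchor[s]
                              for s in keep},
        pairwise_similarity={p: v for p, v in
                             assignment.pairwise_similarity.items()
                             if all(s in keep for s in p)},
    )
    return reduced, log
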