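"""Ortholog-catalog construction by group-to-group best-bidirectional hits.

A gene of a new species joins an existing ortholog group if and only if the
best similarity hit over all of the gene's isoforms lands inside that
group, and the best hit from the group's members back into the new species
lands on an isoform of that same gene.  Similarity is Smith–Waterman local
alignment under BLOSUM62 with affine gaps (open 11, extend 1), with a
shared-5-mer prescreen standing in for a word-based search heuristic.
Hits below a noise floor (identity < 0.25 or aligned length < 30 residues)
are ignored.

A seed catalog can be supplied as TSV, or built de novo by single-linkage
clustering of bidirectional best hits among a core species set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .align import shared_kmer_count
from .seq_io import OrthologGroup, Transcript

__all__ = ["SimilarityHit", "ScoreFloor", "protein_similarity",
           "best_hit_group", "assign_species", "seed_catalog_de_novo"]


@dataclass(frozen=True)
class SimilarityHit:
    query_transcript: str
    subject_transcript: str
    score: float
    identity: float


@dataclass(frozen=True)
class ScoreFloor:
    min_identity: float = 0.25
    min_aligned_length: int = 30

    def passes(self, hit: "SimilarityHit", aligned_length: int) -> bool:
        return (hit.identity >= self.min_identity
                and aligned_length >= self.min_aligned_length)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()
_B62_ALPHABET = set(_ALIGNER.substitution_matrix.alphabet)


def _sanitize(seq: str) -> str:
    return "".join(c if c in _B62_ALPHABET else "X" for c in seq.upper())


def protein_similarity(a: str, b: str) -> tuple[SimilarityHit, int]:
    """Best local alignment of two proteins.

    Returns the hit plus the aligned length (columns of the local
    alignment) used for the noise floor.  Scoring is symmetric and
    deterministic for a fixed pair.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    alignment = _ALIGNER.align(_sanitize(a), _sanitize(b))[0]
    aligned_cols = 0
    identical = 0
    for (s1, e1), (s2, e2) in zip(*alignment.aligned):
        aligned_cols += e1 - s1
        for x, y in zip(alignment.target[s1:e1], alignment.query[s2:e2]):
            identical += x == y
    identity = identical / aligned_cols if aligned_cols else 0.0
    hit = SimilarityHit("query", "subject", float(alignment.score), identity)
    return hit, aligned_cols


def _score_pair(a: Transcript, b: Transcript, floor: ScoreFloor,
                prescreen_kmers: int) -> Optional[SimilarityHit]:
    if prescreen_kmers > 0 and shared_kmer_count(a.protein, b.protein) \
            < prescreen_kmers:
        return None
    hit, cols = protein_similarity(a.protein, b.protein)
    if not floor.passes(hit, cols):
        return None
    return SimilarityHit(a.transcript_id, b.transcript_id, hit.score,
                         hit.identity)


ScoreFn = Callable[[Transcript, Transcript], Optional[SimilarityHit]]


def _default_scorer(floor: ScoreFloor, prescreen_kmers: int) -> ScoreFn:
    def score(a: Transcript, b: Transcript) -> Optional[SimilarityHit]:
        return _score_pair(a, b, floor, prescreen_kmers)
    return score


def best_hit_group(gene_isoforms: list[Transcript],
                   catalog: Iterable[OrthologGroup],
                   scorer: Optional[ScoreFn] = None,
                   floor: Optional[ScoreFloor] = None,
                   prescreen_kmers: int = 2):
    """Group holding the best hit over all isoform × member pairs, or None.

    Ties on score are broken by the lexicographically smallest
    (group_id, subject_transcript_id).
    """
    scorer = scorer or _default_scorer(floor or ScoreFloor(), prescreen_kmers)
    best = None  # (-score, group_id, subject_tid, hit)
    for group in catalog:
        for member in sorted(group.transcripts(), key=lambda t: t.key):
            for iso in sorted(gene_isoforms, key=lambda t: t.key):
                hit = scorer(iso, member)
                if hit is None:
                    continue
                key = (-hit.score, group.group_id, member.transcript_id)
                if best is None or key < best[0]:
                    best = (key, group.group_id, hit)
    if best is None:
        return None
    return best[1], best[2]


def _best_subject(queries: list[Transcript], subjects: list[Transcript],
                  scorer: ScoreFn) -> Optional[tuple[Transcript, SimilarityHit]]:
    best = None
    for subject in sorted(subjects, key=lambda t: t.key):
        for query in sorted(queries, key=lambda t: t.key):
            hit = scorer(query, subject)
            if hit is None:
                continue
            key = (-hit.score, subject.key)
            if best is None or key < best[0]:
                best = (key, subject, hit)
    if best is None:
        return None
    return best[1], best[2]


def assign_species(catalog: list[OrthologGroup],
                   new_transcripts: list[Transcript],
                   scorer: Optional[ScoreFn] = None,
                   floor: Optional[ScoreFloor] = None,
                   prescreen_kmers: int = 2):
    """Group-to-group best-bidirectional-hit assignment of one new species.

    Gene X joins group Y iff X's best hit (over all its isoforms) lies in Y
    *and* Y's best hit into the new species lands on an isoform of X.
    Returns (extended catalog, report) where the report lists unassigned
    genes with reasons; each gene joins at most one group and input order
    never affects the result.
    """
    species = {t.species for t in new_transcripts}
    if len(species) != 1:
        raise ValueError("assign_species expects transcripts of one species")
    sp = species.pop()
    if any(sp in g.members for g in catalog):
        raise ValueError(f"species {sp!r} already present in catalog")
    scorer = scorer or _default_scorer(floor or ScoreFloor(), prescreen_kmers)

    genes: dict[str, list[Transcript]] = {}
    for t in sorted(new_transcripts, key=lambda t: t.key):
        genes.setdefault(t.gene_id, []).append(t)

    report = {"assigned": {}, "unassigned": []}
    # best hit from each group into the whole new-species set (computed once)
    group_best: dict[str, Optional[tuple[Transcript, SimilarityHit]]] = {}
    for group in catalog:
        members = sorted(group.transcripts(), key=lambda t: t.key)
        group_best[group.group_id] = _best_subject(
            members, sorted(new_transcripts, key=lambda t: t.key), scorer)

    assignments: dict[str, str] = {}
    for gene_id in sorted(genes):
        fwd = best_hit_group(genes[gene_id], catalog, scorer=scorer)
        if fwd is None:
            report["unassigned"].append((gene_id, "no_hit_above_floor"))
            continue
        gid, hit = fwd
        back = group_best[gid]
        if back is None:
            report["unassigned"].append((gene_id, "group_has_no_back_hit"))
            continue
        back_tx, _ = back
        if back_tx.gene_id != gene_id:
            report["unassigned"].append((gene_id, "not_bidirectional"))
            continue
        assignments[gene_id] = gid

    extended = []
    for group in catalog:
        g = OrthologGroup(group.group_id,
                          {s: list(txs) for s, txs in group.members.items()})
        extended.append(g)
    by_id = {g.group_id: g for g in extended}
    for gene_id, gid in sorted(assignments.items()):
        for tx in genes[gene_id]:
            by_id[gid].add(tx)
        report["assigned"][gene_id] = gid
    return extended, report


def seed_catalog_de_novo(core_transcripts: list[Transcript],
                         scorer: Optional[ScoreFn] = None,
                         floor: Optional[ScoreFloor] = None,
                         prescreen_kmers: int = 2) -> list[OrthologGroup]:
    """Seed groups by single-linkage over bidirectional best gene pairs
    among a core species set (replacement for a curated seed database)."""
    scorer = scorer or _default_scorer(floor or ScoreFloor(), prescreen_kmers)
    genes: dict[tuple[str, str], list[Transcript]] = {}
    for t in sorted(core_transcripts, key=lambda t: t.key):
        genes.setdefault((t.species, t.gene_id), []).append(t)
    keys = sorted(genes)
    # best partner of each gene in every other species
    best: dict[tuple, dict[str, tuple]] = {k: {} for k in keys}
    for k in keys:
        for other_sp in sorted({s for s, _ in keys if s != k[0]}):
            subjects = [t for kk in keys if kk[0] == other_sp
                        for t in genes[kk]]
            found = _best_subject(genes[k], subjects, scorer)
            if found is not None:
                tx, hit = found
                best[k][other_sp] = ((tx.species, tx.gene_id), hit)
    # union-find over bidirectional best pairs
    parent = {k: k for k in keys}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in keys:
        for other_sp, (partner, _) in best[k].items():
            back = best[partner].get(k[0])
            if back is not None and back[0] == k:
                ra, rb = find(k), find(partner)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[tuple, list[tuple]] = {}
    for k in keys:
        clusters.setdefault(find(k), []).append(k)
    groups = []
    for i, root in enumerate(sorted(clusters), 1):
        members = clusters[root]
        if len(members) < 2:
            continue
        g = OrthologGroup(f"G{i:05d}")
        for k in members:
            for tx in genes[k]:
                g.add(tx)
        groups.append(g)
    return groups
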