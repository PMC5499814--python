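"""Bidirectional-best-hit ortholog assignment and its scoring primitive."""

import numpy as np
import pytest

from posiselect.ortholog_catalog import (ScoreFloor, SimilarityHit,
                                         assign_species, best_hit_group,
                                         protein_similarity,
                                         seed_catalog_de_novo)
from posiselect.seq_io import OrthologGroup, Transcript

AA = list("ARNDCQEGHILKMFPSTWYV")


def _tx(sp, gene, tid, protein="M" * 40):
    return Transcript(tid, gene, sp, "ATG" * len(protein), protein)


def test_hand_summed_blosum62_score():
    # M↔M=5, K↔K=5, V↔V=4 on the BLOSUM62 diagonal
    hit, cols = protein_similarity("MKV", "MKV")
    assert hit.score == 14 and hit.identity == 1.0 and cols == 3


def test_identical_sequences_score_equals_self_score():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(AA, 100))
    hit, cols = protein_similarity(seq, seq)
    assert hit.identity == 1.0 and cols == 100
    hit2, _ = protein_similarity(seq, seq)
    assert hit.score == hit2.score  # deterministic


def test_symmetric_scoring():
    rng = np.random.default_rng(2)
    for _ in range(5):
        a = "".join(rng.choice(AA, 60))
        b = "".join(rng.choice(AA, 60))
        ha, _ = protein_similarity(a, b)
        hb, _ = protein_similarity(b, a)
        assert ha.score == hb.score


def test_random_pairs_fall_below_noise_floor():
    """Unrelated random proteins rarely clear the identity/length floor,
    and when they do the short local hit stays far from homolog-level
    identity (empirical distribution, frozen from 200 seeded pairs)."""
    rng = np.random.default_rng(0)
    floor = ScoreFloor()
    n_rejected = 0
    passing = []
    for _ in range(200):
        a = "".join(rng.choice(AA, 100))
        b = "".join(rng.choice(AA, 100))
        hit, cols = protein_similarity(a, b)
        if floor.passes(hit, cols):
            passing.append(hit.identity)
        else:
            n_rejected += 1
    assert n_rejected >= 170
    assert all(i < 0.55 for i in passing)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        protein_similarity("", "MKV")


# -- constructed score tables (injected scorer = adapter seam) --------------


def _table_scorer(table):
    def score(a, b):
        s = table.get((a.transcript_id, b.transcript_id))
        if s is None:
            return None
        return SimilarityHit(a.transcript_id, b.transcript_id, s, 1.0)
    return score


def test_best_hit_group_matches_brute_force_argmax():
    groups = [OrthologGroup(f"Y{i}", {"hs": [_tx("hs", f"g{i}", f"s{i}a")],
                                      "mm": [_tx("mm", f"g{i}", f"s{i}b")]})
              for i in range(3)]
    gene = [_tx("nm", "gx", "q1"), _tx("nm", "gx", "q2")]
    rng = np.random.default_rng(3)
    table = {(q.transcript_id, s.transcript_id): float(rng.integers(10, 100))
             for q in gene for g in groups for s in g.transcripts()}
    result = best_hit_group(gene, groups, scorer=_table_scorer(table))
    # oracle: exhaustive scan
    best = max(((v, g.group_id, s.transcript_id)
                for g in groups for s in g.transcripts()
                for q in gene
                for v in [table[(q.transcript_id, s.transcript_id)]]),
               key=lambda x: (x[0], [-ord(c) for c in x[1]]))
    assert result[0] == best[1]
    assert result[1].score == best[0]


def test_best_hit_group_none_when_below_floor():
    groups = [OrthologGroup("Y1", {"hs": [_tx("hs", "g", "s1")]})]
    assert best_hit_group([_tx("nm", "gx", "q")], groups,
                          scorer=lambda a, b: None) is None


def test_tie_break_lexicographic():
    groups = [OrthologGroup("Y2", {"hs": [_tx("hs", "g2", "sB")]}),
              OrthologGroup("Y1", {"hs": [_tx("hs", "g1", "sZ")]})]
    table = {("q", "sB"): 50.0, ("q", "sZ"): 50.0}
    gid, hit = best_hit_group([_tx("nm", "gx", "q")], groups,
                              scorer=_table_scorer(table))
    assert gid == "Y1"  # smallest (group_id, subject) on equal scores


class TestAssignSpecies:
    def _catalog(self):
        return [OrthologGroup("Y1", {"hs": [_tx("hs", "hg1", "h1")]}),
                OrthologGroup("Y2", {"hs": [_tx("hs", "hg2", "h2")]}),
                OrthologGroup("Y3", {"hs": [_tx("hs", "hg3", "h3")]})]

    def test_symmetric_best_hits_join(self):
        table = {("n1", "h1"): 90.0, ("h1", "n1"): 90.0,
                 ("n1", "h2"): 10.0, ("h2", "n1"): 10.0}
        cat, report = assign_species(
            self._catalog(), [_tx("nm", "gA", "n1")],
            scorer=_table_scorer(table))
        assert report["assigned"] == {"gA": "Y1"}
        assert any(t.transcript_id == "n1"
                   for t in cat[0].members.get("nm", []))

    def test_asymmetric_best_hit_unassigned(self):
        # X's best is Y1, but Y1's best new-species gene is gB, not gA
        table = {("n1", "h1"): 80.0, ("h1", "n1"): 80.0,
                 ("n2", "h1"): 10.0, ("h1", "n2"): 95.0}
        cat, report = assign_species(
            self._catalog(),
            [_tx("nm", "gA", "n1"), _tx("nm", "gB", "n2")],
            scorer=_table_scorer(table))
        assert ("gA", "not_bidirectional") in report["unassigned"]

    def test_matches_brute_force_bidirectional_criterion(self):
        rng = np.random.default_rng(7)
        catalog = self._catalog()
        new = [_tx("nm", f"g{i}", f"n{i}") for i in range(5)]
        table = {}
        for n in new:
            for g in catalog:
                for m in g.transcripts():
                    v = float(rng.integers(1, 1000))
                    table[(n.transcript_id, m.transcript_id)] = v
                    table[(m.transcript_id, n.transcript_id)] = v
        cat, report = assign_species(catalog, new,
                                     scorer=_table_scorer(table))
        # brute force over the full score table
        members = {g.group_id: [t for t in g.transcripts()] for g in catalog}
        for n in new:
            fwd = max(((table[(n.transcript_id, m.transcript_id)],
                        g.group_id)
                       for g in catalog for m in g.transcripts()))
            gid = fwd[1]
            back = max(((table[(m.transcript_id, x.transcript_id)],
                         x.gene_id)
                        for m in members[gid] for x in new))
            expected = gid if back[1] == n.gene_id else None
            got = report["assigned"].get(n.gene_id)
            assert got == expected

    def test_each_gene_joins_at_most_one_group_and_order_invariance(self):
        rng = np.random.default_rng(11)
        catalog = self._catalog()
        new = [_tx("nm", f"g{i}", f"n{i}") for i in range(4)]
        table = {}
        for n in new:
            for g in catalog:
                for m in g.transcripts():
                    v = float(rng.integers(1, 1000))
                    table[(n.transcript_id, m.transcript_id)] = v
                    table[(m.transcript_id, n.transcript_id)] = v
        cat1, rep1 = assign_species(catalog, new, scorer=_table_scorer(table))
        cat2, rep2 = assign_species(list(reversed(catalog)),
                                    list(reversed(new)),
                                    scorer=_table_scorer(table))
        assert rep1["assigned"] == rep2["assigned"]
        counts = {}
        for g in cat1:
            for t in g.members.get("nm", []):
                counts[t.gene_id] = counts.get(t.gene_id, 0) + 1
        assert all(v >= 1 for v in counts.values())
        assert len(rep1["assigned"]) == len(counts)

    def test_removing_non_best_transcript_never_changes_assignment(self):
        catalog = self._catalog()
        # add a second, worse member to Y1
        catalog[0].add(_tx("mm", "mg1", "m1"))
        table = {("n1", "h1"): 90.0, ("h1", "n1"): 90.0,
                 ("n1", "m1"): 20.0, ("m1", "n1"): 20.0}
        _, rep_full = assign_species(catalog, [_tx("nm", "gA", "n1")],
                                     scorer=_table_scorer(table))
        catalog2 = self._catalog()
        _, rep_red = assign_species(catalog2, [_tx("nm", "gA", "n1")],
                                    scorer=_table_scorer(table))
        assert rep_full["assigned"] == rep_red["assigned"]


def test_seed_catalog_de_novo_groups_homologs():
    rng = np.random.default_rng(5)
    base1 = "".join(rng.choice(AA, 80))
    base2 = "".join(rng.choice(AA, 80))

    def mutate(s, n):
        s = list(s)
        for i in rng.choice(len(s), n, replace=False):
            s[i] = str(rng.choice(AA))
        return "".join(s)

    txs = [_tx("hs", "geneA", "hA", base1), _tx("mm", "geneA", "mA", mutate(base1, 8)),
           _tx("hs", "geneB", "hB", base2), _tx("mm", "geneB", "mB", mutate(base2, 8))]
    groups = seed_catalog_de_novo(txs)
    families = sorted(tuple(sorted(t.gene_id for t in g.transcripts()))
                      for g in groups)
    assert families == [("geneA", "geneA"), ("geneB", "geneB")]
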