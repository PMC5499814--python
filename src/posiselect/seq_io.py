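"""Sequence, ortholog-group and alignment data model plus on-disk formats.

Coding sequences come in as FASTA (header convention
``species|gene_id|transcript_id``, configurable via a regex with named
captures) or GenBank flat files (CDS features, with ``Region`` features
mapped to protein-domain annotations).  Ortholog catalogs are plain TSV.
All parsing of the underlying formats is done with Biopython; this module
owns validation and the domain types.

Validation rules for a CDS:

* only A, C, G, T, N are allowed (other ambiguity codes reject the record);
* a trailing partial codon is trimmed, a trailing stop codon is stripped;
* an internal stop codon invalidates the transcript (unrecognized
  pseudogenes are a classic source of spurious positive-selection signal);
* codons containing N translate to X and are treated as missing data
  downstream.

Rejected records are always returned alongside the accepted ones with a
reason — never silently dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

import numpy as np
from Bio import SeqIO

from ._codons import STOP_CODONS, codons_of, encode_codon, translate_codon
from .trees import SpeciesTree

DEFAULT_HEADER_RE = re.compile(
    r"^(?P<species>[^|]+)\|(?P<gene_id>[^|]+)\|(?P<transcript_id>[^|]+)"
)

_VALID_NT = set("ACGTN")


@dataclass
class Transcript:
    """One coding isoform of a gene in one species."""

    transcript_id: str
    gene_id: str
    species: str
    cds: str
    protein: str = ""
    #: (start_codon, end_codon, label), 1-based inclusive codon coordinates
    domains: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.transcript_id)

    def __len__(self) -> int:
        return len(self.cds) // 3


@dataclass
class RejectedRecord:
    record_id: str
    reason: str
    line: Optional[int] = None


def validate_cds(cds: str) -> tuple[Optional[str], Optional[str]]:
    """Return (cleaned cds, None) or (None, reason)."""
    cds = cds.upper().replace("U", "T")
    bad = set(cds) - _VALID_NT
    if bad:
        return None, f"invalid nucleotide characters: {''.join(sorted(bad))}"
    cds = cds[: len(cds) - len(cds) % 3]  # trim trailing partial codon
    if not cds:
        return None, "empty CDS"
    codons = codons_of(cds)
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        return None, "CDS is a bare stop codon"
    if any(c in STOP_CODONS for c in codons):
        return None, "internal stop codon"
    return "".join(codons), None


def make_transcript(transcript_id, gene_id, species, cds, domains=()):
    """Validate a CDS and build a Transcript, or return the rejection reason."""
    clean, reason = validate_cds(cds)
    if clean is None:
        return None, reason
    protein = "".join(translate_codon(c) for c in codons_of(clean))
    return (
        Transcript(transcript_id, gene_id, species, clean, protein, list(domains)),
        None,
    )


def parse_transcripts(path, format="fasta", header_re=DEFAULT_HEADER_RE):
    """Read and validate coding sequences.

    Returns
    -------
    (transcripts, rejected)
        Accepted :class:`Transcript` records and :class:`RejectedRecord`
        entries; ``len(transcripts) + len(rejected)`` equals the number of
        input records.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format: {format}")
    if isinstance(header_re, str):
        header_re = re.compile(header_re)
    accepted: list[Transcript] = []
    rejected: list[RejectedRecord] = []
    seen: set[tuple[str, str]] = set()
    if format == "fasta":
        line_no = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if line.startswith(">"):
                    line_no[line[1:].strip().split()[0]] = i
        records = SeqIO.parse(path, "fasta")
    else:
        records = SeqIO.parse(path, "genbank")
        line_no = {}

    for rec in records:
        if format == "fasta":
            m = header_re.match(rec.description)
            if not m:
                rejected.append(RejectedRecord(
                    rec.id, "header does not match species|gene_id|transcript_id",
                    line_no.get(rec.id)))
                continue
            ids = m.groupdict()
            cds = str(rec.seq)
            domains = []
        else:
            ids, cds, domains, reason = _extract_genbank(rec)
            if ids is None:
                rejected.append(RejectedRecord(rec.id, reason))
                continue
        tx, reason = make_transcript(
            ids["transcript_id"], ids["gene_id"], ids["species"], cds, domains)
        if tx is None:
            rejected.append(RejectedRecord(rec.id, reason, line_no.get(rec.id)))
            continue
        if tx.key in seen:
            rejected.append(RejectedRecord(
                rec.id, f"duplicate (species, transcript_id) {tx.key}"))
            continue
        seen.add(tx.key)
        accepted.append(tx)
    return accepted, rejected


def _extract_genbank(rec):
    cds_feats = [f for f in rec.features if f.type == "CDS"]
    if not cds_feats:
        return None, None, None, "no CDS feature"
    feat = cds_feats[0]
    cds = str(feat.extract(rec.seq))
    organism = rec.annotations.get("organism", "")
    for f in rec.features:
        if f.type == "source" and "organism" in f.qualifiers:
            organism = f.qualifiers["organism"][0]
    if not organism:
        return None, None, None, "no organism annotation"
    species = organism.replace(" ", "_")
    gene = feat.qualifiers.get("gene", [rec.id])[0]
    ids = {"species": species, "gene_id": gene, "transcript_id": rec.id}
    cds_start = int(feat.location.start)
    domains = []
    for f in rec.features:
        if f.type != "Region":
            continue
        label = (f.qualifiers.get("region_name") or f.qualifiers.get("note")
                 or ["region"])[0]
        start_codon = (int(f.location.start) - cds_start) // 3 + 1
        end_codon = (int(f.location.end) - 1 - cds_start) // 3 + 1
        if end_codon >= 1:
            domains.append((max(1, start_codon), end_codon, label))
    return ids, cds, domains, None


# ---------------------------------------------------------------------------
# ortholog groups / catalog TSV


@dataclass
class OrthologGroup:
    """Cross-species homology set: species → member transcripts."""

    group_id: str
    members: dict[str, list[Transcript]] = field(default_factory=dict)

    @property
    def species(self) -> frozenset:
        return frozenset(self.members)

    def transcripts(self):
        for txs in self.members.values():
            yield from txs

    def add(self, tx: Transcript):
        self.members.setdefault(tx.species, []).append(tx)


def read_catalog(path, transcripts=None):
    """Read an ortholog catalog TSV (group_id, species, gene_id, transcript_id).

    If `transcripts` (mapping (species, transcript_id) → Transcript) is given,
    members are resolved against it; referenced-but-absent transcripts are
    omitted and counted in the report.  Without it, placeholder Transcripts
    carrying only identifiers are built (structure-only use).
    """
    groups: dict[str, OrthologGroup] = {}
    report = {"rows": 0, "duplicates": 0, "missing": [], "groups": 0}
    seen: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "group_id":
                continue
            if len(parts) < 4:
                raise ValueError(f"malformed catalog row: {line!r}")
            gid, species, gene_id, tid = parts[:4]
            report["rows"] += 1
            if (gid, species, tid) in seen:
                report["duplicates"] += 1
                continue
            seen.add((gid, species, tid))
            if transcripts is not None:
                tx = transcripts.get((species, tid))
                if tx is None:
                    report["missing"].append((gid, species, tid))
                    continue
            else:
                tx = Transcript(tid, gene_id, species, cds="")
            groups.setdefault(gid, OrthologGroup(gid)).add(tx)
    report["groups"] = len(groups)
    return list(groups.values()), report


def write_catalog(groups, path, comment: str = ""):
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("group_id\tspecies\tgene_id\ttranscript_id\n")
        for g in groups:
            for species in sorted(g.members):
                for tx in g.members[species]:
                    fh.write(f"{g.group_id}\t{species}\t{tx.gene_id}\t"
                             f"{tx.transcript_id}\n")


def transcript_index(transcripts) -> dict[tuple[str, str], Transcript]:
    return {tx.key: tx for tx in transcripts}


# ---------------------------------------------------------------------------
# trees


def parse_tree(path, species=None, foreground=None) -> SpeciesTree:
    """Read a Newick species tree (unrooted internally).

    If `species` is given, every leaf label must belong to it.
    """
    tree = SpeciesTree.read(path, foreground=foreground)
    if species is not None:
        extra = tree.leaves - frozenset(species)
        if extra:
            raise ValueError(f"tree leaf not in species set: {sorted(extra)}")
    return tree


# ---------------------------------------------------------------------------
# codon alignments


@dataclass
class CodonAlignment:
    """Aligned codon matrix: one gapped CDS row per species.

    Rows are nucleotide strings of equal length divisible by 3; gaps are
    codon-aligned (``---``).
    """

    species: list[str]
    rows: list[str]
    transcript_ids: Optional[list[str]] = None

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("unequal alignment row lengths")
        if self.rows and len(self.rows[0]) % 3:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    def codon(self, seq_index: int, col: int) -> str:
        return self.rows[seq_index][3 * col : 3 * col + 3]

    def to_state_matrix(self) -> np.ndarray:
        """(n_seqs, n_codons) codon-state matrix; -1 for gap/N codons."""
        mat = np.empty((self.n_seqs, self.n_codons), dtype=np.int16)
        for i, row in enumerate(self.rows):
            mat[i] = [encode_codon(row[3 * j : 3 * j + 3])
                      for j in range(self.n_codons)]
        return mat

    def subset_columns(self, keep: np.ndarray) -> "CodonAlignment":
        idx = np.flatnonzero(np.asarray(keep))
        rows = ["".join(r[3 * j : 3 * j + 3] for j in idx) for r in self.rows]
        return CodonAlignment(list(self.species), rows, self.transcript_ids)

    def anchor_codon_map(self, species: str) -> np.ndarray:
        """For each alignment codon column, the 1-based codon position in the
        ungapped sequence of `species` (0 where that row has a gap)."""
        row = self.row(species)
        out = np.zeros(self.n_codons, dtype=np.int32)
        pos = 0
        for j in range(self.n_codons):
            if row[3 * j : 3 * j + 3] != "---":
                pos += 1
                out[j] = pos
        return out

    def to_fasta(self) -> str:
        buf = StringIO()
        for sp, row in zip(self.species, self.rows):
            buf.write(f">{sp}\n{row}\n")
        return buf.getvalue()
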