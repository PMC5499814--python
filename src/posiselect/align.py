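"""Internal protein aligner: pairwise and progressive profile alignment.

A lightweight replacement for an external progressive aligner: sequences
are clustered by k-mer distance (UPGMA guide tree), then aligned
profile-to-profile with BLOSUM62 and affine gap costs so that more similar
sequences are aligned first.  Codon alignments are obtained by
back-threading each aligned residue onto its source codon.

An adapter seam (`aligner=` callables in the consuming modules) allows an
external aligner to be substituted; everything here is self-contained.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seq_io import CodonAlignment

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(_AA_ORDER)}
N_AA = len(_AA_ORDER)


def _blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    S = np.zeros((N_AA, N_AA))
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            S[i, j] = mat[a][b]
    return S


BLOSUM62 = _blosum62()


def _encode(seq: str) -> np.ndarray:
    # unknown residues (X etc.) get a neutral profile: uniform over amino acids
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def _profile(rows: list[str]) -> np.ndarray:
    """(n_cols, N_AA) amino-acid frequency profile; gaps contribute nothing."""
    n_cols = len(rows[0])
    prof = np.zeros((n_cols, N_AA))
    for row in rows:
        for j, c in enumerate(row):
            i = _AA_INDEX.get(c, -1)
            if i >= 0:
                prof[j, i] += 1.0
            elif c != "-":
                prof[j] += 1.0 / N_AA
    denom = len(rows)
    return prof / denom


@njit(cache=True)
def _gotoh(S, gap_open, gap_ext):  # pragma: no cover - numba
    m, n = S.shape
    NEG = -1e30
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # column of A against gap
    Y = np.full((m + 1, n + 1), NEG)  # gap against column of B
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_ext
    for j in range(1, n + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_ext
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_ext,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_ext,
                          X[i, j - 1] - gap_open)
            M[i, j] = S[i - 1, j - 1] + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                            Y[i - 1, j - 1])
    # traceback
    out_a = np.empty(m + n, dtype=np.int64)
    out_b = np.empty(m + n, dtype=np.int64)
    k = 0
    i, j = m, n
    if M[i, j] >= X[i, j] and M[i, j] >= Y[i, j]:
        state = 0
    elif X[i, j] >= Y[i, j]:
        state = 1
    else:
        state = 2
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a[k] = i - 1
            out_b[k] = j - 1
            k += 1
            prev = M[i, j] - S[i - 1, j - 1]
            if abs(prev - M[i - 1, j - 1]) < 1e-9:
                state = 0
            elif abs(prev - X[i - 1, j - 1]) < 1e-9:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1 and i > 0:
            out_a[k] = i - 1
            out_b[k] = -1
            k += 1
            cur = X[i, j]
            if abs(cur - (M[i - 1, j] - gap_open)) < 1e-9:
                state = 0
            elif abs(cur - (X[i - 1, j] - gap_ext)) < 1e-9:
                state = 1
            else:
                state = 2
            i -= 1
        elif state == 2 and j > 0:
            out_a[k] = -1
            out_b[k] = j - 1
            k += 1
            cur = Y[i, j]
            if abs(cur - (M[i, j - 1] - gap_open)) < 1e-9:
                state = 0
            elif abs(cur - (Y[i, j - 1] - gap_ext)) < 1e-9:
                state = 2
            else:
                state = 1
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2
    return out_a[:k][::-1].copy(), out_b[:k][::-1].copy()


def _align_profiles(rows_a: list[str], rows_b: list[str]):
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ BLOSUM62 @ pb.T
    # soften gap costs by the non-gap occupancy of each profile column
    ia, ib = _gotoh(S, GAP_OPEN, GAP_EXTEND)
    out_a = ["".join(r[i] if i >= 0 else "-" for i in ia) for r in rows_a]
    out_b = ["".join(r[j] if j >= 0 else "-" for j in ib) for r in rows_b]
    return out_a, out_b


def kmer_distances(seqs: list[str], k: int = 3) -> np.ndarray:
    """1 − fractional shared k-mer count, the guide-tree distance."""
    sets = []
    for s in seqs:
        sets.append({s[i:i + k] for i in range(max(0, len(s) - k + 1))})
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            denom = max(1, min(len(sets[i]), len(sets[j])))
            D[i, j] = D[j, i] = 1.0 - inter / denom
    return D


def shared_kmer_count(a: str, b: str, k: int = 5) -> int:
    sa = {a[i:i + k] for i in range(max(0, len(a) - k + 1))}
    sb = {b[i:i + k] for i in range(max(0, len(b) - k + 1))}
    return len(sa & sb)


def progressive_protein_msa(seqs: list[str]) -> list[str]:
    """Progressive multiple alignment of protein sequences (input order kept).

    More similar sequences (by k-mer distance, UPGMA guide tree) are merged
    first, which limits spurious alignment of non-homologous regions such as
    alternative exons.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if any(not s for s in seqs):
        raise ValueError("empty sequence")
    n = len(seqs)
    if n == 2:
        a, b = _align_profiles([seqs[0]], [seqs[1]])
        return [a[0], b[0]]
    D = kmer_distances(seqs)
    Z = linkage(squareform(D, checks=False), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        al_a, al_b = _align_profiles(rows_a, rows_b)
        clusters[n + step] = (idx_a + idx_b, al_a + al_b)
    (order, rows), = clusters.values()
    out = [None] * n
    for pos, row in zip(order, rows):
        out[pos] = row
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Identical residues / columns where both are non-gap (0 if none)."""
    both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)


def backthread_codons(protein_rows: list[str], cds_list: list[str],
                      species: list[str], transcript_ids=None) -> CodonAlignment:
    """Thread each aligned residue back onto its source codon."""
    rows = []
    for prot_row, cds in zip(protein_rows, cds_list):
        n_res = sum(1 for c in prot_row if c != "-")
        if n_res * 3 != len(cds):
            raise ValueError(
                f"protein row has {n_res} residues but CDS has "
                f"{len(cds) // 3} codons")
        out = []
        pos = 0
        for c in prot_row:
            if c == "-":
                out.append("---")
            else:
                out.append(cds[3 * pos: 3 * pos + 3])
                pos += 1
        rows.append("".join(out))
    return CodonAlignment(list(species), rows, transcript_ids)
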