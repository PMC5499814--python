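"""Gblocks-style removal of gapped and unreliable codon columns.

Column filtering operates on codon columns while conservation is judged on
the protein translation.  Each column is classified as *gap* (any sequence
has a gap or an N-containing codon), *conserved* (at least ``cons_frac`` of
the sequences share the majority amino acid) or *non-conserved*.  The mask
then

1. drops every gap column (``allow_gaps=False``, the stringent default),
2. drops non-conserved columns contiguous with a gap column,
3. drops runs of more than ``max_noncons_run`` contiguous non-conserved
   columns (isolated ambiguous columns inside otherwise conserved blocks
   are kept — removing every non-conserved column would preferentially
   delete the sites carrying substitutions on deep branches and bias both
   branch lengths and the selection test),
4. trims each retained block so it starts and ends with a conserved
   column, and
5. drops blocks shorter than ``min_block`` codons.

Filtering is idempotent, and tightening any parameter never retains more
columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._codons import translate_codon
from .seq_io import CodonAlignment

GAP, NONCONS, CONS = 0, 1, 2


@dataclass
class FilterParams:
    #: fraction of sequences that must share the majority amino acid;
    #: default one sequence above half, mirroring stringent Gblocks use
    cons_frac: Optional[float] = None
    min_block: int = 5
    max_noncons_run: int = 8
    allow_gaps: bool = False

    def resolved_cons_frac(self, n_seq: int) -> float:
        if self.cons_frac is not None:
            return self.cons_frac
        return 0.5 + 1.0 / n_seq


@dataclass
class ColumnMask:
    keep: np.ndarray
    params: FilterParams
    summary: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def blocks(self) -> list[tuple[int, int]]:
        """Kept blocks as 0-based half-open (start, stop) codon columns."""
        out = []
        start = None
        for i, k in enumerate(self.keep):
            if k and start is None:
                start = i
            elif not k and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(self.keep)))
        return out

    def to_intervals_tsv(self, anchor_map: Optional[np.ndarray] = None) -> str:
        """Kept intervals, 1-based inclusive, alignment coordinates; with an
        anchor codon map also in ungapped anchor coordinates."""
        lines = ["#start\tend" + ("\tanchor_start\tanchor_end" if anchor_map
                                  is not None else "")]
        for start, stop in self.blocks():
            row = f"{start + 1}\t{stop}"
            if anchor_map is not None:
                inside = anchor_map[start:stop]
                inside = inside[inside > 0]
                if len(inside):
                    row += f"\t{inside.min()}\t{inside.max()}"
                else:
                    row += "\t.\t."
            lines.append(row)
        return "\n".join(lines) + "\n"


def _classify(msa: CodonAlignment, params: FilterParams) -> np.ndarray:
    cons_frac = params.resolved_cons_frac(msa.n_seqs)
    status = np.empty(msa.n_codons, dtype=np.int8)
    for j in range(msa.n_codons):
        codons = [r[3 * j: 3 * j + 3] for r in msa.rows]
        has_gap = any("-" in c or "N" in c for c in codons)
        if has_gap and not params.allow_gaps:
            status[j] = GAP
            continue
        aas = [translate_codon(c) for c in codons if "-" not in c
               and "N" not in c]
        if not aas:
            status[j] = GAP
            continue
        majority = Counter(aas).most_common(1)[0][1]
        status[j] = CONS if majority / msa.n_seqs >= cons_frac else NONCONS
    return status


def filter_columns(msa: CodonAlignment, params: Optional[FilterParams] = None
                   ) -> ColumnMask:
    """Compute the kept-column mask for a codon alignment."""
    if params is None:
        params = FilterParams()
    if msa.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    status = _classify(msa, params)
    n = len(status)
    keep = status != GAP

    # non-conserved columns contiguous with a gap column
    for j in np.flatnonzero(status == GAP):
        k = j - 1
        while k >= 0 and status[k] == NONCONS:
            keep[k] = False
            k -= 1
        k = j + 1
        while k < n and status[k] == NONCONS:
            keep[k] = False
            k += 1

    # long non-conserved runs
    run_start = None
    for j in range(n + 1):
        inside = j < n and keep[j] and status[j] == NONCONS
        if inside and run_start is None:
            run_start = j
        elif not inside and run_start is not None:
            if j - run_start > params.max_noncons_run:
                keep[run_start:j] = False
            run_start = None

    # trim blocks to conserved ends, enforce minimum block length
    start = None
    for j in range(n + 1):
        inside = j < n and keep[j]
        if inside and start is None:
            start = j
        elif not inside and start is not None:
            lo, hi = start, j
            while lo < hi and status[lo] != CONS:
                lo += 1
            while hi > lo and status[hi - 1] != CONS:
                hi -= 1
            keep[start:lo] = False
            keep[hi:j] = False
            if hi - lo < params.min_block:
                keep[lo:hi] = False
            start = None

    return ColumnMask(keep, params, summary={
        "n_columns": n,
        "n_kept": int(keep.sum()),
        "n_gap_or_n": int((status == GAP).sum()),
        "n_unconserved": int((status == NONCONS).sum()),
    })
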