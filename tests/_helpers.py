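"""Independent oracles and small builders shared across test modules."""

import numpy as np

from posiselect._codons import CODON_AA, CODONS, N_STATES
from posiselect.seq_io import OrthologGroup, make_transcript


def hand_generator(kappa, omega, pi):
    """Independent GY94 construction: explicit loop over codon pairs."""
    purines = {"A", "G"}
    Q = np.zeros((N_STATES, N_STATES))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            rate = pi[j]
            if (a in purines) == (b in purines):
                rate *= kappa
            if CODON_AA[i] != CODON_AA[j]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def series_expm(Q, t, terms=60):
    """Taylor-series matrix exponential (independent oracle)."""
    P = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms):
        term = term @ (Q * t) / k
        P = P + term
    return P


def toy_groups(n_genes=3, seed=0):
    """Tiny catalog of diverged gene families over 4 species."""
    rng = np.random.default_rng(seed)
    groups = []
    for g in range(n_genes):
        core = list(rng.choice(CODONS, 60))
        group = OrthologGroup(f"G{g}")
        for sp in ("human", "chimp", "mouse", "dog"):
            codons = list(core)
            for i in rng.choice(60, 6, replace=False):
                codons[int(i)] = str(rng.choice(CODONS))
            tx, err = make_transcript(f"{sp}_t{g}", f"gene{g}", sp,
                                      "".join(codons))
            assert err is None, err
            group.add(tx)
        groups.append(group)
    return groups
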