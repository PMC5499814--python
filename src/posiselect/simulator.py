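"""Coding-sequence evolution along a tree under site-wise selection schemes.

The simulator evolves codon sequences by an exact Gillespie algorithm under
the GY94 model: every site carries an ω class drawn from a discrete
selection scheme, substitution events fire with the class- and
state-specific exit rates, and frame-preserving indels fire at a fixed
event-rate ratio relative to substitutions (default 1 indel per 43
substitutions) with geometrically distributed lengths in codons.

Selection schemes
-----------------
* Scheme **N** — a baseline discrete site-ω distribution with mean 0.21222
  and no mass above 1 (purifying/neutral only).  The default baseline is a
  synthetic stand-in for an empirical mammalian site-ω distribution: 20
  equiprobable atoms on a linear grid rescaled to the stated mean.
* Schemes **A–E** — the baseline mixed with a point mass of positively
  selected sites on the designated branch (fractions 1, 3, 5, 7, 9 % of
  codons), with the foreground ω solved so the overall mean sitewise ω is
  0.9 on that branch.

Branch lengths of the configured tree are multiplied by ``branch_scale``
(default 3) before simulation; the generator of each branch is normalised
so one unit of scaled branch length equals one expected substitution per
codon under that branch's scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._codons import CODONS, N_STATES
from .codon_model import _unscaled_generator
from .seq_io import CodonAlignment, Transcript
from .trees import SpeciesTree

__all__ = [
    "SelectionScheme", "IndelModel", "SimulationConfig", "SimulatedFamily",
    "build_scheme", "baseline_distribution", "sample_indel_length",
    "evolve", "default_species_tree", "default_pi", "run_validation",
]

BASELINE_MEAN = 0.21222
SCHEME_FRACTIONS = {"A": 0.01, "B": 0.03, "C": 0.05, "D": 0.07, "E": 0.09}


def baseline_distribution(n_atoms: int = 20, mean: float = BASELINE_MEAN):
    """Discrete purifying/neutral site-ω baseline: equiprobable atoms on a
    linear grid in (0.001, 1], rescaled to the requested mean."""
    atoms = np.linspace(0.001, 1.0, n_atoms)
    atoms = atoms * (mean / atoms.mean())
    probs = np.full(n_atoms, 1.0 / n_atoms)
    return atoms, probs


@dataclass(eq=False)
class SelectionScheme:
    """Discrete site-ω distribution, optionally with a positively selected
    component active on the designated (foreground) branch."""

    omega_values: np.ndarray
    probabilities: np.ndarray
    label: str = "custom"
    fg_fraction: float = 0.0
    fg_omega: Optional[float] = None

    def __post_init__(self):
        self.omega_values = np.asarray(self.omega_values, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        if (self.omega_values < 0).any():
            raise ValueError("omega values must be >= 0")
        if self.fg_fraction and (self.fg_omega is None or self.fg_omega < 1):
            raise ValueError("fg_omega must be >= 1 when fg_fraction > 0")

    @property
    def mean_omega(self) -> float:
        """Expected sitewise ω (on the designated branch, if any)."""
        base = float(self.probabilities @ self.omega_values)
        if self.fg_fraction:
            return (1 - self.fg_fraction) * base + self.fg_fraction * self.fg_omega
        return base


def build_scheme(label: str = "N", baseline=None, fg_fraction: Optional[float] = None,
                 target_mean: float = 0.9) -> SelectionScheme:
    """Construct scheme N or one of the positive-selection schemes A–E.

    For A–E the foreground ω solves the mixture-mean equation
    ``(1−f)·baseline_mean + f·ω₊ = target_mean``.
    """
    if baseline is None:
        baseline = baseline_distribution()
    atoms, probs = baseline
    if label == "N" or (fg_fraction is not None and fg_fraction == 0):
        return SelectionScheme(atoms, probs, label="N")
    if fg_fraction is None:
        try:
            fg_fraction = SCHEME_FRACTIONS[label]
        except KeyError:
            raise ValueError(f"unknown scheme label {label!r}") from None
    base_mean = float(np.dot(atoms, probs))
    fg_omega = (target_mean - (1 - fg_fraction) * base_mean) / fg_fraction
    if fg_omega < 1:
        raise ValueError(
            f"infeasible scheme: solved foreground omega {fg_omega:.4f} < 1")
    return SelectionScheme(atoms, probs, label=label,
                           fg_fraction=fg_fraction, fg_omega=fg_omega)


@dataclass
class IndelModel:
    """Geometric indel length model (codons) with an event-rate ratio."""

    q: float = 0.35
    subst_indel_ratio: float = 43.0
    ins_del_ratio: float = 1.0

    def __post_init__(self):
        if not 0 <= self.q < 1:
            raise ValueError("need 0 <= q < 1")
        if self.subst_indel_ratio <= 0 or self.ins_del_ratio <= 0:
            raise ValueError("ratios must be > 0")

    @property
    def mean_length(self) -> float:
        return 1.0 / (1.0 - self.q)

    @property
    def sd_length(self) -> float:
        return float(np.sqrt(self.q) / (1.0 - self.q))


def sample_indel_length(model: IndelModel, rng: np.random.Generator) -> int:
    """Geometric length in codons: P(L=k) = (1−q)·q^(k−1), k ≥ 1."""
    if model.q == 0:
        return 1
    return int(rng.geometric(1.0 - model.q))


def default_species_tree() -> SpeciesTree:
    """Nine mammals with the primate/rodent/laurasiatherian topology used for
    validation.  Branch lengths are plausible synthetic values on the
    per-nucleotide-site scale that tree estimation from coding alignments
    produces; the simulator's ``branch_scale`` (default 3) converts them to
    expected substitutions per codon."""
    newick = (
        "((((human:0.02,chimp:0.015):0.01,gorilla:0.02):0.015,"
        "macaque:0.04):0.03,"
        "(mouse:0.08,rat:0.08):0.10,"
        "((dog:0.05,cat:0.05):0.03,cattle:0.09):0.02);"
    )
    return SpeciesTree.from_newick(newick)


def default_pi() -> np.ndarray:
    """Synthetic F3x4 codon frequencies from typical mammalian coding-position
    nucleotide compositions (stand-in for a real gene's stationary
    frequencies; configurable)."""
    f = np.array([
        [0.27, 0.26, 0.31, 0.16],  # pos 1: A C G T
        [0.31, 0.23, 0.19, 0.27],  # pos 2
        [0.19, 0.32, 0.31, 0.18],  # pos 3
    ])
    nuc = {"A": 0, "C": 1, "G": 2, "T": 3}
    pi = np.array([f[0, nuc[c[0]]] * f[1, nuc[c[1]]] * f[2, nuc[c[2]]]
                   for c in CODONS])
    return pi / pi.sum()


@dataclass
class SimulationConfig:
    """Study conditions for one simulated gene family."""

    tree: SpeciesTree = field(default_factory=default_species_tree)
    kappa: float = 2.0
    pi: Optional[np.ndarray] = None
    root_length: int = 400
    branch_scale: float = 3.0
    indel: IndelModel = field(default_factory=IndelModel)
    #: scheme applied to every branch unless overridden
    background_scheme: SelectionScheme = None
    #: branch (terminal name or leaf set) → scheme
    scheme_per_branch: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pi is None:
            self.pi = default_pi()
        if self.background_scheme is None:
            self.background_scheme = build_scheme("N")
        if self.root_length <= 0 or self.branch_scale <= 0:
            raise ValueError("root_length and branch_scale must be > 0")


@dataclass
class SimulatedFamily:
    """Leaf sequences plus ground truth of one simulated gene family."""

    transcripts: list[Transcript]
    true_alignment: CodonAlignment
    #: per true-alignment column: True where the root/insertion draw put the
    #: site in the positively selected class of the branch scheme
    positive_site: np.ndarray
    #: substitution / insertion / deletion event counts per branch leafset
    event_counts: dict[frozenset, dict[str, int]]

    @property
    def n_substitutions(self) -> int:
        return sum(c["sub"] for c in self.event_counts.values())

    @property
    def n_indels(self) -> int:
        return sum(c["ins"] + c["del"] for c in self.event_counts.values())


class _SchemeRates:
    """Per-ω-class unscaled generators, exit rates and jump distributions."""

    def __init__(self, omegas, kappa, pi):
        self.omegas = np.asarray(omegas, dtype=float)
        self.exit = np.empty((len(omegas), N_STATES))
        self.jump = []
        for k, w in enumerate(self.omegas):
            Q = _unscaled_generator(kappa, w, pi)
            exit = -np.diag(Q).copy()
            P = Q.copy()
            np.fill_diagonal(P, 0.0)
            P /= np.where(exit > 0, exit, 1.0)[:, None]
            self.exit[k] = exit
            self.jump.append(P)


def evolve(config: SimulationConfig, rng) -> SimulatedFamily:
    """Simulate one gene family along the configured tree.

    Every site carries a token identity so the true multiple alignment
    (including indel history) is recovered exactly.  A site's baseline ω is
    drawn once (root or insertion); sites flagged positively selected use
    the scheme's foreground ω on the branch carrying that scheme and their
    baseline ω elsewhere.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tree = config.tree
    pi = config.pi
    kappa = config.kappa

    branch_scheme = {id(node): config.background_scheme
                     for node in tree.branches().values()}
    for spec, scheme in config.scheme_per_branch.items():
        key = frozenset([spec]) if isinstance(spec, str) else frozenset(spec)
        branches = tree.branches()
        node = branches.get(key) or branches.get(tree.leaves - key)
        if node is None:
            raise ValueError(f"no branch for scheme override {spec!r}")
        branch_scheme[id(node)] = scheme

    schemes = set(branch_scheme.values())
    base = config.background_scheme
    atoms = np.asarray(base.omega_values, dtype=float)
    base_probs = np.asarray(base.probabilities, dtype=float)
    for s in schemes:
        if not np.array_equal(np.asarray(s.omega_values), atoms):
            raise ValueError("all branch schemes must share the baseline atoms")
    fg_omegas = sorted({s.fg_omega for s in schemes if s.fg_fraction})
    all_omegas = np.concatenate([atoms, np.asarray(fg_omegas)])
    rates = _SchemeRates(all_omegas, kappa, pi)
    stat_exit = rates.exit @ pi
    fg_class = {w: len(atoms) + i for i, w in enumerate(fg_omegas)}

    info = {}
    for s in schemes:
        if s.fg_fraction:
            probs = np.concatenate([base_probs * (1 - s.fg_fraction),
                                    [s.fg_fraction]])
            exits = np.concatenate([stat_exit[: len(atoms)],
                                    [stat_exit[fg_class[s.fg_omega]]]])
            rho = float(np.dot(probs, exits))
            info[id(s)] = (s.fg_fraction, fg_class[s.fg_omega], rho)
        else:
            rho = float(np.dot(base_probs, stat_exit[: len(atoms)]))
            info[id(s)] = (0.0, None, rho)

    n0 = config.root_length
    # a site's positively-selected status is global: it uses the foreground
    # omega on the branch whose scheme carries it, baseline omega elsewhere
    f_global = max((s.fg_fraction for s in schemes), default=0.0)
    root_states = rng.choice(N_STATES, size=n0, p=pi)
    root_classes = rng.choice(len(atoms), size=n0, p=base_probs)
    root_positive = rng.random(n0) < f_global

    master: list[int] = list(range(n0))  # token order in the true alignment
    next_token = [n0]
    token_class: dict[int, int] = dict(enumerate(int(c) for c in root_classes))
    token_positive: dict[int, bool] = dict(enumerate(map(bool, root_positive)))
    event_counts: dict[frozenset, dict[str, int]] = {}
    leaf_seqs: dict[str, tuple[list[int], list[int]]] = {}

    def evolve_branch(tokens, states, node):
        scheme = branch_scheme[id(node)]
        f, pos_class, rho = info[id(scheme)]
        counts = {"sub": 0, "ins": 0, "del": 0}
        t_left = node.length * config.branch_scale
        tokens = list(tokens)
        base_cls = np.array([token_class[t] for t in tokens], dtype=int)
        positive = np.array([token_positive[t] for t in tokens], dtype=bool)
        cls = np.where(positive & (pos_class is not None),
                       pos_class if pos_class is not None else 0, base_cls)
        st = np.asarray(states, dtype=int)
        exit_rates = rates.exit[cls, st] / rho
        total_sub = float(exit_rates.sum())
        ratio = config.indel.subst_indel_ratio
        p_ins = config.indel.ins_del_ratio / (1 + config.indel.ins_del_ratio)
        while True:
            total_indel = total_sub / ratio if len(tokens) else 0.0
            total = total_sub + total_indel
            if total <= 0:
                break
            dt = rng.exponential(1.0 / total)
            if dt > t_left:
                break
            t_left -= dt
            if rng.random() < total_sub / total:
                i = int(rng.choice(len(tokens), p=exit_rates / total_sub))
                new_state = int(rng.choice(N_STATES, p=rates.jump[cls[i]][st[i]]))
                st[i] = new_state
                new_exit = rates.exit[cls[i], new_state] / rho
                total_sub += new_exit - exit_rates[i]
                exit_rates[i] = new_exit
                counts["sub"] += 1
            else:
                length = sample_indel_length(config.indel, rng)
                if rng.random() < p_ins:
                    pos = int(rng.integers(0, len(tokens) + 1))
                    new_states = rng.choice(N_STATES, size=length, p=pi)
                    new_base = rng.choice(len(atoms), size=length, p=base_probs)
                    new_pos = rng.random(length) < f_global
                    new_tokens = list(range(next_token[0], next_token[0] + length))
                    next_token[0] += length
                    for tok, c, z in zip(new_tokens, new_base, new_pos):
                        token_class[tok] = int(c)
                        token_positive[tok] = bool(z)
                    # place new tokens in the master order after the left
                    # neighbour (or at the front)
                    anchor = master.index(tokens[pos - 1]) + 1 if pos > 0 else 0
                    master[anchor:anchor] = new_tokens
                    tokens[pos:pos] = new_tokens
                    new_cls = np.where(new_pos & (pos_class is not None),
                                       pos_class if pos_class is not None else 0,
                                       new_base)
                    st = np.concatenate([st[:pos], new_states, st[pos:]])
                    cls = np.concatenate([cls[:pos], new_cls, cls[pos:]])
                    new_exit = rates.exit[new_cls, new_states] / rho
                    exit_rates = np.concatenate(
                        [exit_rates[:pos], new_exit, exit_rates[pos:]])
                    total_sub = float(exit_rates.sum())
                    counts["ins"] += 1
                elif len(tokens):
                    start = int(rng.integers(0, len(tokens)))
                    stop = min(start + length, len(tokens))
                    del tokens[start:stop]
                    st = np.delete(st, slice(start, stop))
                    cls = np.delete(cls, slice(start, stop))
                    exit_rates = np.delete(exit_rates, slice(start, stop))
                    total_sub = float(exit_rates.sum())
                    counts["del"] += 1
        event_counts[node.leaf_names()] = counts
        return tokens, [int(s) for s in st]

    def recurse(node, tokens, states):
        for child in node.children:
            ct, cs = evolve_branch(tokens, states, child)
            if child.is_leaf:
                leaf_seqs[child.name] = (ct, cs)
            else:
                recurse(child, ct, cs)

    recurse(tree.root, master[:n0], list(root_states))

    # build the true alignment over surviving master columns
    used = set()
    for toks, _ in leaf_seqs.values():
        used.update(toks)
    columns = [t for t in master if t in used]
    col_index = {t: i for i, t in enumerate(columns)}
    species = sorted(leaf_seqs)
    rows = []
    for sp in species:
        toks, sts = leaf_seqs[sp]
        row = ["---"] * len(columns)
        for tok, s in zip(toks, sts):
            row[col_index[tok]] = CODONS[s]
        rows.append("".join(row))
    true_aln = CodonAlignment(species, rows)
    positive = np.array([token_positive[t] for t in columns])

    transcripts = []
    for sp in species:
        toks, sts = leaf_seqs[sp]
        cds = "".join(CODONS[s] for s in sts)
        tx = Transcript(f"{sp}_t1", f"{sp}_g1", sp, cds,
                        protein="")
        transcripts.append(tx)
    return SimulatedFamily(transcripts, true_aln, positive, event_counts)


def run_validation(scenario: str = "N", branch="human", n_reps: int = 100,
                   seed: int = 0, root_length: int = 400,
                   tree: Optional[SpeciesTree] = None, alpha: float = 0.05,
                   config_kwargs: Optional[dict] = None,
                   progress: bool = False, save_dir=None):
    """Simulate gene families and run the full scan on the designated branch.

    Returns a summary dict with the detection fraction (nominal p ≤ alpha and
    all plausibility filters passed), a binomial CI, and per-replicate
    records.  With `save_dir`, each replicate's leaf sequences, true
    alignment and true-site annotations are written there as text files.
    """
    from .selection_pipeline import test_family  # deferred: avoids cycle

    if scenario not in ("N", "A", "B", "C", "D", "E"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if tree is None:
        tree = default_species_tree()
    fg = frozenset([branch]) if isinstance(branch, str) else frozenset(branch)
    scheme_per_branch = {}
    if scenario != "N":
        scheme_per_branch[fg] = build_scheme(scenario)
    config = SimulationConfig(tree=tree, root_length=root_length,
                              scheme_per_branch=scheme_per_branch,
                              **(config_kwargs or {}))
    rng = np.random.default_rng(seed)
    records = []
    detected = 0
    if save_dir is not None:
        from pathlib import Path
        save_dir = Path(save_dir)
        save_dir.mkdir(parents=True, exist_ok=True)
    for rep in range(n_reps):
        fam = evolve(config, rng)
        if save_dir is not None:
            _save_family(fam, save_dir, rep)
        res = test_family(fam.transcripts, tree, fg)
        is_psg = (res is not None and res.p_value <= alpha
                  and not res.filter_flags)
        detected += bool(is_psg)
        records.append({
            "rep": rep,
            "p": res.p_value if res is not None else np.nan,
            "fg_omega": res.foreground_omega if res is not None else np.nan,
            "flags": ",".join(sorted(res.filter_flags)) if res is not None
                     else "untestable",
            "psg": bool(is_psg),
        })
        if progress and (rep + 1) % 10 == 0:
            print(f"  replicate {rep + 1}/{n_reps}", flush=True)
    frac = detected / n_reps if n_reps else float("nan")
    if n_reps:
        se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / n_reps))
        ci = (max(0.0, frac - 1.96 * se), min(1.0, frac + 1.96 * se))
    else:
        ci = (float("nan"), float("nan"))
    return {"scenario": scenario, "branch": branch, "n": n_reps,
            "detected": detected, "fraction": frac, "ci95": ci,
            "records": records}


def _save_family(fam: SimulatedFamily, save_dir, rep: int):
    stem = save_dir / f"rep_{rep:04d}"
    with open(f"{stem}.fasta", "w") as fh:
        for tx in fam.transcripts:
            fh.write(f">{tx.species}|{tx.gene_id}|{tx.transcript_id}\n"
                     f"{tx.cds}\n")
    with open(f"{stem}.true_alignment.fasta", "w") as fh:
        fh.write(fam.true_alignment.to_fasta())
    with open(f"{stem}.true_sites.tsv", "w") as fh:
        fh.write("column\tpositively_selected\n")
        for i, flag in enumerate(fam.positive_site, 1):
            fh.write(f"{i}\t{int(flag)}\n")
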