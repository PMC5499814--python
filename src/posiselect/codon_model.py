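"""GY94-type codon substitution model and the branch-site test of positive selection.

The model follows Goldman–Yang: instantaneous rates between codons differing
at exactly one nucleotide are proportional to the target codon's stationary
frequency, multiplied by κ for transitions and by ω for nonsynonymous
changes.  The branch-site ("model A") mixture has four site classes —

====== ============ ============
class  background ω foreground ω
====== ============ ============
0      ω₀ ∈ (0,1]   ω₀
1      1            1
2a     ω₀           ω₂ ≥ 1
2b     1            ω₂
====== ============ ============

with proportions p0, p1, p2a = (1−p0−p1)·p0/(p0+p1),
p2b = (1−p0−p1)·p1/(p0+p1).  The null model fixes ω₂ = 1; the alternative
frees it.  Twice the log-likelihood difference is referred to χ² with one
degree of freedom.

Fitting strategy: branch lengths are taken from the species tree up to a
global scale factor.  A single-ω (M0) pre-fit per gene estimates κ, ω and
that scale; the null/alternative mixture fits then keep κ and the scale
fixed at the M0 estimates and optimise only the mixture parameters (with
``fix_scale=False`` the scale is re-estimated in each fit).  Likelihoods are
computed by Felsenstein pruning over unique site patterns, with gap/N codons
integrated over all 61 states.  Transition matrices come from the symmetric
eigendecomposition that time-reversibility affords.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.stats import chi2

from ._codons import (CODON_INDEX, N_STATES, PAIR_I, PAIR_J, PAIR_NONSYN,
                      PAIR_TRANSITION)
from .seq_io import CodonAlignment
from .trees import SpeciesTree

__all__ = [
    "CodonRateModel", "BranchSiteParams", "LRTResult",
    "BranchSiteModel", "BranchSiteResults",
    "build_generator", "transition_probs", "branch_site_loglik",
    "fit_model", "lrt", "uniform_pi", "f3x4_frequencies",
]

OMEGA0_BOUNDS = (1e-4, 1.0)
OMEGA2_BOUNDS = (1.0, 999.0)
_PEPS = 1e-6


def uniform_pi() -> np.ndarray:
    return np.full(N_STATES, 1.0 / N_STATES)


def f3x4_frequencies(alignment: CodonAlignment, floor: float = 1e-6) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies (F3x4)."""
    counts = np.zeros((3, 4))
    nuc_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for row in alignment.rows:
        for j in range(0, len(row), 3):
            codon = row[j:j + 3]
            if "-" in codon:
                continue
            for pos, nt in enumerate(codon):
                if nt in nuc_idx:
                    counts[pos, nuc_idx[nt]] += 1
    counts += 0.5  # pseudocount keeps frequencies strictly positive
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.empty(N_STATES)
    for codon, i in CODON_INDEX.items():
        pi[i] = (freqs[0, nuc_idx[codon[0]]] * freqs[1, nuc_idx[codon[1]]]
                 * freqs[2, nuc_idx[codon[2]]])
    pi = np.maximum(pi / pi.sum(), floor)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# generator and transition probabilities


@dataclass
class CodonRateModel:
    """Single-ω GY94 rate model."""

    kappa: float
    pi: np.ndarray
    omega: float

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0 or self.omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-8 \
                or len(self.pi) != N_STATES:
            raise ValueError("pi must be a distribution over the 61 sense codons")


def _unscaled_generator(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    Q = np.zeros((N_STATES, N_STATES))
    factor = np.where(PAIR_TRANSITION, kappa, 1.0) * np.where(PAIR_NONSYN, omega, 1.0)
    Q[PAIR_I, PAIR_J] = pi[PAIR_J] * factor
    Q[PAIR_J, PAIR_I] = pi[PAIR_I] * factor
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _rate_coefficients(pi: np.ndarray):
    """rate(ω, κ) = a + b·κ + ω·(c + d·κ), the flow −Σπᵢqᵢᵢ of the unscaled Q."""
    flow = 2.0 * pi[PAIR_I] * pi[PAIR_J]
    ts, ns = PAIR_TRANSITION, PAIR_NONSYN
    a = flow[~ts & ~ns].sum()
    b = flow[ts & ~ns].sum()
    c = flow[~ts & ns].sum()
    d = flow[ts & ns].sum()
    return a, b, c, d


def build_generator(model: CodonRateModel, normalize: bool = True) -> np.ndarray:
    """61×61 GY94 generator; if `normalize`, scaled to one expected
    substitution per codon per unit time at stationarity."""
    Q = _unscaled_generator(model.kappa, model.omega, model.pi)
    if normalize:
        rate = -(model.pi * np.diag(Q)).sum()
        Q = Q / rate
    return Q


def _stationary(Q: np.ndarray) -> np.ndarray:
    A = np.vstack([Q.T, np.ones(Q.shape[0])])
    b = np.zeros(Q.shape[0] + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.maximum(pi, 0) / np.maximum(pi, 0).sum()


class _Eig:
    """Symmetric eigendecomposition of a reversible generator: P(t) fast."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, U = eigh((B + B.T) / 2.0)
        self.w = w
        self.A = U / sq[:, None]
        self.Binv = U.T * sq[None, :]

    def P(self, t: float) -> np.ndarray:
        if t == 0.0:  # exact: impossible patterns must get likelihood 0
            return np.eye(len(self.w))
        P = (self.A * np.exp(self.w * t)) @ self.Binv
        np.clip(P, 0.0, None, out=P)
        return P


def transition_probs(generator: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the reversible eigendecomposition."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    pi = _stationary(generator)
    P = _Eig(generator, pi).P(t)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# parameters / results


@dataclass
class BranchSiteParams:
    """Mixture parameters of branch-site model A."""

    p0: float
    p1: float
    omega0: float
    omega2: float = 1.0

    def __post_init__(self):
        if not (0 < self.p0 < 1 and 0 < self.p1 < 1 and self.p0 + self.p1 <= 1):
            raise ValueError("need p0, p1 in (0,1) with p0 + p1 <= 1")
        if not (0 < self.omega0 <= 1):
            raise ValueError("omega0 must be in (0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")

    @property
    def p2a(self) -> float:
        return (1 - self.p0 - self.p1) * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        return (1 - self.p0 - self.p1) * self.p1 / (self.p0 + self.p1)

    def class_probs(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    def class_omegas(self) -> list[tuple[float, float]]:
        """(background ω, foreground ω) of classes 0, 1, 2a, 2b."""
        return [(self.omega0, self.omega0), (1.0, 1.0),
                (self.omega0, self.omega2), (1.0, self.omega2)]


@dataclass
class LRTResult:
    lnL0: float
    lnL1: float
    statistic: float
    p_value: float
    site_posteriors: Optional[np.ndarray] = None


def lrt(lnL0: float, lnL1: float, site_posteriors=None) -> LRTResult:
    """χ²₁ likelihood-ratio test; the statistic is clamped at zero."""
    stat = max(0.0, 2.0 * (lnL1 - lnL0))
    return LRTResult(lnL0, lnL1, stat, float(chi2.sf(stat, df=1)), site_posteriors)


# ---------------------------------------------------------------------------
# likelihood engine


class _LikelihoodEngine:
    """Pruning likelihood over unique site patterns of one gene."""

    def __init__(self, alignment: CodonAlignment, tree: SpeciesTree, pi: np.ndarray):
        self.pi = pi
        self.rate_coef = _rate_coefficients(pi)
        species = set(alignment.species)
        if species != tree.leaves:
            tree = tree.restricted(species)
        self.tree = tree
        mat = alignment.to_state_matrix()
        patterns, counts = np.unique(mat, axis=1, return_counts=True)
        self.counts = counts.astype(float)
        self.n_sites = mat.shape[1]
        self._site_to_pattern = None
        # map full columns to pattern index for per-site posteriors
        _, inverse = np.unique(mat, axis=1, return_inverse=True)
        self._site_to_pattern = inverse
        # flatten tree
        nodes = list(tree.root.postorder())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.nodes = nodes
        self.lengths = np.array([n.length for n in nodes])
        fg = tree.foreground
        fg_node = tree.branches().get(fg) if fg is not None else None
        self.is_fg = np.array([n is fg_node for n in nodes])
        self.leaf_states = {}
        sp_row = {s: i for i, s in enumerate(alignment.species)}
        for i, n in enumerate(nodes):
            if n.is_leaf:
                self.leaf_states[i] = patterns[sp_row[n.name]]
        self.n_pat = patterns.shape[1]
        self._eig_cache: dict[tuple, _Eig] = {}
        self._class_cache: dict[tuple, np.ndarray] = {}
        self._pstack_cache: dict[tuple, np.ndarray] = {}

    def _eig(self, kappa: float, omega: float) -> _Eig:
        key = (round(kappa, 12), round(omega, 12))
        if key not in self._eig_cache:
            Q = _unscaled_generator(kappa, omega, self.pi)
            self._eig_cache[key] = _Eig(Q, self.pi)
            if len(self._eig_cache) > 64:
                self._eig_cache.pop(next(iter(self._eig_cache)))
        return self._eig_cache[key]

    def _rate(self, kappa: float, omega: float) -> float:
        a, b, c, d = self.rate_coef
        return a + b * kappa + omega * (c + d * kappa)

    def class_site_logliks(self, kappa, tfac, class_omegas) -> np.ndarray:
        """(n_class, n_pat) log site likelihood per class.

        `tfac` converts the tree's branch lengths to units of the unscaled
        generator (the public surface divides the user-facing scale by the
        mixture-average rate before calling this).
        """
        out = np.empty((len(class_omegas), self.n_pat))
        missing = []
        for ci, (bg, fg) in enumerate(class_omegas):
            key = (round(kappa, 12), round(tfac, 14),
                   round(bg, 12), round(fg, 12))
            cached = self._class_cache.get(key)
            if cached is None:
                missing.append((ci, key, bg, fg))
            else:
                out[ci] = cached
        if missing:
            fresh = self._multi_class(kappa, tfac,
                                      [(bg, fg) for _, _, bg, fg in missing])
            if len(self._class_cache) > 64:
                self._class_cache.clear()
            for (ci, key, _, _), row in zip(missing, fresh):
                self._class_cache[key] = row
                out[ci] = row
        return out

    def _multi_class(self, kappa, tfac, pairs) -> np.ndarray:
        """Batched pruning over several (bg ω, fg ω) classes at once."""
        C = len(pairs)
        n_nodes = len(self.nodes)
        P = np.empty((C, n_nodes, N_STATES, N_STATES))
        fg_idx = np.flatnonzero(self.is_fg)
        for ci, (bg, fg) in enumerate(pairs):
            P[ci] = self._pstack(kappa, tfac, bg)
            if fg != bg and len(fg_idx):
                j = int(fg_idx[0])
                P[ci, j] = self._eig(kappa, fg).P(self.lengths[j] * tfac)
        partial: dict[int, np.ndarray] = {}
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                continue
            prod = None
            for child in node.children:
                j = self.index[id(child)]
                if child.is_leaf:
                    s = self.leaf_states[j]
                    contrib = P[:, j][:, :, np.where(s < 0, 0, s)]
                    contrib = contrib.transpose(0, 2, 1).copy()
                    contrib[:, s < 0, :] = 1.0
                else:
                    contrib = np.matmul(partial.pop(j),
                                        P[:, j].transpose(0, 2, 1))
                prod = contrib if prod is None else prod * contrib
            partial[i] = prod
        ri = self.index[id(self.tree.root)]
        site = partial[ri] @ self.pi
        if (site <= 0).any() or not np.isfinite(site).all():
            # rare underflow: fall back to the per-node-rescaled path
            return np.stack([self._one_class(kappa, tfac, bg, fg)
                             for bg, fg in pairs])
        return np.log(site)

    def _pstack(self, kappa, tfac, omega) -> np.ndarray:
        """(n_nodes, 61, 61) transition matrices for every branch at once."""
        key = (round(kappa, 12), round(tfac, 14), round(omega, 12))
        P = self._pstack_cache.get(key)
        if P is None:
            eig = self._eig(kappa, omega)
            t = self.lengths * tfac
            E = np.exp(np.outer(t, eig.w))
            P = np.matmul(eig.A[None, :, :] * E[:, None, :], eig.Binv[None])
            np.clip(P, 0.0, None, out=P)
            P[t == 0.0] = np.eye(N_STATES)
            if len(self._pstack_cache) > 24:
                self._pstack_cache.clear()
            self._pstack_cache[key] = P
        return P

    def _one_class(self, kappa, tfac, bg, fg) -> np.ndarray:
        P = self._pstack(kappa, tfac, bg)
        if fg != bg and self.is_fg.any():
            P = P.copy()
            j = int(np.flatnonzero(self.is_fg)[0])
            eig = self._eig(kappa, fg)
            P[j] = eig.P(self.lengths[j] * tfac)
        n_pat = self.n_pat
        partial = {}
        logscale = {}
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                continue
            prod = np.ones((n_pat, N_STATES))
            lsc = np.zeros(n_pat)
            for child in node.children:
                j = self.index[id(child)]
                if child.is_leaf:
                    s = self.leaf_states[j]
                    contrib = P[j][:, np.where(s < 0, 0, s)].T.copy()
                    contrib[s < 0] = 1.0
                else:
                    contrib = partial.pop(j) @ P[j].T
                    lsc += logscale.pop(j)
                prod *= contrib
            m = prod.max(axis=1)
            nz = m > 0
            prod[nz] /= m[nz, None]
            with np.errstate(divide="ignore"):
                lsc += np.log(m)
            partial[i] = prod
            logscale[i] = lsc
        ri = self.index[id(self.tree.root)]
        with np.errstate(divide="ignore"):
            return np.log(partial[ri] @ self.pi) + logscale[ri]

    def mixture_loglik(self, probs, class_logliks) -> float:
        probs = np.asarray(probs, dtype=float)
        mx = class_logliks.max(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            site = mx + np.log(np.tensordot(probs, np.exp(class_logliks - mx),
                                            axes=(0, 0)))
        site = np.where(np.isnan(site), -np.inf, site)
        return float((self.counts * site).sum())

    def mixture_rate(self, params: BranchSiteParams, kappa: float) -> float:
        """Mixture-average substitution flow of the unscaled generator."""
        return float(np.dot(params.class_probs(),
                            [self._rate(kappa, bg)
                             for bg, _ in params.class_omegas()]))

    def loglik(self, params: BranchSiteParams, kappa: float, scale: float) -> float:
        # public convention: `scale` is in expected substitutions per codon
        # per unit branch length, averaged over the site-class mixture
        rho = self.mixture_rate(params, kappa)
        return self.loglik_raw(params, kappa, scale / rho)

    def loglik_raw(self, params: BranchSiteParams, kappa: float,
                   tfac: float) -> float:
        probs = params.class_probs()
        cls = self.class_site_logliks(kappa, tfac, params.class_omegas())
        return self.mixture_loglik(probs, cls)

    def m0_loglik(self, kappa: float, omega: float, scale: float) -> float:
        rho = self._rate(kappa, omega)
        cls = self.class_site_logliks(kappa, scale / rho, [(omega, omega)])
        return self.mixture_loglik([1.0], cls)

    def mixture_loglik_lengths(self, kappa: float, omegas, probs,
                               lengths: np.ndarray) -> float:
        """Site-ω-mixture log-likelihood with explicit per-branch lengths
        (expected substitutions per codon under the mixture); bypasses the
        parameter caches."""
        omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
        probs = np.atleast_1d(np.asarray(probs, dtype=float))
        rho = float(np.dot(probs, [self._rate(kappa, w) for w in omegas]))
        t = np.asarray(lengths) / rho
        site = np.zeros(self.n_pat)
        for w, p in zip(omegas, probs):
            eig = self._eig(kappa, w)
            E = np.exp(np.outer(t, eig.w))
            P = np.matmul(eig.A[None, :, :] * E[:, None, :], eig.Binv[None])
            np.clip(P, 0.0, None, out=P)
            partial: dict[int, np.ndarray] = {}
            for i, node in enumerate(self.nodes):
                if node.is_leaf:
                    continue
                prod = None
                for child in node.children:
                    j = self.index[id(child)]
                    if child.is_leaf:
                        s = self.leaf_states[j]
                        contrib = P[j][:, np.where(s < 0, 0, s)].T.copy()
                        contrib[s < 0] = 1.0
                    else:
                        contrib = partial.pop(j) @ P[j].T
                    prod = contrib if prod is None else prod * contrib
                partial[i] = prod
            ri = self.index[id(self.tree.root)]
            site += p * (partial[ri] @ self.pi)
        with np.errstate(divide="ignore"):
            return float((self.counts * np.log(site)).sum())

    def m0_loglik_lengths(self, kappa: float, omega: float,
                          lengths: np.ndarray) -> float:
        """Single-ω special case of :meth:`mixture_loglik_lengths`."""
        return self.mixture_loglik_lengths(kappa, [omega], [1.0], lengths)

    def site_posteriors(self, params: BranchSiteParams, kappa, tfac) -> np.ndarray:
        """Per alignment column, posterior P(class 2a ∪ 2b | data, MLEs);
        `tfac` is on the raw generator time scale."""
        probs = params.class_probs()
        cls = self.class_site_logliks(kappa, tfac, params.class_omegas())
        with np.errstate(divide="ignore"):
            logw = np.log(probs)[:, None] + cls
        mx = logw.max(axis=0)
        w = np.exp(logw - mx)
        post = w / w.sum(axis=0)
        per_pattern = post[2] + post[3]
        return per_pattern[self._site_to_pattern]


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class BranchSiteResults:
    """Fitted branch-site test for one alignment/foreground branch."""

    lnL0: float
    lnL1: float
    statistic: float
    p_value: float
    kappa: float
    scale: float
    m0_omega: float
    params_null: Optional[BranchSiteParams]
    params_alt: Optional[BranchSiteParams]
    site_posteriors: np.ndarray
    converged: bool
    n_codons: int
    foreground: frozenset
    posterior_threshold: float = 0.95
    filter_flags: set = field(default_factory=set)

    @property
    def foreground_omega(self) -> float:
        return self.params_alt.omega2 if self.params_alt is not None else np.nan

    @property
    def selected_sites(self) -> np.ndarray:
        """0-based masked-alignment columns with posterior > threshold."""
        return np.flatnonzero(self.site_posteriors > self.posterior_threshold)

    def lrt(self) -> LRTResult:
        return LRTResult(self.lnL0, self.lnL1, self.statistic, self.p_value,
                         self.site_posteriors)

    def summary(self) -> str:
        lines = [
            "Branch-site test of positive selection",
            "=" * 54,
            f"foreground branch        {'+'.join(sorted(self.foreground))}",
            f"codon columns            {self.n_codons}",
            f"kappa (M0)               {self.kappa:.4f}",
            f"tree scale (M0)          {self.scale:.4f}",
            f"M0 omega                 {self.m0_omega:.4f}",
            f"lnL null / alternative   {self.lnL0:.4f} / {self.lnL1:.4f}",
            f"2*deltaLnL               {self.statistic:.4f}",
            f"p (chi2, 1 df)           {self.p_value:.4g}",
        ]
        if self.params_alt is not None:
            pa = self.params_alt
            lines += [
                f"foreground omega2        {pa.omega2:.4f}",
                f"p0/p1/p2a/p2b            {pa.p0:.3f}/{pa.p1:.3f}/"
                f"{pa.p2a:.3f}/{pa.p2b:.3f}",
                f"sites posterior > {self.posterior_threshold:.2f}  "
                f"{len(self.selected_sites)}",
            ]
        lines.append(f"converged                {self.converged}")
        return "\n".join(lines)


class BranchSiteModel:
    """Branch-site codon model for one codon alignment on a species tree.

    Parameters
    ----------
    alignment : CodonAlignment
        Masked codon alignment (gap/N codons are treated as missing data).
    tree : SpeciesTree
        Tree with branch lengths; restricted internally to the alignment's
        species.  Relative branch lengths are kept fixed; an overall scale
        is estimated.
    foreground : branch specification, optional
        Terminal species or leaf set; defaults to the tree's foreground.
    pi : "f3x4" | "uniform" | array
        Stationary codon frequencies.
    """

    def __init__(self, alignment: CodonAlignment, tree: SpeciesTree,
                 foreground=None, pi="f3x4"):
        if alignment.n_seqs < 2:
            raise ValueError("need at least 2 sequences")
        if isinstance(pi, str):
            pi = f3x4_frequencies(alignment) if pi == "f3x4" else uniform_pi()
        self.pi = np.asarray(pi, dtype=float)
        tree = tree.copy()
        species = set(alignment.species)
        if species != tree.leaves:
            tree = tree.restricted(species)
        if foreground is not None:
            tree.set_foreground(foreground)
        if tree.foreground is None:
            raise ValueError("a foreground branch is required")
        self.tree = tree
        self.alignment = alignment
        self.engine = _LikelihoodEngine(alignment, tree, self.pi)

    # -- raw likelihood (exposed for oracle tests) ---------------------

    def loglik(self, params: BranchSiteParams, kappa: float = 2.0,
               scale: float = 1.0) -> float:
        return self.engine.loglik(params, kappa, scale)

    def m0_loglik(self, kappa: float, omega: float, scale: float = 1.0) -> float:
        return self.engine.m0_loglik(kappa, omega, scale)

    # -- fitting -------------------------------------------------------

    def fit_m0(self, kappa0=2.0, omega0=0.4, scale0=1.0):
        eng = self.engine

        def nll(x):
            return -eng.m0_loglik(np.exp(x[0]), np.exp(x[1]), np.exp(x[2]))

        x0 = np.log([kappa0, omega0, scale0])
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(np.log(0.05), np.log(50)),
                               (np.log(1e-4), np.log(20)),
                               (np.log(1e-3), np.log(1e3))],
                       options={"maxiter": 60, "ftol": 1e-7})
        kappa, omega, scale = np.exp(res.x)
        return float(kappa), float(omega), float(scale), -float(res.fun)

    def _fit_mixture(self, kappa, scale, null, omega0_init, starts=3,
                     init=None):
        """Optimise (p0, p1, ω0[, ω2], tree scale) with κ fixed.

        Internally the scale parameter is the raw generator time factor; the
        optimiser therefore leaves cached per-class site likelihoods valid
        while it perturbs the mixture proportions.
        """
        eng = self.engine
        w0 = float(np.clip(omega0_init, 1e-3, 0.9))

        def unpack(x):
            p0 = min(max(x[0], _PEPS), 1 - 2 * _PEPS)
            p1 = min(max(x[1] * (1 - p0), _PEPS), 1 - p0 - _PEPS)
            omega0 = float(np.exp(x[2]))
            omega2 = 1.0 if null else float(np.exp(x[3]))
            tfac = float(np.exp(x[-1]))
            return BranchSiteParams(p0, p1, omega0, omega2), tfac

        def nll(x):
            params, tfac = unpack(x)
            return -eng.loglik_raw(params, kappa, tfac)

        bounds = [(_PEPS, 1 - 2 * _PEPS), (_PEPS, 1 - 2 * _PEPS),
                  (np.log(OMEGA0_BOUNDS[0]), np.log(OMEGA0_BOUNDS[1]))]
        if not null:
            bounds.append((np.log(OMEGA2_BOUNDS[0] + 1e-9),
                           np.log(OMEGA2_BOUNDS[1])))
        bounds.append((np.log(1e-4), np.log(1e4)))

        if null:
            base_starts = [(0.75, 0.8, w0), (0.45, 0.5, w0), (0.90, 0.3, 0.05)]
            x0s = [[d1, d2, np.log(o)] for d1, d2, o in base_starts]
        else:
            if init is not None:
                d1 = init.p0
                d2 = init.p1 / max(1 - init.p0, _PEPS)
                o = init.omega0
            else:
                d1, d2, o = 0.75, 0.8, w0
            x0s = [[d1, min(d2, 1 - 2 * _PEPS),
                    np.log(np.clip(o, *OMEGA0_BOUNDS)), np.log(w2)]
                   for w2 in (1.5, 8.0, 50.0)]
        for x0 in x0s:
            params0, _ = unpack(x0 + [0.0])
            x0.append(np.log(scale / eng.mixture_rate(params0, kappa)))

        # short deterministic multi-starts to pick a basin, then one polish
        best = None
        for x0 in x0s[:starts]:
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 12, "ftol": 1e-6})
            if best is None or res.fun < best.fun:
                best = res
        res = minimize(nll, best.x, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 40, "ftol": 1e-7})
        if res.fun > best.fun:  # polish must never lose ground
            res = best
        params, tfac = unpack(res.x)
        return params, tfac, -float(res.fun), bool(res.success)

    def fit(self, starts: int = 3) -> BranchSiteResults:
        """M0 pre-fit, then null and alternative branch-site fits and the LRT."""
        kappa, m0_omega, scale, _ = self.fit_m0()
        pn, tf0, lnL0, ok0 = self._fit_mixture(
            kappa, scale, null=True, omega0_init=m0_omega, starts=starts)
        pa, tf1, lnL1, ok1 = self._fit_mixture(
            kappa, scale, null=False, omega0_init=m0_omega, starts=starts,
            init=pn)
        if lnL1 < lnL0:
            # nesting safeguard: the null is a boundary point of the alternative
            pa = BranchSiteParams(pn.p0, pn.p1, pn.omega0, 1.0)
            tf1, lnL1 = tf0, lnL0
        test = lrt(lnL0, lnL1)
        post = self.engine.site_posteriors(pa, kappa, tf1)
        return BranchSiteResults(
            lnL0=lnL0, lnL1=lnL1, statistic=test.statistic,
            p_value=test.p_value, kappa=kappa, scale=scale, m0_omega=m0_omega,
            params_null=pn, params_alt=pa, site_posteriors=post,
            converged=ok0 and ok1, n_codons=self.alignment.n_codons,
            foreground=self.tree.foreground)


def estimate_branch_lengths(alignment: CodonAlignment, tree: SpeciesTree,
                            pi="f3x4", max_sites: int = 3000,
                            n_classes: int = 3) -> SpeciesTree:
    """ML branch lengths (expected substitutions per codon) keeping the
    given topology, under a discrete site-ω mixture.

    Across-site variation in ω matters here: an equal-rates fit compresses
    short internal branches because shared changes at fast sites are
    re-explained as parallel terminal changes.  A small free ω mixture
    (default 3 classes, M3-style) removes that bias.  The alignment is
    thinned to at most `max_sites` evenly spaced codon columns; initial
    lengths come from the input tree (e.g. the parsimony consensus).
    """
    if alignment.n_codons > max_sites:
        idx = np.linspace(0, alignment.n_codons - 1, max_sites).astype(int)
        keep = np.zeros(alignment.n_codons, dtype=bool)
        keep[idx] = True
        alignment = alignment.subset_columns(keep)
    if isinstance(pi, str):
        pi = f3x4_frequencies(alignment) if pi == "f3x4" else uniform_pi()
    work = tree.copy()
    if set(alignment.species) != work.leaves:
        work = work.restricted(set(alignment.species))
    engine = _LikelihoodEngine(alignment, work, np.asarray(pi, dtype=float))
    n_nodes = len(engine.nodes)
    free = [i for i, n in enumerate(engine.nodes) if n is not engine.tree.root]
    init = np.clip(engine.lengths[free], 1e-4, 10.0)
    K = max(1, n_classes)

    def unpack(x):
        kappa = np.exp(x[0])
        omegas = np.exp(x[1:1 + K])
        raw = np.concatenate([x[1 + K:K + K], [0.0]])  # K-1 free logits
        w = np.exp(raw - raw.max())
        probs = w / w.sum()
        lengths = np.zeros(n_nodes)
        lengths[free] = np.exp(x[2 * K:])
        return kappa, omegas, probs, lengths

    def nll(x):
        kappa, omegas, probs, lengths = unpack(x)
        return -engine.mixture_loglik_lengths(kappa, omegas, probs, lengths)

    om0 = np.geomspace(0.03, 0.8, K) if K > 1 else np.array([0.3])
    x0 = np.concatenate([[np.log(2.0)], np.log(om0), np.zeros(K - 1),
                         np.log(init)])
    bounds = ([(np.log(0.05), np.log(50))]
              + [(np.log(1e-4), np.log(20))] * K
              + [(-6.0, 6.0)] * (K - 1)
              + [(np.log(1e-5), np.log(10.0))] * len(free))
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 300, "ftol": 1e-8})
    _, _, _, lengths = unpack(res.x)
    for i in free:
        engine.nodes[i].length = float(lengths[i])
    return engine.tree


# ---------------------------------------------------------------------------
# functional surface


def branch_site_loglik(alignment: CodonAlignment, tree: SpeciesTree,
                       params: BranchSiteParams, kappa: float = 2.0,
                       pi="f3x4", scale: float = 1.0,
                       foreground=None) -> float:
    """Branch-site mixture log-likelihood at given parameter values."""
    model = BranchSiteModel(alignment, tree, foreground=foreground, pi=pi)
    return model.loglik(params, kappa=kappa, scale=scale)


def fit_model(alignment: CodonAlignment, tree: SpeciesTree, foreground=None,
              variant: str = "alternative", pi="f3x4", starts: int = 3):
    """Fit the branch-site model; `variant` in {"null", "alternative", "both"}.

    Returns a :class:`BranchSiteResults` carrying both fits and the LRT.
    """
    model = BranchSiteModel(alignment, tree, foreground=foreground, pi=pi)
    if variant not in ("null", "alternative", "both"):
        raise ValueError(f"unknown variant {variant!r}")
    return model.fit(starts=starts)


def site_posteriors(alignment: CodonAlignment, tree: SpeciesTree,
                    params: BranchSiteParams, kappa: float = 2.0,
                    scale: float = 1.0, pi="f3x4", foreground=None) -> np.ndarray:
    """Per-column posterior probability of the positively selected classes."""
    model = BranchSiteModel(alignment, tree, foreground=foreground, pi=pi)
    rho = model.engine.mixture_rate(params, kappa)
    return model.engine.site_posteriors(params, kappa, scale / rho)
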