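# Methods

`posiselect` scans protein-coding genes for positive selection on a chosen
branch of a species tree. This note describes the models and procedures the
package implements, the defaults it ships with and why, what the simulator
does and does not emulate, and the numerical choices that matter when
interpreting its output.

## The codon substitution model

Substitutions between sense codons follow a GY94-type Markov process. For
codons *i*, *j* differing at exactly one nucleotide position,

  q_ij = π_j · κ^[transition] · ω^[nonsynonymous],

with q_ij = 0 for multi-nucleotide changes and diagonal entries fixed by the
zero row-sum constraint. κ is the transition/transversion rate ratio, ω the
nonsynonymous/synonymous rate ratio, and π the stationary codon frequencies
(F3x4 estimated from the alignment by default; uniform or user-supplied
alternatives). The generator is rescaled so one unit of branch length equals
one expected substitution per codon at stationarity, averaged over the site
classes in mixture models; the rescaling factor is shared across classes so
site classes differ in rate as well as in ω, as they should. Because the
process is time-reversible, transition matrices come from a symmetric
eigendecomposition and the likelihood is independent of root placement;
trees are handled unrooted throughout.

## The branch-site test

The branch-site ("model A") mixture assigns every codon column to one of
four latent classes:

| class | proportion | background ω | foreground ω |
|-------|------------|--------------|--------------|
| 0     | p0         | ω0 ∈ (0,1]   | ω0           |
| 1     | p1         | 1            | 1            |
| 2a    | (1−p0−p1)·p0/(p0+p1) | ω0 | ω2 ≥ 1     |
| 2b    | (1−p0−p1)·p1/(p0+p1) | 1  | ω2          |

The null model fixes ω2 = 1, the alternative frees it; twice the
log-likelihood difference is referred to χ² with one degree of freedom. The
pure χ²₁ reference (rather than the 50:50 boundary mixture) is deliberately
conservative for the null hypothesis on the boundary and is used for all
reported p-values. Likelihoods are computed by Felsenstein pruning over
unique site patterns; codons containing gaps or N integrate over all 61
states (missing data).

Fitting proceeds in three stages per gene. A single-ω (M0) pre-fit
estimates κ, ω and a global scale for the relative branch lengths of the
species tree. The null and alternative mixture fits then hold κ at the M0
estimate and optimise (p0, p1, ω0[, ω2]) together with the tree scale by
bounded L-BFGS-B; ω0 is optimised on [1e−4, 1] and ω2 on [1, 999], both on
the log scale. Each mixture fit uses three deterministic starts (for the
alternative: ω2 started at 1.5, 8 and 50 from the null solution) explored
briefly, with the best basin polished to convergence. Fixing κ after M0
trades a negligible likelihood loss for a large speedup on genome-scale
scans; because the null is a boundary point of the alternative, the fitted
alternative is floored at the null likelihood, so the LRT statistic is
never negative. Internally the mixture fits parameterise time in raw
generator units, which keeps cached per-class site likelihoods valid while
the optimiser perturbs only the mixture proportions — an exact
reparameterisation, not an approximation.

Sites are localised with naive empirical Bayes: at the alternative-model
MLEs, the posterior probability that a column belongs to class 2a ∪ 2b is
reported, and columns above 0.95 are flagged. A full Bayes empirical Bayes
treatment (integrating over parameter uncertainty) is a possible extension;
NEB point estimates are known to be anticonservative when data are weak,
which the plausibility filters partly absorb.

## Alignment and filtering

Isoform handling follows an anchor-species design: all isoforms of an
ortholog group are aligned once at the protein level (progressive profile
alignment, BLOSUM62, affine gaps 11/1, UPGMA guide tree on k-mer
distances), and for each anchor isoform the most similar isoform of every
other species is selected. Similarity is the fraction of identical residues
over columns where both sequences are non-gap, which does not penalise
alternative exons. Divergent sequences are removed in two stages: below an
anchor-similarity threshold (θ_anchor, default 0.5) outright; then,
iteratively, the sequence violating the pairwise threshold (θ_pair, default
0.5) against the most other sequences, ties broken by the lowest anchor
similarity, recounting after each removal. The thresholds are fractions of
identical residues; 0.5 is permissive enough to keep genuinely fast-evolving
orthologs while discarding misassigned fragments.

Codon alignments are built by threading each aligned residue back onto its
source codon, so gaps are always frame-preserving. Column filtering is
Gblocks-like and operates on codon columns with conservation judged on the
translation: gap columns (and non-conserved columns contiguous with them)
are removed, runs of more than 8 consecutive non-conserved columns are
removed, blocks are trimmed to conserved end columns and must span at least
5 codons. Isolated ambiguous columns *inside* conserved blocks are kept on
purpose: removing every non-conserved column would preferentially delete
the sites that carry substitutions on deep branches (a single change on the
stem of a 4-species clade in a 9-species alignment leaves only a 5/9
majority) and measurably biases both branch-length estimates and
internal-branch tests.

## Species-tree inference

Isoform assignments that retain all requested species are concatenated,
cut into 20 equal chunks, and column-filtered. Each chunk yields an
unrooted parsimony tree: Fitch score on 61-state codon columns, exhaustive
search up to 6 taxa, otherwise first-improvement NNI from a
neighbour-joining start. Chunk trees are summarised by strict-majority
consensus (splits in more than half of the chunk trees; exactly 50% is
excluded). Chunk branch lengths are expected changes per site under a
uniform sample of most-parsimonious reconstructions (unit-cost Sankoff DP
with solution counting, three samples), corrected for unseen multiple hits
by the many-state Poisson inversion −log(1−c), and consensus lengths
average over the chunk trees containing each split (terminal branches over
all chunks). Because parsimony still undercounts on long branches and an
equal-rates model compresses short internal branches when sites vary in
rate, the consensus lengths are refined by maximum likelihood under a free
three-class discrete-ω mixture (M3-style) on the filtered superalignment,
thinned to at most 3,000 evenly spaced codon columns. On data simulated
along the default tree at 10,000 codons this recovers every branch length
within 10%.

## Plausibility filters and multiple testing

A fitted gene is flagged (and never counted as a positively selected gene)
when: fewer than 50 codon columns or less than 20% of the anchor's codons
survive filtering; fewer than 3 sequences remain; the fitted foreground ω
is ≥ 100 (disproportionate rates indicate alignment artefacts rather than
selection); the estimated p2a+p2b exceeds 0.8 or more than 60% of sites
have posterior > 0.5 (implausibly pervasive selection); the optimiser did
not converge; or no species from the sister clade of the tested branch is
present in the alignment, in which case selection cannot be localised to
the tested branch and the gene is not fitted at all. Of these cutoffs only
the ω ≥ 100 rule has an established reference value; the others are
package defaults, all configurable. Nominal p-values are accompanied by
Bonferroni and Benjamini–Hochberg adjusted values computed across all
tested genes; a PSG is defined by nominal p ≤ 0.05 with no flags.

## The simulator and the validation experiments

The simulator evolves codon sequences along a tree by an exact Gillespie
algorithm under the same GY94 process the test assumes, plus
frame-preserving indels. Site-wise selective pressure follows a discrete
scheme:

* **Scheme N** (no positive selection): a baseline distribution with mean
  ω 0.21222 and no mass above 1 — 20 equiprobable atoms on a linear grid
  rescaled to that mean. The baseline stands in for an empirical mammalian
  site-ω distribution; any discrete distribution can be supplied instead.
* **Schemes A–E**: the baseline mixed with a point mass of positively
  selected sites on the tested branch at fractions 1, 3, 5, 7 and 9% of
  codons, with the foreground ω solved from
  (1−f)·0.21222 + f·ω₊ = 0.9, i.e. constant overall mean
  sitewise ω of 0.9 (moderate purifying selection overall); for scheme A
  this gives ω₊ = 68.99022. A positively selected site uses ω₊ on the
  designated branch and its baseline ω elsewhere.

Indel events fire at 1/43 of the current total substitution rate, are
insertions or deletions with equal odds, and draw lengths (in codons) from
a geometric distribution with q = 0.35 (mean 1.54, SD 0.91 codons).
Insertion content is drawn from π. κ is fixed at 2. The root sequence
(default 400 codons; the desk-scale experiments use 200) is drawn from π.
Branch lengths of the configured tree are multiplied by 3 before
simulation, reflecting the convention difference between per-nucleotide
tree estimates and per-codon simulation time; each branch's generator is
normalised to one expected substitution per codon per unit scaled length
under that branch's scheme. Site tokens carry identity through indels, so
the true multiple alignment and the true per-site selection status are
returned exactly.

The default 9-taxon tree uses the primate/rodent/laurasiatherian topology
(((((human, chimp), gorilla), macaque), (mouse, rat), ((dog, cat),
cattle))) with synthetic branch lengths on the per-site scale of a
moderately evolving globin-like gene (tree length 0.60 before the ×3
convention). The lengths are plausible values, not estimates from data, and
are configurable; detection rates in the validation experiments scale with
the length of the tested branch, so they should be read relative to this
tree.

`run_validation` ties everything together: simulate families, align the
leaf sequences from scratch (the true alignment is *not* used), filter
columns, check the sister taxon, run the branch-site test, apply the
filters, and report the detected fraction with a binomial CI. At desk
scale (200 families × 200 codons, one CPU) the no-selection false positive
rate is well below the 5% nominal level — the combination of the
conservative χ²₁ reference and the filtering suppresses the false signals
that alignment noise would otherwise create — and detection across schemes
A–E decreases as the selection signal is diluted over more sites.

What the simulator does **not** emulate: paralogy and gene duplication,
assembly or annotation errors, pseudogenes, splice-isoform variation
(every simulated gene has one transcript per species), codon-usage or GC
heterogeneity across lineages, and rate variation beyond the discrete-ω
site classes. Passing validation therefore demonstrates correctness of the
statistical machinery and robustness to indel-induced alignment error, not
robustness to every failure mode of real genome-wide data.

## Numerical choices and degenerate inputs

Transition matrices are clipped at 0 and renormalised only in the public
`transition_probs`; branch lengths of exactly 0 map to exact identity
matrices so impossible patterns get likelihood 0, and a zero-length tree
with conflicting sequences reports lnL = −∞. Pruning runs over unique site
patterns without per-node rescaling (double precision is ample for tens of
taxa), falling back to a rescaled path if a site likelihood underflows.
Optimiser tolerances (ftol 1e−7) give log-likelihoods accurate to well
below the 0.01 LRT units that would matter at the p = 0.05 boundary.
Tie-breaks are deterministic everywhere (lexicographic on identifiers;
fixed multi-start order), scans are invariant to thread count, and all
randomness flows from a single integer seed.

## Known limitations

* The branch-site fits fix κ after the M0 pre-fit and keep relative branch
  lengths from the species tree (one free scale); genes with strongly
  gene-specific κ or topology-scale deviations inherit that approximation.
* NEB site identification uses point estimates of the mixture parameters.
* The internal progressive aligner is a generic profile aligner; a
  phylogeny-aware aligner places insertions more accurately on real data,
  and the adapter seam (`aligner=` callables / external tool wrappers)
  exists precisely so one can be substituted.
* Strict-majority consensus can return multifurcating trees when chunks
  disagree; downstream code accepts them, but branch-site power on poorly
  resolved trees is reduced.
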