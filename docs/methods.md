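# Methods

## Model

A binary phylogenetic network is a rooted directed acyclic graph: the root
has out-degree 2, leaves (labelled bijectively by taxa) in-degree 1, internal
tree nodes in-degree 1 / out-degree 2, and reticulation nodes in-degree 2 /
out-degree 1. Branch lengths are expected substitutions per site. Each
reticulation edge carries an inheritance probability γ, the probability that
a gene is inherited through that parent; the two γ's entering a reticulation
node sum to one. Only acyclicity is enforced — time-consistency of
reticulation edges (the requirement that donor and recipient be
contemporaneous) is not, since nothing in the likelihood needs it.

Displayed trees are obtained by keeping one incoming edge per reticulation
node, deleting subtrees left without leaves, and suppressing degree-two nodes
while **summing** the lengths of merged edges (so root-to-leaf path lengths
are preserved — this is what makes the base displayed tree of an augmented
network score identically to the unaugmented network). `P(T | N, γ)` sums the
γ-products over all induction choices whose displayed trees share an unrooted
topology; a displayed topology class is represented by the tree from the
first induction choice in deterministic order.

The gene likelihood `P(S_i | T)` is Felsenstein pruning under K80 with
uniform root frequencies. The model is normalized to one expected
substitution per unit branch length; the default transition/transversion
*ratio* 2 corresponds to κ = α/β = 4. Ambiguous or non-ACGT characters are
treated as missing data (all-ones partials). The network likelihood
`L(N, γ | S)` mixes per-gene tree likelihoods with the displayed-tree
probabilities via log-sum-exp. Inside the mixture, components are
deduplicated by exact (topology, branch lengths) — two induction choices that
yield the same topology but different induced lengths keep separate
`P(S_i | T)` terms, so the likelihood equals a literal enumeration over
induction sets (the form our oracle tests verify).

## Branch lengths: induced, not re-estimated

Candidate displayed trees are scored at the branch lengths induced by the
network (subdivision midpoints, reticulation edges of length 0 by default —
an instantaneous transfer). A per-gene maximum-likelihood branch-length mode
(Brent sweeps per branch, relative tolerance 1e-4, at most 5 sweeps) is
available via `optimize_branches=True` on `tree_log_likelihood` and
`network_log_likelihood`, but the search pipeline does not use it: scoring
every candidate topology for every gene with per-gene branch re-optimization
costs roughly three orders of magnitude more, and — measured on
reticulation-free data — re-scoring only the chosen networks with optimized
lengths while ranking with induced lengths produces incoherent (negative)
improvement sequences, so we do not mix the two.

Consequences worth knowing:

* On data simulated from a known network, induced lengths are the true
  lengths, so placement and γ estimation are well calibrated.
* On reticulation-free data the best augmentation's improvement is a maximum
  of near-zero-mean statistics; it is usually positive but can be slightly
  negative at late search steps (the γ grid starts at 0.05, so the null model
  is not nested in every candidate). With per-gene branch re-optimization the
  improvement is positive essentially always; that behavior belongs to the
  optimizing mode only.

## Search and model selection

Forward selection: the optimal network with h+1 reticulations is the best
single-edge augmentation of the optimal network with h. Candidates are all
ordered pairs of existing edges (donor, recipient), both subdivided at their
midpoints; pairs sharing a tail node ("sibling edges") and pairs whose new
edge would close a directed cycle are excluded. Candidate order is
deterministic (edges sorted by the leaf set below their head); ties in the
likelihood break toward the earlier candidate and the smaller γ. The γ of the
new edge is grid-searched over {0.05, …, 0.50} with existing γ's held fixed;
candidate evaluations are independent, so any evaluation order gives
identical results. Per-gene tree log-likelihoods are cached by the displayed
tree's canonical Newick (topology + lengths), which is what makes the search
tractable: candidates overwhelmingly share displayed trees.

Model selection uses the likelihood-improvement form of AIC/BIC with one
parameter per reticulation: accept the i-th edge iff
`ln L(i) − ln L(i−1) > 1` (AIC) or `> ln(n)/2` (BIC), n = total sites.
Reported AIC/BIC *values* use K = number of branches of the network; the
selection rule is deliberately the per-reticulation threshold form (the two
differ because a subdivision adds three graph edges — the threshold form is
what defines the published decision rule). Default selection is sequential
stopping at the first failed threshold; a `global` mode returning the
criterion-minimizing h over the whole trajectory is provided for when the
improvement sequence is non-monotone.

## Simulator: what it emulates

The generator reproduces the classic HGT-detection study design: a species
tree, a single planted transfer, k genes split deterministically between the
two histories (`round(γ·k)` genes on the transferred tree — the grid values
make γ·k integral; the last `round(γ·k)` gene indices are the transferred
ones), and 100 sites per gene under K80 (ti/tv = 2), root sequence drawn from
the stationary uniform distribution. All randomness flows from
`numpy.random.SeedSequence` spawns of a single seed, so every artifact is
bit-reproducible.

Study geometry (chosen once, since the source studies do not print their
branch lengths):

* **Placement / γ-recovery / model-selection studies**: 10-taxon caterpillar,
  pendant and internal branches 0.25. Donor = midpoint of taxon 3's pendant
  edge; recipients at taxa 4, 6, 8 give reticulation *diameters* (tree-path
  length between attachment midpoints) of exactly 0.5, 1.0, 1.5, all with the
  same height 0.25 and the same donor.
* **Diameter/height-effect studies**: 16-taxon caterpillar, pendant 0.05,
  internal 0.1: transfers from taxon 1 to taxa 3..8 give the diameter series
  0.15, 0.25, …, 0.65.
* A seeded birth-death mode (via dendropy) is available for non-caterpillar
  shapes; the caterpillar is the default study condition.

What the simulator does **not** emulate: rate variation across sites, indels,
model misspecification, deep coalescence, recombination within genes, or
unsampled donors. Passing tests therefore show that the estimator recovers
planted transfers *under its own model*, not that real data are this kind.

## Replication and problem sizes

Replicated studies default to 20 seeded replicates per condition (the
original design used 50); genome sizes 10–80 genes of 100 sites. At these
sizes the full acceptance run (three placement conditions plus the
model-selection study searched to four reticulations at genome sizes 10 and
80) completes in about six minutes on one CPU.

## Numerical choices

* Pruning is vectorized over the pooled unique site patterns of all genes;
  per-pattern rescaling happens only when a partial drops below 1e-150.
* Mixtures accumulate as log-sum-exp; zero-probability components are
  dropped (an all-zero mixture raises).
* Degenerate inference: a single-reticulation network whose two displayed
  trees share an unrooted topology displays only one distinct tree; placement
  results then compare against the base tree and set a `degenerate` flag.
* Reticulation geometry on multi-reticulation networks removes only the
  queried edge and takes the shortest undirected weighted path between its
  endpoints (equal to the unique tree path whenever the remainder is a
  subdivided tree); heights are longest directed root-free paths to leaves.
* eNewick canonical form orders children and chooses the primary parent of
  each reticulation node by name-free structural signatures, so
  `write(parse(x))` is bit-identical on canonical input even though internal
  node names are not serialized.

## Known limitations

* K80 only (no GTR, no gamma rate heterogeneity, no amino-acid models); one
  substitution model across genes.
* The search adds edges only (no removal or rewiring), so it can be trapped
  by a bad early choice, as any forward selection can.
* Networks are binary with reticulation out-degree 1; no time-consistency
  check.
* With the γ grid capped at 0.5, a transfer affecting more than half the
  genes is reported from the other side (the base/transferred roles swap).
* BIC selection on reticulation-free data sits close to its threshold at
  n = 1000 (k = 10 genes): the best spurious improvement occasionally exceeds
  ln(n)/2, so isolated false positives can occur at small genome sizes.
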