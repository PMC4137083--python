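# Methods

`ccci` implements the computational core of a network view of the cilium and
centrosome: integrate heterogeneous pairwise evidence into a high-confidence
gene–gene interaction network, decompose it into dense communities, test
those communities for functional, localization and regulatory signals, and
summarise how communities interconnect.  Every stage runs on synthetic data
with planted structure, so the whole pipeline is testable without any
external database.

## Evidence combination

Each gene pair carries scores in [0, 1] from independent evidence channels
(genomic context, high-throughput experiments, co-expression, prior
knowledge).  Channels are combined with the probabilistic noisy-OR used by
functional-association databases, after removing a shared prior *p*:

    s'_i = max(0, (s_i − p) / (1 − p))
    c'   = 1 − ∏_i (1 − s'_i)
    c    = c'·(1 − p) + p        (0 when no channel exceeds the prior)

Channels can be excluded by name before combination (the canonical use is
dropping a text-mining channel).  The default prior is 0.041 and is exposed
as configuration — it is a convention of the source database family, not a
fitted quantity.  Properties relied on downstream and enforced by tests:
monotonicity in every channel, permutation invariance, and the fact that
excluding a channel can never raise the combined score.

The interactome keeps pairs with combined score ≥ 0.7 (inclusive — a pair
at exactly the cutoff is kept) whose endpoints both belong to the supplied
gene universe.  Genes left with degree 0 are reported as removed
singletons.  Connected components are labelled deterministically (largest
first, ties by smallest member id).  The degree distribution is summarised
by an ordinary least-squares fit of log₁₀ frequency on log₁₀ degree — the
convention of interactive network-analysis tools, chosen deliberately over
a maximum-likelihood fit for comparability; a continuous MLE exponent (with
k_min at the smallest observed degree) is available as a cross-check mode.
Fewer than three distinct degrees yields an explicitly undefined fit.

## Community detection (MCODE)

MCODE is implemented from scratch in three stages:

1. **Vertex weighting.** The weight of *v* is k·density of the highest
   k-core of the closed neighbourhood N[v]; vertices with degree below the
   degree cutoff (default 2) weigh 0.  The implementation is checked against
   a brute-force oracle that enumerates all subsets of N[v] on every
   connected graph with ≤ 7 nodes.
2. **Complex prediction.** Seeds are visited in decreasing weight; from an
   unassigned seed, a breadth-first expansion (≤ max_depth levels) adds
   unassigned neighbours whose weight is ≥ seed_weight·(1 − node_score_cutoff).
   Each vertex joins at most one complex.  Only vertices with positive
   weight may seed: a zero-weight seed would set the expansion threshold to
   zero and swallow its entire component.
3. **Post-processing.** Complexes without a 2-core are discarded; haircut
   iteratively removes degree-1 members; optional fluff (off by default)
   adds boundary vertices whose closed-neighbourhood density exceeds the
   fluff cutoff and may overlap between complexes.  The complex score is
   density × size, and communities are renumbered by descending score.

Defaults follow the clusterMaker-style parameterisation: degree cutoff 2,
node score cutoff 0.2, k-core 2, max depth 100, haircut on, fluff off.
All ties — seed order, neighbour visitation, final ranking — break
lexicographically on vertex id, so results are independent of input row
order.  This determinism is a deliberate choice; classic MCODE
implementations are iteration-order-dependent.  Edge weights are carried as
metadata but never influence the clustering (MCODE is topological).

One behavioural consequence worth knowing: two equally dense cliques joined
by a single bridge merge into one complex, because both bridge endpoints
inherit full weight from their own clique and pass the 80% threshold.  This
is the algorithm as specified, verified by hand on an 8-node example.

## Enrichment

Every enrichment question reduces to one exact test: a community of size
*n* drawn from a background of *N* genes containing *k* members of a set
with *K* background members is scored P(X ≥ k), X ~ Hypergeometric(N, K, n)
— the one-sided (greater) Fisher exact test.  One-sided is a deliberate
choice: enrichment is directional, and depletion is not of interest here.
Benjamini–Hochberg correction runs over one family per collection per run.
A row is significant at q < 0.05 with at least `min_overlap` overlapping
genes (0 for term/localization tests, 5 for TF-target tests).  Communities
below 5 genes are not tested.  GO-graph-aware decorrelation methods are
intentionally out of scope; this is the classic per-term test with the
network as background.

Note on BH: adjusted p-values are *not* idempotent under re-adjustment
(p = [0.0625, 1] at α = 0.2 is a counterexample), so the test suite checks
the meaningful property instead — thresholding q at α reproduces the BH
step-up decision rule on the raw p-values.

## Interaction Strength and super-communities

For disjoint communities *i*, *j* on a gene-wise network with *N* nodes and
*E* edges,

    IS(i, j) = observed_ij / (n_i · n_j · ρ),   ρ = 2E / (N(N−1))

i.e. observed inter-community edges over the count expected if edges were
placed uniformly at the network's global density.  This exchangeable-edge
null is the simplest calibratable choice: on Erdős–Rényi graphs with an
arbitrary partition the mean IS is exactly 1 in expectation (conditioning
on the total edge count makes the ratio unbiased), which the acceptance
suite verifies by simulation.  It is a deliberate stand-in for a richer
configuration-model expectation and should not be read as anything more.

The community-wise network has an edge wherever at least one gene-wise edge
crosses a community pair (IS > 0), annotated with the raw count and IS.
Super-communities are found by re-running MCODE with the same defaults on
the unweighted topology restricted to communities with ≥ 5 genes; IS
magnitudes are reported but do not influence the clustering.

## Sub-localization calls

Curated evidence takes precedence: genes in the curated centrosome
collection are centrosomal, then genes curated as ciliary are ciliary; a
gene in both collections is unresolved (the conflict case is undefined
upstream, so no arbitrary priority is invented).  Remaining genes are voted
from experiment membership counts, A over the 10 ciliary-group and B over
the 7 centrosomal-group experiments:

    A > B + 1 → ciliary;  B > A + 1 → centrosomal;  |A − B| ≤ 1 → unknown

The rule is total and is tested exhaustively on A ∈ {0..10} × B ∈ {0..7}
against an independent transcription.  Nuclear localization is an
orthogonal flag, never a competing call.

## TF targets

A gene is a candidate target of a TF when one of the TF's binding sites
overlaps (≥ 1 bp) the gene's regulatory window: gene body plus 10 kb beyond
the 5' end and 3 kb beyond the 3' end, strand-aware, 0-based half-open,
clipped at zero.  (10 kb/3 kb are the governing values; both are
configurable.)  Candidates are kept when Pearson r with the TF profile is
≥ 0.5 and the t-test of r survives BH at q < 0.05, the family being all
(TF, candidate) pairs of the run — an explicit, tunable proxy for a
"significantly co-expressed" criterion whose original definition is not
reproducible here.  TFs missing from the expression matrix, zero-variance
profiles, and TFs left without targets are dropped with warnings.
Community enrichment of target sets then uses the generic machinery with a
minimum of 5 targets, and a per-TF summary separates community-specific
TFs from shared ones.

## The synthetic generator

The generator emulates the shape of the real inputs, not their
distributions.  Defaults (a 100-gene universe; planted blocks of 8, 10, 12
and 15 genes; p_intra = 0.9; p_inter = 0.01; 4 evidence channels with
Gaussian channel noise sd 0.05; 10 + 7 experiments with flip probability
0.1; 8 TFs with 10-gene regulons; 30 expression conditions with noise sd
0.5) are the benchmark conditions used throughout the tests; they were
chosen once as a desk-scale regime where planted structure is recoverable
but not trivial.

* **Evidence.** Intra-block pairs are sampled at p_intra and draw Beta(8, 2)
  channel scores; if a sampled planted pair would combine below the cutoff
  pre-noise, its strongest channel is raised deterministically so the
  combined score reaches 0.75 — planted edges are guaranteed edges.  All
  other sampled pairs (rate p_inter) draw Beta(2, 8) scores that mostly
  fall below 0.7, so thresholding has real work to do on both sides of the
  cutoff.  Optional block groups add high-score cross-links between related
  blocks at p_group, giving the community graph dense regions for
  super-community recovery tests.
* **Experiments.** A truly ciliary gene appears in each ciliary-group
  experiment with probability 1 − flip_prob and in each centrosomal-group
  experiment with probability flip_prob (symmetrically for centrosomal;
  background genes flip everywhere).
* **Annotations.** One term per planted block seeds ~60% of the block and
  grows until its hypergeometric p against the universe is below 1e-4;
  other terms are uniform draws, which double as the null for calibration
  tests.
* **Regulons.** Planted regulons are pairwise disjoint and never contain a
  TF gene, so each target tracks exactly one latent factor and the planted
  correlation structure is well defined.  Expression ties TF and targets to
  a shared latent N(0, 1) profile plus noise; the expected TF–target
  Pearson r is 1/(1 + sd²) = 0.8 at the default sd 0.5.  Binding sites for
  every true target land inside the target's window; a configurable
  fraction of spurious in-window sites on non-targets gives the
  co-expression filter genuine false positives to remove, and one decoy per
  TF sits in the dead zone between windows (gene bodies of 10 kb separated
  by 30 kb guarantee windows never touch).
* **Determinism.** One RNG stream per run, drawn in a fixed order
  (universe → evidence → experiments → annotations → curated sets → TF
  data); identical configs produce byte-identical files.

What the generator does **not** emulate: real evidence-score distributions,
orthology structure, overlapping regulons, sequence-level motifs, GO DAG
structure, or degree heterogeneity beyond what the planted blocks induce.
Passing tests therefore demonstrate correctness of the machinery under
known structure — not performance claims about real interactome data.

## Measurement conventions

* **Planted-partition recovery** is scored by Adjusted Rand Index between
  planted block labels and detected community labels over the planted genes
  that were assigned to some community, with coverage (fraction of planted
  genes assigned) asserted separately (≥ 0.85).  MCODE is a partial
  clustering by design — background genes are never assigned — so
  conflating coverage with accuracy would measure neither.  Under the
  default conditions this yields mean ARI ≈ 0.96 and coverage ≈ 0.94 over
  20 seeds; the genes lost are those whose vertex weight falls just below
  the seed's 80% expansion threshold.
* **Null calibration** uses complete-null simulations (random communities,
  random sets), where the realized false-discovery proportion is 1 for any
  simulation with a rejection; the discreteness of the hypergeometric makes
  the procedure conservative, and the observed rate sits well below 0.05.
* Simulation sizes in the acceptance script (10 pipeline seeds, 50
  calibration graphs) are desk-scale choices; the test suite runs the
  larger 20-seed/100-graph versions.

## Known limitations

* The IS null ignores degree heterogeneity; hub-rich communities inflate
  IS relative to a configuration-model expectation.
* The OLS degree-distribution fit is a descriptive convention; it is biased
  as an estimator of a true power-law exponent and is reported with r²
  rather than a goodness-of-fit test.
* MCODE's greedy growth can merge equally dense modules joined by a heavy
  bridge and can orphan low-degree members of a module (see above); both
  behaviours are properties of the algorithm, not defects.
* Curated-set precedence means a miscurated gene cannot be rescued by
  experimental votes.
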