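# Methods

This note records the statistical models, conventions and numerical choices
behind `repeatome-kit`, in the spirit of a methods appendix.

## Data model and conventions

Abundances are genome proportions in percent of the holoploid (1C) genome;
absolute repeat amounts in Mbp are reconstructed as (%/100) × 1Cx(Mbp).
Mass/size conversion uses 1 pg = 978 Mbp, and 1Cx = 2C/ploidy. Published
tables print 1Cx rounded to 2 decimals while deriving the Mbp column from
the unrounded quotient, so the record validator allows a rounding-aware
tolerance (±0.0051 pg on 1Cx; ±6 Mbp on the product).

Missing abundance cells are *absent* (NaN), never zero: printed tables carry
explicit zeros, so 0 means a measured zero. Hitsort read names carry a
fixed-length species-code prefix ending at the first underscore (default
3 characters, configurable); comparative-clustering tools do not standardize
this, so the code length is surfaced rather than guessed.

## Observed/expected similarity matrices

For a cluster with E edges over N reads, the expected edge count of a
species pair (s, t) is the uniform-random-edges null conditioned on
per-species read counts: E·n_s·n_t/C(N,2) between species and
E·C(n_s,2)/C(N,2) within. The observed/expected ratio is 1 everywhere when
edges are exchangeable. This is the simplest null consistent with an
"observed/expected interspecies edges" statistic; whether upstream tools
post-normalize their matrices differently is unknowable from their outputs,
so the null is documented here rather than asserted as identical.

Two distance transforms are provided: the Euclidean distance between
species' full ratio profiles (diagonal columns included — they carry the
intra-species signal) and the elementwise inverse 1/S of off-diagonal
similarities. The Euclidean transform is a metric; the inverse transform
need not satisfy the triangle inequality and is kept for comparability.
Clusters with any missing or zero interspecies ratio are discarded before
network building, with per-cluster reasons reported.

## Neighbor-Joining and consensus networks

NJ is the standard Saitou–Nei agglomeration (minimize
Q_ij = (n−2)d_ij − Σd_ik − Σd_jk). Negative branch-length estimates are
clamped to zero with the deficit transferred to the joined partner's branch,
preserving the path length between the joined nodes; Q ties break at the
lowest (i, j) index pair, making runs deterministic. Consistency (exact
recovery on additive matrices) is tested exhaustively over all 4- and
5-taxon topologies and cross-checked against an independent implementation.

The consensus network retains every nontrivial split appearing in more than
a threshold fraction of the NJ trees, plus all trivial splits. The default
threshold is 0.25 — deliberately below majority rule, since the point of a
split network is to display conflicting signal; at ≥ 0.5 the output is a
compatible majority-rule split set. Split weights are the mean branch
length over the trees containing the split (mean rather than median; both
are defensible, the mean is configurable away). Splits are serialized as a
SplitsTree-compatible NEXUS SPLITS block.

## Phylogenetic signal (Blomberg's K)

K is computed from the Brownian covariance V (root-to-MRCA shared path
lengths) by the standard ratio-of-MSE formula with its Brownian
normalization. Significance uses tip randomization with the
phylogenetically corrected MSE as statistic (smaller = more signal) and the
add-one p-value, so p ≥ 1/(n_perm+1). The implementation matches a direct
GLS re-derivation to 1e-10 and the reference R implementation (phytools) to
1e-5 on fixture trees; under Brownian simulation on a 32-tip tree the mean
K is ≈ 1.0 and the permutation test's type-I error is ≈ 0.05.

K needs a rooted covariance; unrooted input trees are midpoint-rooted in
the pipeline (an outgroup can be used instead by rooting beforehand). A
`cladogram` flag sets all branch lengths to 1 for analyses on tree shapes
rather than divergence times — both modes are provided because comparative
studies often report only "tree cladograms were used".

## Contrasts, correlations, contributions

Independent contrasts follow Felsenstein's pruning on a fully bifurcating
tree with positive branch lengths (polytomies are rejected with an
instruction to resolve, rather than silently resolved). Contrasts have
expectation zero, so the per-family correlation with genome-size contrasts
is computed without re-centering (regression through the origin, n−1 df) —
the standard contrasts convention.

The contribution of family f to the genome-size difference of a pair
(a, b), oriented so GS_a > GS_b, is 100·(A_fa − A_fb)/(GS_a − GS_b); the
reported contribution is the mean over pairs. Signed orientation (not
absolute differences) is used so that families anti-correlated with genome
size show negative contributions, as published tables do. Pairs whose
genome sizes differ by less than 1% of the mean genome size (configurable)
are excluded to avoid division blow-ups; on additively composed data the
family contributions sum exactly to 100 minus the unclassified share.

## Hs/Ho conservatism profiles

Each read's intraspecific hit count Hs and interspecific count Ho are
per-capita normalized, ρ = [Hs/(n_s−1)]/[Ho/(N−n_s)], making the expected
ratio independent of sampling depth (verified by a depth-doubling test).
Reads with no hits are excluded; reads with only intraspecific hits are
capped at the histogram maximum and only-interspecific reads floored at the
minimum, so informative extremes stay counted instead of being dropped.
Histograms use 40 bins over log₁₀ρ ∈ [−2, 3] — wide enough for the long
diversified tails — and report the mode bin center and the fraction of
reads with |log₁₀ρ| < 0.2.

## Tandem-repeat graph typology

The connected-component index C is the largest-component fraction of the
cluster graph. Our generator produces undirected similarity graphs, so C
uses undirected components (the upstream tandem-detection tool works on a
directed graph; the two need not coincide exactly).

Loop counting: edges below `prune_weight_frac` (default 0.1) times the
median weight are pruned, the graph is restricted to its largest component
and degree-1 nodes are trimmed. On this residue the loop count is the
*triangle-filled* first Betti number: the cycle rank E − V + 1 minus the
GF(2) rank of the triangle boundary matrix. Plain cycle rank is the natural
"number of loops" on sparse skeletons (a circle: 1; a theta graph: 2), but
read-similarity graphs of tandem repeats are locally dense — overlapping
reads triangulate the circle — and cycle rank then counts every redundant
local chord. Filling triangles recovers the topological loop count (a thick
circular band still counts 1; two monomer circles glued along the conserved
gene segment count 2) while leaving sparse skeletons unchanged. Shape
type 1 ⇔ one loop, type 2 ⇔ two or more; a loop-free residue is flagged
"linear/ambiguous" instead of being forced into a type. This automates a
classification that is done by visual inspection in practice.

The k-mer cycle score builds a de Bruijn multigraph (default k = 11),
starts a greedy best-neighbor walk at the most frequent k-mer (ties
lexicographic), closes on first revisit, and reports the closed cycle's
share of all k-mer occurrences. Error-free single-monomer read sets score
≈ 1; two equal-abundance ribotypes of length L sharing a g-bp gene score
≈ (L+g)/2L (≈ 0.68 at the defaults); unrelated sequence fails to close
(score 0, with a warning).

## The synthetic-data generator

The generator emulates the *statistical structure* of comparative
read-clustering outputs, not sequencing itself. Defaults (8 species,
8 signal + 4 noise clusters, 40 reads/species/cluster) keep a full run
around a second while preserving the analyses' operating regime; real runs
feed ~500 000 reads per sample into clustering, which here survives only in
the proportion arithmetic (e.g. 5S proportions out of 500 000 reads).

* **Tree**: Yule (pure-birth) via forward simulation, rescaled to
  root-to-tip depth 1; one extra exponential waiting time after the last
  split keeps every terminal branch positive.
* **Amounts**: signal clusters are exp(Brownian motion) on the tree
  (σ² = 0.25 on the log scale around log 250 Mbp) — positive, right-skewed
  and tree-correlated, like real repeat families; noise clusters are i.i.d.
  log-normal. Genome size is Σ amounts /(1 − unclassified fraction), so
  composition is exact by construction and 1Cx sums land in the
  2 000–5 000 Mbp range typical of large-genome grasses.
* **Graphs**: within-species edge probability p_in = 0.5; between species
  p_in·c·exp(−λ·d_st) with conservatism c ∈ (0,1], decay λ ≥ 0 and
  patristic distance d_st. λ = 0, c = 1 makes species exchangeable
  (mean observed/expected ratio 1, tested); λ = 2, c = 0.2 gives strongly
  tree-structured graphs.
* **Tandem clusters**: 340-bp random circular monomers (5S repeat units are
  ~250–320 bp), a 120-bp shared gene segment in the two-ribotype case,
  100-bp reads (the platform's read length) from random circular offsets,
  edges between reads sharing ≥ 30 11-mers, optional per-base substitution
  errors. One RNG stream per seed, consumed in documented order
  (tree → amounts → graphs), so partial re-runs reproduce.

What the generator does *not* emulate: sequence-level retrotransposon
structure, chimeric clusters, library/GC biases, paired-end constraints, or
annotation errors. Passing tests therefore demonstrate correctness of the
downstream statistics under the stated generative model, not robustness to
every artifact of real skim data.

## Problem sizes and seeds

The test suite and the acceptance script run at desk scale by design:
calibration uses 200 Brownian replicates (32 tips) and 500 null datasets
(16 tips, 199 permutations each); tandem classification uses 50 clusters
per condition; Hs/Ho separation uses 20 replicate pairs; NJ consistency is
exhaustive over all 4- and 5-taxon topologies. All randomness flows from
explicit seeds, and pipeline runs write a manifest (version, seed, config
hash, per-output SHA-256) sufficient to reproduce a run byte-identically.

## Known limitations

* The headline published correlation between summed repeat amounts and
  genome size (R² = 0.83 in Loliinae) is not recomputable here: it needs
  per-species supplementary amounts and the study tree with branch lengths,
  neither of which is printed. The package instead demonstrates the
  estimator's correctness on additively composed synthetic data.
* Kruskal–Wallis grouping is caller-supplied; published tables are
  ambiguous about the grouping used for their per-family tests.
* The inverse-similarity distance is not a metric; NJ accepts it, but the
  Euclidean transform generally resolves better (as also observed in
  practice).
* Consensus-network appearance depends on the threshold; published figures
  rarely state the setting used, so it is a surfaced parameter rather than
  a fixed constant.
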