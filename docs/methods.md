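# Methods

## Model

The ranker rests on guilt-by-association: genes whose protein products
sit close together in the interactome tend to cause phenotypically
similar diseases. Similarity between two genes is therefore defined
piecewise on the PPI graph G(V, E, W):

- **Adjacent pairs — direct-neighbor (DN) score.** The neighborhood
  Γ(v) is *self-inclusive* (v's neighbors plus v, with w(v, v) = 1), so
  for an edge (i, j) both endpoints contribute 1 to the numerator
  Σ_{k ∈ Γᵢ∩Γⱼ} w(i,k)·w(j,k). This is the only reading under which
  every clause of the definition is exercised, and it gives an isolated
  dyad the score 2/√1 = 2. The denominator √max(Kᵢ, Kⱼ) deflates edges
  incident to hubs, whose many connections would otherwise inflate
  common-neighbor counts.

- **Non-adjacent pairs — t-step local random walk (LRW).** A walker
  started at i evolves by π(s+1) = Pᵀπ(s) with P[i,j] = w(i,j)/Kᵢ; the
  pair score combines both directions, weighted by Kᵥ/M. Truncating at
  t steps (default 3) keeps the score local — evidence cannot leak in
  from remote parts of the network — and costs O(t·|E|) per source via
  sparse matrix-vector products. Self-similarity is undefined and
  excluded everywhere: a seed gene is never its own candidate.

On weighted networks the binary adjacency a_ij generalizes to w(i,j) and
the degree k_i to the strength K_i; on a binary network the two coincide
exactly. The edge count M stays a count in either case.

- **GO similarity** is the information content −log(min_k |S_k|/S_max) of
  the most specific shared term, pooling all three GO aspects. Only
  directly assigned terms are used by default; `GOAnnotationSet` accepts
  an optional term→ancestors mapping for annotation propagation, but the
  measure is designed around annotation sets as given, not the GO DAG.
  The log base is natural by default and configurable — changing it is a
  monotone rescaling that the blend weight α absorbs.

- **Complex similarity** scores each catalogued complex on the network:
  density (edge count of the induced subgraph over its maximum) times
  the internal-weight ratio w_in/(w_in + w_bound). Density uses the
  members actually present in the network; complexes with fewer than two
  present members, or no internal edge, score 0 (this also guards the
  density denominator). On binary networks the score lies in [0, 1] and
  reaches 1 exactly for an isolated clique. SimCOM sums the scores of
  all complexes containing both genes.

## Blending and ranking

Sim = (1−α−β)·topo + α·SimGO + β·SimCOM with α, β ≥ 0, α+β ≤ 1
(defaults α = β = 0.1). The three components live on incommensurate
scales — DN is bounded by neighborhood sizes, SimGO by log(S_max), SimCOM
by catalog depth — so by default each component is divided by its maximum
over all (seed, candidate) pairs of the current ranking task before
blending. This per-task rescaling is the principal reproducibility
caveat: the raw blend is available via `normalize=False`, and with
α = β = 0 the two behaviors produce identical rankings.

A candidate's disease score is the sum of its blended similarity to
every known gene. Ranks are pessimistic: a candidate's rank is the
number of candidates scoring at least as high, so the gene of interest
is ranked last among ties (conservative success@k; an `average` tie rule
is available). Candidates with score exactly 0 rank at the candidate-set
size regardless of tie rule.

## Evaluation protocol

Leave-one-out with decoys: for each disease with at least `min_genes`
(default 5) known genes in the network, each known gene in turn is held
out, the remainder seed the ranker, and the target is ranked among
`decoys` (default 99) genes drawn uniformly without replacement from the
network excluding the disease's entire known-gene set — excluding fellow
seeds avoids label leakage, and the decoy draw is repeated per trial
from an RNG seeded by (config seed + trial index), making reports
reproducible from the seed alone. success@k is the fraction of trials
with target rank ≤ k, reported for k = 1..10.

Method variants: `dignifi` (topo only), `simgo`/`simcom`/`simbio`
(adding GO, complexes, or both), `lrw` (the walk for *all* pairs,
adjacent included), and `rwr` — random walk with restart, restart
probability 0.8, iterated to an L1 change below 1e-10 (an error with
iteration diagnostics is raised on non-convergence; with restart 0.8 the
contraction factor is 0.2, so convergence takes ~15 iterations). A thin
`rank_ttest` utility compares two methods' per-trial rank lists with a
two-tailed paired t-test.

## Synthetic benchmark

`FixtureSpec` generates all five inputs. The background interactome is a
preferential-attachment graph (500 genes, 3 edges per arriving node):
heavy-tailed degrees exercise the hub penalty the way a real interactome
would. Twenty disease modules of 6 genes each are wired internally with
probability 0.8 and outward to each background gene with probability
0.01, so within-module similarity dominates module-to-background
similarity. Each module carries one GO term annotating exactly its
genes; 30 background terms of 40–120 genes each (drawn over all genes,
3 extra per gene) provide uninformative annotation mass and set S_max.
80% of each module is wrapped as a complex; each module is one disease.
A 200-pair co-occurrence table with article counts 1–59 straddles the
enrichment threshold of 30. Everything is a deterministic function of
the spec seed; the reference configuration uses seed 42 and yields 620
genes and 2356 interactions.

What the generator does *not* emulate: false-positive/negative
interactions and study bias in curated PPI data, the GO DAG's
hierarchical correlation structure, complexes that cut across disease
modules, and diseases whose genes are topologically dispersed. Passing
the planted-module benchmark therefore shows the machinery recovers
modular signal under clean conditions; it does not predict absolute
performance on real interactome snapshots, where reported top-1 success
rates are several-fold lower.

## Numerical choices and conventions

- Edge-list cleaning: self-loops dropped, duplicate edges keep the
  maximum weight (deterministic and conservative), degree-0 nodes
  removed so every transition-matrix row is defined; cleaning is
  order-independent and the writer canonicalizes edge orientation, so
  write∘read is the identity.
- Literature-enrichment edges get weight 1.0 even on weighted networks —
  co-mention counts measure attention, not interaction strength.
- Walk vectors are memoized per (source, t) on the network object; no
  all-pairs precomputation (the per-seed cost is O(t·|E|)).
- Gene identifiers are opaque case-sensitive strings; no symbol aliasing
  or ID mapping is attempted.
- Tests compare floating-point values at absolute tolerance 1e-10
  (1e-12 for hand-derived closed forms); scores are reported at full
  double precision.
- Benchmark sizes (500-gene background, 120 leave-one-out trials, random
  oracle graphs ≤ 50 nodes) were chosen so the whole suite runs in
  seconds while every code path — including the full decoy protocol — is
  exercised end to end.

## Known limitations

- The per-task component rescaling means blended scores are comparable
  within one ranking task, not across tasks or diseases.
- GAF parsing keeps all evidence codes by default (`exclude_iea=True`
  drops electronic annotations); qualifier handling is limited to
  skipping NOT rows.
- Genes absent from the network score 0 as candidates unless
  `allow_offnet` admits their GO/complex components; known genes absent
  from the network are dropped with a warning.
- Other published rankers (shortest-path and annotation-weighted
  variants) are not implemented; the evaluation report format accepts
  externally computed rank files for side-by-side comparison instead.
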