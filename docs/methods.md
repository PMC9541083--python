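# Methods

## Model of a protein complex

The package treats a complex as a node subset of a weighted undirected PPI
graph `G = (V, E, W)`, organized as a dense *core* plus peripheral
*attachment* proteins. The core is assumed to be functionally homogeneous,
co-localized and co-expressed; attachments are recognized purely
topologically, by the aggregate weight with which they bind the core. These
assumptions drive each pipeline stage: co-expression and co-localization
gate local core growth, edge weights and the fitness function drive
attachment, and functional terms drive the final filter.

## Edge weights

Weights are reliability scores in [0, 1]. The default scorer is term-set
Jaccard similarity per GO branch (CC, BP, MF), averaged across branches; a
branch in which either protein is unannotated scores 0. This is a simple,
dependency-free annotation-overlap scorer; topology-aware semantic
similarity scorers that use the GO graph structure produce different (often
better-calibrated) weights, and the loader accepts their output verbatim as
a 3-column TSV. Zero-weight edges are kept: the cohesiveness and awm terms
handle zeros, and pruning would hide topology that forming can still use.
Duplicate input edges collapse to the maximum weight — the conservative
choice when two reports of the same interaction disagree.

## Tunable parameters

| parameter | meaning | range | note |
|---|---|---|---|
| `GCE` | co-expression threshold for absorbing a seed's neighbor (CEV scale, dimensionless) | 0.6–0.9 | CEV = (Pearson r + 1)/2 |
| `inflate` | MCL inflation exponent (granularity of global cores) | 0.5–4.0 | larger = finer clusters |
| `ratio` | fraction of proteins used as seeds | 0.5–0.9 | interpreted as a fraction, not a percentage: at sub-percent values real networks would yield almost no seeds |

These three are what the harmony search tunes. The search's own constants
(memory 30, 300 iterations, HMCR 0.7–0.95, PAR 0.5→0.1, fret width
0.01–0.1) are fixed defaults; tests and experiments shrink `maxiter` to 10–50
to keep runtimes in seconds, which is sufficient because the memory holds 30
evaluated harmonies before the loop even starts.

Degenerate-input conventions: an isolated protein has WCC 0; a zero-variance
expression vector yields CEV 0.5 (r treated as 0); all 0/0 ratios in the
fitness terms resolve to 0, so a degenerate cluster can never pass the
`fitness > 0` retention gate.

## Numerical choices

* **MCL.** Unit self-loops, column-stochastic flow matrix, expansion =
  matrix squaring, inflation = entrywise power + renormalization, pruning
  of entries below 1e-5, convergence when the largest entry change is below
  1e-6, cap 100 iterations (on non-convergence — typical for inflation
  exponents near 1, where inflation barely sharpens the flow — the current
  clustering is returned with a warning). Clusters are connected components
  of the converged flow's support, which guarantees a partition; singleton
  components are dropped since they can never reach the size-3 gate.
* **Forming.** Accepted moves must *strictly* increase fitness; with
  fitness bounded by 3 this guarantees termination, and together with
  lexicographic tie-breaking on protein IDs (used for seed ranking, best
  attachment and worst member alike) makes the whole pipeline
  deterministic. The two-round cap encodes the small-diameter assumption on
  complexes. The contraction pass only acts while the candidate has ≥ 4
  members.
* **Harmony search.** The fret-width perturbation is multiplied by each
  parameter's range width: the three parameters span very different scales
  (0.3 vs 3.5), and an unscaled step of at most 0.1 would effectively never
  move the inflation exponent. A pitch adjustment perturbs all three
  dimensions at once. Randomly generated harmonies always receive the
  perturbation, using the fret width of a worst-fitness harmony (widest
  step — they are explorers). Replacement of the worst memory slot requires
  a strictly better objective, so the best-objective trace is
  non-decreasing. The objective is memoized on parameters rounded to 4
  decimals — below the smallest fret-width step, so memoization can never
  mask a genuine move — and the parameter-independent ingredients (WCC
  ranking, pairwise CEV) are computed once per network. The schedules are
  evaluated as convex combinations so the endpoint values are floating-point
  exact. All randomness flows from one seeded NumPy generator.
* **Enrichment.** Hypergeometric upper tails come from scipy's survival
  function (log-space internally); the exact-rational oracle in the test
  suite confirms them to 1e-9 relative error on small universes. The 0.01
  significance cutoff is applied to raw minimum p-values, without
  multiple-testing correction, matching common complex-enrichment practice.
* **MMR** is implemented exactly as the per-reference-maximum formula
  (average of each reference complex's best neighborhood affinity), not as
  a bipartite one-to-one matching; the two differ when one prediction is
  the best match of several references.

## Synthetic fixtures

`simulate.generate` plants `n_complexes` vertex-disjoint near-clique cores
(sizes 4–8, intra-core edge probability 0.9 on top of a guaranteed spanning
ring, weights 0.8–1.0), 1–3 attachment proteins per core bound to at least
half the core at weights 0.4–0.7, background proteins, and sparse noise
edges (probability 0.005, weights 0.05–0.3). Core members share one
compartment and one functional term; attachments share the term and the
compartment half the time. Expression is a per-core latent time course
(12 points) mixed with Gaussian noise; the mixing weight is solved on the
Fisher z scale with a one-sided 95% margin so the *realized* pairwise CEV
reaches the 0.9 target despite short time courses (attachments target CEV
0.75). An overlapping mode shares one protein between consecutive cores.

What the generator does *not* emulate: scale-free degree structure, the
density regimes of real interactome screens, annotation incompleteness
correlated with study bias, or condition-dependent expression. Passing the
recovery tests therefore shows the pipeline is a correct implementation of
the method under its own assumptions — not that it attains any particular
accuracy on real interactomes.

`simulate.gce_window_fixture` is an adversarial identifiability fixture for
the parameter search. Three sparse hub-and-spokes modules are recoverable
only by local (co-expression-gated) mining: their leaves belong to dense
cliques that capture them under Markov clustering at every inflation, and a
dense decoy clique — bridged to every module protein by weak edges and
carrying the larger annotation group — floods the modules' seed-grown cores
whenever GCE drops below the planted between-group CEV of 0.72, after which
the functional filter eliminates them. Expression is built with *exact*
sample correlations (orthonormal-basis construction through the Cholesky
factor of the target correlation matrix), so the objective landscape has a
sharp step at GCE = 0.72 instead of a noise-smeared slope. Low-WCC filler
proteins pad the seed ranking so the module hubs fall inside the seed
cutoff across the whole ratio range. The fixture's manifest records the
window (0.72, 0.9]; the parameter-recovery experiment checks that the
search's best GCE lands inside [0.7, 0.9].

## Problem sizes

The test suite and experiments run on fixtures of roughly 40–160 proteins,
with 1000-case brute-force oracle sweeps on graphs of ≤ 12 nodes, 20 seeded
optimizer runs at 50 iterations for the monotonicity/reproducibility and
window-recovery experiments, and exact-rational hypergeometric checks up to
a 30-protein universe. These sizes make every oracle enumerable and keep
the full suite under a minute while exercising all code paths; the pipeline
itself is O(|V|·deg²) for seeding plus dense-matrix MCL, comfortably
handling the few-thousand-node networks the method targets.

## Known limitations

* The Jaccard annotation scorer is a stand-in interface default, not a
  semantic-similarity method; real analyses should load precomputed
  weights from a dedicated tool.
* MCL uses dense matrices — fine to ~10⁴ nodes, wasteful beyond.
* The functional filter assumes annotations exist for most complex
  members; sparsely annotated networks will see many candidates dropped at
  the size-3 gate.
* Harmony-search quality depends on the objective being informative: on
  networks where the filtered-complex fitness sum is flat in a parameter,
  that parameter is returned essentially at random within its range (the
  window fixture demonstrates the identifiable case).
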