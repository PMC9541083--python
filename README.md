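# ppicomplex

Detection of protein complexes in weighted protein–protein interaction (PPI)
networks, for systems biologists who have an interaction network plus the
usual side evidence — gene-expression time courses, subcellular localization
and functional (GO-slim style) annotation — and want complex predictions
whose tuning parameters are chosen automatically for the network at hand.

## The method

Protein complexes have a *core–attachment* organization: a dense, highly
co-expressed, co-localized core plus peripheral attachment proteins bound to
it. The pipeline mirrors that structure:

1. **Edge weighting.** Each interaction (v, u) gets a reliability weight
   from functional-annotation similarity, averaged over the three GO
   branches: `w(v,u) = (sim_CC + sim_BP + sim_MF) / 3`. The per-branch
   scorer is pluggable (built-in term-set Jaccard; weights from external
   semantic-similarity tools can be loaded verbatim).
2. **Core mining.** Seeds are the top `ratio` fraction of proteins by the
   weighted local clustering coefficient
   `WCC(p) = 2 Σ_{(v,u)∈LN(p)} w(v,u) / (√|LN(p)| (|LN(p)|−1))`,
   with `LN(p) = N(p) ∪ {p}`. A seed absorbs each neighbor that is
   co-expressed with it — rescaled Pearson correlation
   `CEV(v,u) = (r+1)/2` above the threshold `GCE` — and shares a
   subcellular compartment. Global cores come independently from Markov
   clustering (MCL) with inflation exponent `inflate`; the two core sets
   are unioned and deduplicated.
3. **Fitness.** A cluster C is scored by
   `fitness(C) = density(C) + cohesiveness(C) + awm(C)` where
   `cohesiveness = W_in/(W_in+W_out)`, `density = 2W_in/(|C|(|C|−1))` and
   `awm = AIEW/(AIEW+ABEW)` compares average internal and border edge
   weights.
4. **Forming.** Each core alternately inserts the neighbor with the best
   attachment score `attachscore(v,C) = Σ_{u∈C} w(v,u)/|C|` and removes its
   weakest member, accepting only moves that strictly increase fitness, for
   at most two rounds. Candidates survive iff fitness > 0 and size ≥ 3.
5. **Filtering.** Within each candidate only the members sharing the most
   common functional term are kept (size ≥ 3 again).
6. **Parameter adaptation.** The three tunables (GCE ∈ [0.6, 0.9],
   inflate ∈ [0.5, 4.0], ratio ∈ [0.5, 0.9]) are chosen by an adaptive
   harmony search maximizing `OF_fitness = Σ_i fitness(C_i)` over the
   detected complexes, with time- and fitness-adaptive control parameters
   (HMCR 0.7→0.95, PAR 0.5→0.1, fret width 0.01–0.1, memory 30,
   300 iterations).

Predictions are scored against reference catalogs with neighborhood
affinity `NA(S,D) = |S∩D|²/(|S||D|)`, F-measure, ACC, MMR, Frac, a
size-weighted Jaccard composite and their sum (total score), plus
hypergeometric functional-enrichment p-values per complex.

## Worked example

Everything below is reproducible; no downloads are needed — the package
ships a synthetic-fixture generator that plants core–attachment complexes
with matched expression, localization and annotation evidence.

```python
from ppicomplex import ComplexDetectionModel
from ppicomplex.simulate import FixtureSpec, generate

fx = generate(FixtureSpec(seed=1))          # 10 planted complexes, 105 proteins
model = ComplexDetectionModel(fx.network, fx.evidence)
res = model.fit(method="fixed", gce=0.8, inflate=2.0, ratio=0.7)
print(res.summary())
print(res.evaluate(fx.truth).summary())
```

```
Protein complex detection results
==============================================
method                    fixed
seed                      0
proteins in network       105
interactions              299
----------------------------------------------
GCE (co-expression thr.)  0.8000
MCL inflation             2.0000
seed ratio                0.7000
objective (sum fitness)   25.9769
----------------------------------------------
detected complexes        11
mean complex size         8.45
==============================================
Complex detection evaluation
----------------------------------------
reference complexes  10
predicted complexes  11
precision            1.0000
recall               1.0000
F-measure            1.0000
Sn                   0.9882
PPV                  1.0000
ACC                  0.9941
MMR                  0.9833
Frac                 1.0000
Jaccard              0.9808
total score          4.9582
```

All 10 planted complexes are matched (Frac = 1, F-measure = 1); the near-1
MMR/Jaccard reflect one attachment protein missed in one complex, and the
extra predictions are sub-variants of planted complexes that differ by one
attachment.
`model.fit(method="harmony", seed=0)` instead searches the parameter space
and returns the best harmony with its optimization trace
(`res.trace`, monotone best objective by construction).

The same pipeline is scriptable from the shell:

```bash
ppicomplex simulate --seed 1 --outdir fx
ppicomplex detect fx/network.tsv --expression fx/expression.tsv \
    --localization fx/localization.tsv --annotations fx/annotations.tsv \
    --gce 0.8 --inflate 2.0 --ratio 0.7 --outdir run
ppicomplex evaluate run/complexes.txt fx/complexes.txt
```

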