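# fpe — essential-protein prediction on PPI networks

`fpe` predicts essential proteins — proteins whose deletion is lethal —
from a protein–protein interaction (PPI) network and three kinds of
biological evidence: gene-expression time courses, subcellular-localization
records and a protein-complex catalog.  It implements a discrete flower
pollination metaheuristic that searches for a size-Q candidate set
maximizing an additive essentiality score, together with the classical
topology-only centralities (DC, SC, IC, EC, LAC, NC, PeC) and a top-k
ranking evaluation suite.  A seeded synthetic-data generator with planted
essentials makes the whole pipeline testable without any database download.

It is intended for computational biologists studying gene essentiality and
for anyone benchmarking set-based metaheuristics on biological networks.

## The score and the search

Each protein i receives

    gsc(i) = SL(i) · [ α·PeC(i) + (1−α)·PC(i) ],      α = 0.6 by default

where

* `PeC(i) = Σ_{v∈N_i} ECC(i,v)·PCC(i,v)` couples the edge clustering
  coefficient `ECC(i,j) = |N_i∩N_j| / min(d_i,d_j)` with the Pearson
  correlation of expression profiles,
* `SL(i)` sums, over protein i's annotated subcellular locations, each
  location's frequency among known essential proteins' annotation records,
* `PC(i)` counts the known complexes containing i.

The fitness of a candidate set H with |H| = Q is `Σ_{i∈H} gsc(i)`.  A
population of "pollens" (candidate sets) is seeded from the Q
highest-degree proteins and evolves by switching, with probability p,
between a Gbest-guided global move (keep the members shared with a random
slice of the best set found so far, refill the rest uniformly) and an
identity local move, with greedy acceptance.  The final best set is
returned ranked by gsc.  See `docs/methods.md` for the full model,
parameter meanings and search-regime analysis.

## Worked example

`examples/03_run_search_and_evaluate.py` generates a 500-protein network
with 50 planted essentials, runs the search for a 50-protein candidate set
and evaluates it:

```text
gbest fitness: 66.897 (initial 12.977)
top 5 candidates (protein, gsc):
  P0318  2.008  [essential]
  P0470  1.852  [background]
  P0280  1.813  [essential]
  P0223  1.809  [background]
  P0128  1.791  [essential]
precision@50: FPE 0.68 vs degree centrality 0.18
jackknife: 34 of the 50 planted essentials appear in the 50 returned candidates
```

The search multiplies the fitness of its top-degree starting set fivefold,
and 34 of its 50 candidates are truly essential, versus 9 of 50 for plain
degree centrality — the planted biological signal (hub location, complex
membership, co-expression) is what separates them.  The other examples show
dataset generation (`01`) and the score table and baselines (`02`).

## Command line

The same pipeline is available as a CLI; every run writes a JSON manifest
(resolved parameters, input digests, seed, version) next to its output.

```sh
fpe synth --out data --n 1000 --seed 7
fpe score --network data/network.tsv --expression data/expression.tsv \
    --subcell data/subcellular.tsv --complexes data/complexes.tsv \
    --essential data/essential.txt --out scores.tsv
fpe baseline --method dc --network data/network.tsv --out dc.tsv
fpe run --network data/network.tsv --expression data/expression.tsv \
    --subcell data/subcellular.tsv --complexes data/complexes.tsv \
    --essential data/essential.txt --q 100 --seed 42 --out ranking.tsv
fpe evaluate --ranking ranking.tsv --ranking dc.tsv \
    --essential data/essential.txt --cutoffs 50,100 --out report.tsv
```

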