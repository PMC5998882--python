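# Methods

## Problem

Essential proteins are those whose loss is lethal to the organism.  In
protein–protein interaction (PPI) networks they are enriched among highly
connected nodes (the centrality–lethality rule), but topology alone is a
weak predictor.  This package predicts a candidate set of essential proteins
from five inputs — an undirected PPI edge list, gene-expression time
courses, subcellular-localization records, a protein-complex catalog and a
list of known essentials — by combining three biological signals into a
single additive set score and searching for a high-scoring set of fixed
size Q with a discrete flower pollination metaheuristic.

## Scores

For an edge (i, j) with neighbor sets N_i, N_j and degrees d_i, d_j:

* **ECC(i, j) = |N_i ∩ N_j| / min(d_i, d_j)** — how embedded an interaction
  is in triangles; values in [0, 1].
* **PCC(i, j)** — sample Pearson correlation of the two proteins' expression
  time courses (length T ≥ 2).  A zero-variance profile yields PCC = 0: the
  correlation is undefined there and 0 is the neutral co-expression value.
* **p_c(i, j) = ECC(i, j) · PCC(i, j)** and **PeC(i) = Σ_{v∈N_i} p_c(i, v)**
  — the co-clustering score of a protein over its interactions.
* **SL(i) = Σ_{r ∈ C(i)} F(r)** where F(r) = S_r / |S| is the frequency of
  location r among the annotation records S of known essential proteins and
  C(i) is protein i's own annotated location set.  SL ∈ [0, 1] because F is
  a probability vector over locations.
* **PC(i)** — the number of cataloged complexes containing i.

The combined per-protein component is

    gsc(i) = SL(i) · [α · PeC(i) + (1 − α) · PC(i)],    α ∈ [0, 1],

and the fitness of a candidate set is the sum of its members' components.
α defaults to 0.6 (the value reported to work best in the parametric
analysis the measure derives from); it weights co-expression topology
against complex membership, with SL acting as a multiplicative gate.

Missing data is neutral everywhere: no expression profile → p_c = 0, no
subcellular record → SL = 0, no complex membership → PC = 0.  Proteins
present in the biological files but absent from the network are scored but
can never enter a candidate set.

Because the fitness is additive, the optimal size-Q set is exactly the top
Q proteins by gsc.  The optimizer is still implemented in full — it is the
method under study — and the closed form serves as the test oracle.

## The discrete flower pollination search

A *pollen* is a set of exactly Q distinct protein IDs.  The population is
seeded from the Q highest-degree proteins (degree ties broken by ID);
each non-elite pollen swaps ⌈β·Q⌉ members for uniform outsiders (β, the
perturbance factor, defaults to 0.2).  Per pollen and iteration a uniform
draw u < p triggers the **global move**:

1. sample a uniform subset G′ of the best-so-far set (Gbest) of size ⌈γ·Q⌉;
2. keep K = pollen ∩ G′;
3. refill the Q − |K| open slots uniformly without replacement from the
   node set minus K.

Otherwise the **local move** applies, which keeps the position unchanged.
A proposal replaces its pollen only when its fitness is at least the
incumbent's (greedy acceptance; the best-so-far fitness is therefore
non-decreasing), and Gbest is updated on strict improvement.  The run
executes a fixed iteration budget with no early stopping, then ranks the
final Gbest members by gsc descending, ties by ID.  One
`numpy.random.Generator` drives everything in a documented order
(initialization, then per-iteration per-pollen draws), so a run is a pure
function of inputs and seed.

Defaults: Q = 600, p = 0.3, α = 0.6, N = 20 pollens, 100 iterations,
β = 0.2, γ = 0.5.

### Search-regime behavior

The move set has a property worth knowing before choosing parameters: a
pollen can *keep* members shared with Gbest but can never *import* Gbest
members it lacks, so pollens that drift away from Gbest produce mostly
rejected proposals and freeze.  The productive search is carried by the
Gbest-adjacent lineage, whose proposal budget is roughly
iterations × P(global move).  Consequences:

* At the coarse defaults (γ = 0.5) an accepted global move replaces about
  half the set with uniform draws.  Such moves almost never improve a good
  set, so the default regime relies on the top-degree initialization being
  already close to the target — which is the realistic situation in PPI
  networks, where degree correlates with essentiality.
* With γ = (Q − 1)/Q the slice drops exactly one member and the global move
  becomes a single-member swap: a stochastic hill climb that provably
  converges on the additive fitness landscape.  With β = 0 all pollens
  start at the elite and remain Gbest-adjacent, so the whole population
  contributes useful proposals.

The convergence and planted-recovery benchmarks therefore run in the
fine-swap regime (γ = (Q−1)/Q, β = 0, p = 1, small population), while the
package defaults keep the coarse, literature-style values.  Both regimes
are plain configurations of the same operator.

## Baseline centralities

Six topology-only baselines are provided for comparison: degree (DC),
subgraph (SC, diagonal of the adjacency matrix exponential, computed
spectrally up to 5000 nodes and by the truncated walk series beyond, series
tolerance 1e−8), eigenvector (EC, per connected component, non-negative
Perron convention, unit Euclidean norm), Stephenson–Zelen information
centrality (IC, with the self-term 1/I_ii taken as 0, per component;
isolated nodes score 0), local average connectivity (LAC) and neighborhood
centrality (NC = per-node sum of incident-edge ECC), plus the PeC score as
a seventh, expression-aware baseline.  EC and IC are defined per connected
component because the measures are undefined across disconnected parts.

## Synthetic benchmark data

`fpe.synthetic.generate_dataset` emulates the five inputs with planted
ground truth:

1. **Network** — a Barabási–Albert preferential-attachment backbone
   (heavy-tailed degrees, connected), m = 3 attachment edges per node.
2. **Essentials** — ⌈0.1·n⌉ proteins drawn uniformly.
3. **Complexes** — 30 cliques of 4–8 members, filled ~70% from the
   essential pool until it exhausts; clique edges are added to the network.
   Planted complexes are pairwise disjoint so each member carries exactly
   one latent expression signal; real catalogs overlap, which this
   generator deliberately does not emulate.
4. **Expression** — T = 36 time points; members of a complex share a latent
   Gaussian signal mixed as x = s·z + ε with s = σ√(ρ/(1−ρ)), giving the
   closed-form expected within-complex Pearson correlation ρ (default 0.7,
   noise σ = 1).  Non-members get independent noise.
5. **Locations** — 11 labels; an essential's primary annotation is a
   designated hub location with probability 0.95, otherwise uniform; every
   protein may carry a second uniform annotation with probability 0.3.

The defaults are calibrated so the planted essentials dominate all three
signals (SL through the hub location, PC and PeC through complex
membership) — that dominance is the premise of the recovery benchmark.
Complex sizes of 4–8 mirror the small average size of curated yeast
catalogs and keep the background-member pool small; a high location bias
encodes the strong concentration of known essentials in one compartment.
What passing the benchmark shows is that the pipeline recovers a signal of
this planted form; it does not certify performance on real data, where
ID mismatches, overlapping complexes, periodic expression structure and
annotation noise all intrude.

## Numerical and procedural choices

* Ranking ties break by protein ID ascending, making every output
  deterministic.
* The network loader drops duplicate (either orientation) and self-loop
  records and refuses files with no valid edge; expression rows with
  non-numeric cells are rejected with a warning, while malformed lengths
  and duplicate IDs are hard errors.
* Location-frequency estimation can exclude a protein set (to avoid
  circularity when evaluating proteins that are themselves in the known
  essential list); the default uses the full list, matching standard
  practice for the SL score.
* Curve containers require non-decreasing x; precision–recall curves repeat
  a recall value at non-hit ranks, jackknife curves are strictly increasing
  in rank.
* Benchmark problem sizes (n = 1000 for recovery, n = 100 / Q = 10 for
  oracle convergence, 100 random graphs of n ≤ 30 for the ECC cross-check)
  were chosen to give stable statistics at desk scale.

## Known limitations

* At coarse settings the optimizer's quality is bounded by its top-degree
  initialization; the fine-swap regime is effectively a seeded hill climb.
  Both are faithful to the published move set — the search is simply not a
  strong optimizer far from its initialization.
* The SL score inherits any circularity present in the known-essential
  list; the `exclude_from_frequencies` option mitigates but does not remove
  this in benchmarking.
* No ID normalization is attempted across input files; callers must supply
  pre-matched identifiers.
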