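"""Run the flower pollination search and evaluate its ranking.

Searches for the 50 most essential-looking proteins in a 500-protein
synthetic network (fine-swap regime: single-member-swap global moves, all
pollens proposing every iteration), then scores the result with top-k
precision and the jackknife curve against the planted truth.
"""

from fpe import (
    FPEConfig,
    GSCConfig,
    SyntheticConfig,
    build_score_table,
    generate_dataset,
    jackknife_curve,
    precision_at_k,
    run_fpe,
)
from fpe.topology import degree_centrality

dataset = generate_dataset(SyntheticConfig(n_proteins=500, seed=11))
table = build_score_table(
    dataset.network, dataset.expression, dataset.subcellular,
    dataset.complexes, dataset.essential,
)

config = FPEConfig(q=50, iterations=2000, p=1.0, beta=0.0,
                   gbest_fraction=0.98, population_size=4, alpha=0.6, seed=11)
result = run_fpe(dataset.network, table, config)

print(f"gbest fitness: {result.gbest_fitness:.3f} "
      f"(initial {result.state.history[0]:.3f})")
print("top 5 candidates (protein, gsc):")
for pid in result.ranking[:5]:
    flag = "essential" if pid in dataset.essential else "background"
    print(f"  {pid}  {result.gsc[pid]:.3f}  [{flag}]")

p50 = precision_at_k(result.ranking, dataset.essential, 50)
dc_rank = degree_centrality(dataset.network).ranking()
dc50 = precision_at_k(dc_rank, dataset.essential, 50)
print(f"precision@50: FPE {p50:.2f} vs degree centrality {dc50:.2f}")

jk = jackknife_curve(result.ranking, dataset.essential)
print(f"jackknife: {int(jk.y[-1])} of the {len(dataset.essential)} planted "
      f"essentials appear in the 50 returned candidates")

# The search multiplies its initial (top-degree) fitness severalfold by
# swapping network hubs for proteins the GSC score marks as essential.
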