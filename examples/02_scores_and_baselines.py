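"""Score proteins with PeC / SL / PC and compare baseline centralities.

Computes the per-protein score table on a small synthetic dataset and shows
how the combined GSC component separates planted essentials from the
background, next to plain degree centrality.
"""

import numpy as np

from fpe import SyntheticConfig, generate_dataset, build_score_table, GSCConfig
from fpe.fitness import attach_gsc
from fpe.topology import centrality_by_name

dataset = generate_dataset(SyntheticConfig(n_proteins=300, n_complexes=10, seed=3))
table = build_score_table(
    dataset.network, dataset.expression, dataset.subcellular,
    dataset.complexes, dataset.essential,
)
attach_gsc(table, GSCConfig(alpha=0.6))

essentials = sorted(dataset.essential.members)
background = sorted(dataset.network.nodes - dataset.essential.members)
for label, group in (("essential", essentials), ("background", background)):
    pec = np.mean([table.pec[p] for p in group])
    sl = np.mean([table.sl[p] for p in group])
    pc = np.mean([table.pc[p] for p in group])
    gsc = np.mean([table.combined[p] for p in group])
    print(f"{label:10s}  mean PeC {pec:5.2f}  mean SL {sl:4.2f}  "
          f"mean PC {pc:4.2f}  mean GSC {gsc:5.2f}")

dc = centrality_by_name(dataset.network, "dc")
top20 = dc.ranking()[:20]
hits = sum(1 for p in top20 if p in dataset.essential)
print(f"degree centrality: {hits}/20 of its top-20 are planted essentials")

# GSC separates the groups by an order of magnitude because the planted
# essentials carry the hub location (high SL) and sit in co-expressed
# cliques (high PeC, PC); degree alone confuses network hubs with them.
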