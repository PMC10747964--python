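#!/usr/bin/env python
"""Fine-scale population structure of the simulated cohort: pedigree
kinship matrix, case counts under shared ancestors, and the mutual
k-nearest-neighbour network (k = 10) from identity-by-state distances.

Reads results/cohort/, writes the kinship matrix and network tables under
results/network/.
"""

from pathlib import Path

import networkx as nx

from lymphmap import formats, network
from lymphmap.kinship import common_ancestor_cases, kinship_matrix, read_pedigree, write_matrix

IN = Path("results/cohort")
OUT = Path("results/network")
OUT.mkdir(parents=True, exist_ok=True)

ped = read_pedigree(IN / "pedigree.tsv")
phi = kinship_matrix(ped)
write_matrix(OUT / "kinship.tsv", phi)

ranked = sorted(
    ((common_ancestor_cases(ped, f), f) for f in ped.founders), reverse=True
)
print("case descendants per founder (top 3):")
for n, f in ranked[:3]:
    print(f"  {f}: {n} cases trace to this ancestor")

gm, phe = formats.read_ped_map(IN / "cohort.ped", IN / "cohort.map")
dist = network.ibs_distance(gm)
status = dict(zip(phe["sample_id"], phe["status"]))
g = network.mutual_knn_network(dist, k=10, status=status)
network.write_network(OUT / "edges.tsv", OUT / "nodes.tsv", g)

comps = list(nx.connected_components(g))
case_comps = {g.nodes[n]["component"] for n in g if g.nodes[n]["status"] == "case"}
print(f"network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges, "
      f"{len(comps)} components")
print(f"cases occur in {len(case_comps)} component(s)")
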