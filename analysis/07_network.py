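"""Spearman co-occurrence network over core taxa: edges need |rho| > 0.25
and BH-adjusted p < 0.001; the hub is the most connected taxon."""

from pathlib import Path

from herdscan import io
from herdscan.diversity import core_taxa_filter
from herdscan.network import build_network, spearman_matrix, write_edge_list, write_graphml

BASE = Path(__file__).resolve().parent.parent / "results"
abundance = io.read_abundance_tsv(BASE / "data" / "abundance.tsv")

core = core_taxa_filter(abundance)
rho, p = spearman_matrix(core)
net = build_network(rho, p)

out = BASE / "network"
out.mkdir(parents=True, exist_ok=True)
write_edge_list(net, out / "edges.tsv")
write_graphml(net, out / "network.graphml")

print(f"{core.shape[1]} core taxa, {len(net.edges)} co-occurrence edges")
if net.hubs:
    deg = net.graph.degree[net.hubs[0]]
    print(f"hub taxa (degree {deg}): {', '.join(net.hubs)}")
    pos = (net.edges['sign'] == 'positive').sum()
    print(f"{pos} positive / {len(net.edges) - pos} negative edges")
else:
    print("no edges pass both thresholds (expected when taxa are "
          "conditionally independent)")
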