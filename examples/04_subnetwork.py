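"""Extract the ferroptosis subnetwork and find its linking node(s).

On a synthetic parent network, seeds the subnetwork from ferroptosis-tagged
genes, adds the mediating nodes needed to connect them, and reports the
nodes through which the subnetwork attaches to the rest of the interactome.
"""

import pcosnet as p
from pcosnet.graph_core import largest_component

spec = p.SyntheticSpec(seed=7)
genes, edges, _ = p.generate_network(spec)
g = p.build_graph(edges, genes)
orphans = set(g.nodes) - largest_component(g)
g = p.annotate_novel(g, p.find_connectors(g, orphans, edges))

report = p.extract_subnetwork(g, literature_tag="fpt_associated")
linking = p.linking_nodes(g, report)

print(f"subnetwork: {len(report.seeds)} seeds + {len(report.mediators)} mediators")
print(f"mediators: {sorted(report.mediators)}")
print(f"linking nodes: {len(linking)}")
if len(linking) == 1:
    print(f"single-bottleneck attachment through {next(iter(linking))}")
# Mediators are non-seed genes sitting on two-edge paths between seeds; the
# linking nodes are where every connection to the remaining network crosses.
# A single linking node marks a one-gene bottleneck between the process
# subnetwork and the rest of the interactome.
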