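"""Build meta-path filtered drug-disease networks from a toy interactome.

A drug and a disease are linked under a meta-path whenever a typed chain of
edges connects them; the filtered-network entry counts those chains.  Here
aspirin shares two target proteins with headache, so the shared-target
meta-path Dr-P-Di counts 2 path instances.
"""

from metapathdr import (
    HeteroNetwork,
    NodeRef,
    build_filtered_network,
    count_paths,
    parse_metapath,
)

net = HeteroNetwork()
net.add_edge("drug-protein", "aspirin", "COX1")
net.add_edge("drug-protein", "aspirin", "COX2")
net.add_edge("drug-protein", "ibuprofen", "COX2")
net.add_edge("disease-protein", "headache", "COX1")
net.add_edge("disease-protein", "headache", "COX2")
net.add_edge("protein-protein", "COX1", "COX2")
net.add_edge("protein-function", "COX1", "prostaglandin_synthesis")
net.add_edge("protein-function", "COX2", "prostaglandin_synthesis")

for spec in ("Dr-P-Di", "Dr-P-P-Di", "Dr-P-F-P-Di"):
    mp = parse_metapath(spec)
    filtered = build_filtered_network(net, mp)
    print(f"meta-path {mp.label}:")
    dense = filtered.matrix.toarray()
    for r, drug in enumerate(filtered.drug_index):
        for c, disease in enumerate(filtered.disease_index):
            oracle = count_paths(net, mp, NodeRef("Dr", drug), NodeRef("Di", disease))
            print(f"  {drug} -> {disease}: {dense[r, c]} path instances"
                  f" (enumeration: {oracle:g})")

print()
print("Each entry is A_P(i, j) from the typed adjacency product; the")
print("brute-force enumeration agrees exactly, including walks that revisit")
print("a protein at different positions.")
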