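"""Generate AP and BP pair-count fingerprints for small molecules.

Each descriptor is "atom type - bond distance - atom type"; its count
is the number of unordered heavy-atom pairs realising it.
"""

from qsardnn import generate_fingerprint, merge_fingerprints, toy_molecules

toys = toy_molecules()
for name in ("propane", "ethanol", "benzene"):
    graph = toys[name]
    ap = generate_fingerprint(graph, "AP", max_distance=7)
    bp = generate_fingerprint(graph, "BP", max_distance=7)
    merged = merge_fingerprints(ap, bp)
    print(f"{name} ({graph.n_atoms} heavy atoms)")
    for key, count in merged.to_text_counts().items():
        print(f"  {key}: {count}")
    print(f"  total pairs counted: {ap.total()} (= n(n-1)/2 when connected)\n")

# The same works for molecules parsed from SDF files or RDKit objects:
try:
    from rdkit import Chem

    from qsardnn.molgraph import graph_from_rdkit

    aspirin = graph_from_rdkit(Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(O)=O"))
    fp = generate_fingerprint(aspirin, "AP", 7)
    print(f"aspirin: {len(fp)} distinct AP descriptors, {fp.total()} pairs")
except ImportError:
    pass
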