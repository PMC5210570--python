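"""Name a functional family from member descriptions and build a network.

Naming drops redundant sequences, scores terms by frequency, and favours
descriptions of typical length.  The network links families whose profile
similarity is strictly above 10 bits; node size is the member count.
"""

from cathkit import name_cluster
from cathkit.funfam import FunFamRecord, build_funfam_network

records = [
    ("s1", "Alanine racemase", "ACDEFGHIKLMNPQRSTVWY"),
    ("s2", "Alanine racemase", "YWVTSRQPNMLKIHGFEDCA"),
    ("s3", "Alanine racemase catabolic", "AACCDDEEFFGGHHIIKKLL"),
    ("s4", "Putative protein", "MMNNPPQQRRSSTTVVWWYY"),
]
result = name_cluster(records)
print(f"chosen name: {result.name}")
print("description scores:")
for text, score in sorted(result.description_scores.items(), key=lambda kv: -kv[1]):
    print(f"  {score:5.2f}  {text}")

fams = [
    FunFamRecord("3.40.50.620/FF/1", members=["a", "b", "c"]),
    FunFamRecord("3.40.50.620/FF/2", members=["d"]),
    FunFamRecord("3.40.50.620/FF/3", members=["e", "f"]),
]
bits = {("3.40.50.620/FF/1", "3.40.50.620/FF/2"): 23.4,
        ("3.40.50.620/FF/2", "3.40.50.620/FF/3"): 9.9}
graph = build_funfam_network(fams, bits, threshold=10.0)
print(f"\nnetwork: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edge(s)")
print("the 9.9-bit pair is NOT linked: edges require strictly more than 10 bits")
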