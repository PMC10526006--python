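"""Score one source-target pair: metapaths, HeteSim, DWPC.

A tiny hand-built graph where a candidate source reaches the target along
two different typed patterns, one of which runs through a promiscuous hub
concept that degree weighting penalizes.
"""

from lbdhub import KnowledgeGraph, dwpc, enumerate_metapaths, hetesim

g = KnowledgeGraph()
for cui, name, st in [
    ("C0000001", "candidate protein", "AAPP"),
    ("C0000002", "specific mediator", "PHSU"),
    ("C0000003", "promiscuous hub", "PHSU"),
    ("C0000010", "disease", "DSYN"),
    ("C0000004", "unrelated a", "AAPP"),
    ("C0000005", "unrelated b", "AAPP"),
]:
    g.add_concept(cui, name, {st})

pmid = iter(range(30000000, 30000100))
for s, p, o in [
    ("C0000001", "STIMULATES", "C0000002"),
    ("C0000002", "CAUSES", "C0000010"),
    ("C0000001", "INTERACTS_WITH", "C0000003"),
    ("C0000003", "CAUSES", "C0000010"),
    ("C0000004", "INTERACTS_WITH", "C0000003"),   # hub noise
    ("C0000005", "INTERACTS_WITH", "C0000003"),
]:
    g.add_predication(s, p, o, {str(next(pmid))})

groups = enumerate_metapaths(g, "C0000001", "C0000010", max_len=2)
print(f"{len(groups)} metapath schemas connect the candidate to the disease:")
for schema, instances in groups.items():
    h = hetesim(g, "C0000001", "C0000010", schema)
    raw = dwpc(instances, g, w=0.0)
    damped = dwpc(instances, g, w=0.4)
    print(f"  {str(schema):45s} instances={len(instances)} "
          f"hetesim={h:.4f} dwpc(w=0)={raw:.3f} dwpc(w=0.4)={damped:.3f}")

print()
print("Both routes look alike to the meeting-probability walk, but degree")
print("weighting tells them apart: the route through the 3-way hub is")
print("down-weighted (0.488 vs 0.758 at w=0.4) because every node degree")
print("along the path enters the weight as degree**(-w).")
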