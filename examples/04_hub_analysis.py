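"""Full hub network analysis: intersect, select hubs, re-target, report.

The intersection of the two target simulations yields sources tied to both
diseases; the best-connected of these become hub nodes; re-running the
simulation with each hub as target reaches concepts at graph distance 3-4
from the original targets that no depth-2 simulation could return.
"""

from lbdhub import (
    HubCriteria,
    SimulationSpec,
    cross_domain_sort,
    intersect,
    run_simulation,
    select_hubs,
    synthdata,
    top_k_by_semtype,
)

graph, truth = synthdata.generate_kg(synthdata.SyntheticConfig(seed=7))
a6 = run_simulation(graph, SimulationSpec("A6", [truth.targets[0]]))
a5 = run_simulation(graph, SimulationSpec("A5", [truth.targets[1]]))

inter = intersect([a5, a6])
print(f"A5/A6 intersection: {len(inter)} base concepts present in both")

hubs = select_hubs(inter, HubCriteria(min_percentile=50.0, n_hubs=3))
print(f"selected hubs: {hubs}")
print(f"planted hub pathway: {truth.hubs} "
      f"({'recovered' if set(hubs) == set(truth.hubs) else 'missed'})")

hub_results = [
    run_simulation(graph, SimulationSpec(f"A{i + 1}", [hub]))
    for i, hub in enumerate(hubs)
]
hub_inter = cross_domain_sort(
    intersect(hub_results, min_frequency=2),
    [r.sim_id for r in hub_results],
)

top = top_k_by_semtype(hub_inter, k=10)
deep = set()
for st, frame in top.items():
    deep |= set(frame["cui"])
found = deep & set(truth.downstream)
shallow = (set(a5.table["cui"]) | set(a6.table["cui"])) & set(truth.downstream)
print()
print(f"cross-domain top-10 per semantic type covers {len(deep)} concepts,")
print(f"of which {len(found)} are planted downstream effectors "
      f"(distance 3-4 from the targets).")
print(f"downstream effectors returned by the depth-2 target simulations: "
      f"{len(shallow)} (structurally impossible).")
print("Hub re-targeting is what extends the effective search depth.")
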