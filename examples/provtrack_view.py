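"""Build the ProvTrack node-link view and walk it.

The view is a typed tree rooted at the Experiment, assembled from several
small queries (one per component family).  Every node carries its type —
one of Entity, Agent, Activity, Step, Plan, Variable — and a sorted
key-value property list for the infobox; any node can be traced back to
the root, and both nodes and edges are searchable.
"""

from provlink import FixtureSpec, build_provtrack_view, path_to_root, search_view
from provlink.fixtures import generate_linked_store

store, experiment_id, _ = generate_linked_store(FixtureSpec(seed=1, n_cells=3, runs_per_cell=2))
view = build_provtrack_view(store, experiment_id)

by_type = {}
for node in view.nodes.values():
    by_type[node.node_type] = by_type.get(node.node_type, 0) + 1
print(f"view: {len(view.nodes)} nodes, {len(view.edges)} edges")
print("nodes by type:", dict(sorted(by_type.items())))

setting = next(i for i in view.nodes if "/setting/part-" in i)
trail = [view.nodes[i].label for i in path_to_root(view, setting)]
print("\npath from a setting back to the experiment root:")
print("  " + "  ->  ".join(trail))

hits = search_view(view, "hasSetting", scope="edges")
print(f"\nedge search for 'hasSetting': {len(hits)} edges")
hits = search_view(view, "laser", scope="nodes")
print(f"node search for 'laser': {[view.nodes[i].label for i in hits]}")
print("\nthe JSON form (view.to_json()) feeds any tree or force-directed renderer.")
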