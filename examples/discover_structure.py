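"""Recover a causal DAG from synthetic additive-noise data.

Generates 2000 samples from a known 6-node DAG (linear mechanisms,
uniform noise), then runs the structure search twice: the plain FCL
baseline (alpha = 0) and IFCL with an adjustment threshold alpha = 0.05.
"""

from ifcl import SyntheticSpec, compare_graphs, hill_climb, sample_anm

TRUE_EDGES = ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5))

spec = SyntheticSpec(n=6, m=2000, edges=TRUE_EDGES, noise="uniform", seed=42)
truth, data = sample_anm(spec)
print(f"true graph: {truth.edges()}  ({truth.n_edges} edges, m={data.m})")

for alpha in (0.0, 0.05):
    state = hill_climb(data, alpha=alpha)
    metrics = compare_graphs(state.graph, truth)
    label = "FCL baseline (alpha=0)" if alpha == 0 else f"IFCL alpha={alpha}"
    print(f"\n{label}")
    print(f"  edges:      {state.graph.edges()}")
    print(f"  total_fcl:  {state.total_fcl:.2f}   normalized: "
          f"{state.total_fcl / (data.n * data.m):.3f}")
    print(f"  SHD={metrics.shd}  redundant={metrics.redundant_edge_count}  "
          f"reversed={metrics.reversed_edge_count}")
# SHD = 0 means the estimated graph matches the generating DAG exactly;
# the adjustment threshold suppresses weakly supported (redundant) edges.
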