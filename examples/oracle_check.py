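"""Validate the greedy search against exhaustive DAG enumeration.

For a 3-node problem all 25 labelled DAGs can be scored; the greedy
hill-climber should land on the same global maximum.
"""

from ifcl import (
    MechanismCache,
    SyntheticSpec,
    enumerate_dags,
    exhaustive_search,
    hill_climb,
    sample_anm,
)

spec = SyntheticSpec(
    n=3, m=1000, edges=((0, 1), (1, 2)), coef_range=(0.9, 0.9),
    noise="uniform", noise_scale=0.5, seed=3,
)
truth, data = sample_anm(spec)
print(f"true chain: {truth.edges()};  DAGs on 3 nodes: "
      f"{sum(1 for _ in enumerate_dags(3))}")

cache = MechanismCache(data)  # shared so nothing is fitted twice
best = exhaustive_search(data, cache=cache)
state = hill_climb(data, alpha=0.0, cache=cache)

print(f"exhaustive optimum: {best.graph.edges()}  total_fcl={best.total_fcl:.2f}")
print(f"hill-climb result:  {state.graph.edges()}  total_fcl={state.total_fcl:.2f}")
print(f"greedy attains the global maximum: "
      f"{state.total_fcl >= best.total_fcl - 1e-9}")
# With strong non-Gaussian signal the penalized noise likelihood ranks
# the generating chain above all 24 alternative DAGs.
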