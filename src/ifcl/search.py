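"""Hill-climbing DAG search under the IFCL acceptance rule.

The search walks the space of DAGs by single-edge moves (add, delete,
reverse). Because the score decomposes over nodes, a move only changes
the local scores of its changed nodes ({to} for add/delete, {from, to}
for reverse). A candidate structure G* is accepted when its iteration
likelihood L_B* exceeds the running adjusted likelihood Lbar_B;
algebraically this is exactly

    sum of local-score gains over changed nodes  >  (#changed) * alpha,

so alpha acts as a per-changed-node acceptance margin: each edge change
must buy more than alpha nats of penalized likelihood per refitted node.
At alpha = 0 the rule reduces to plain FCL hill climbing. The running
total threshold alpha_k starts at n*alpha and decreases by
(#changed)*alpha at every accepted move.

An exhaustive enumeration of all labelled DAGs (practical for n <= 5)
serves as a global-optimum oracle for validating the greedy search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

from .dataio import Dataset
from .errors import CapabilityError, ConfigurationError, StructuralError
from .scoring import (
    CausalGraph,
    MechanismCache,
    ScoredStructure,
    local_score_fcl,
    score_structure,
)

__all__ = [
    "Move",
    "MoveEvaluation",
    "MoveRecord",
    "SearchState",
    "legal_moves",
    "evaluate_move",
    "accept_move",
    "hill_climb",
    "enumerate_dags",
    "exhaustive_search",
]

logger = logging.getLogger(__name__)

_KINDS = ("add", "delete", "reverse")


@dataclass(frozen=True, order=True)
class Move:
    """A single-edge operation on the current graph."""

    kind: str
    edge: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown move kind {self.kind!r}")

    @property
    def changed_nodes(self) -> tuple[int, ...]:
        u, v = self.edge
        return (u, v) if self.kind == "reverse" else (v,)

    def apply(self, graph: CausalGraph) -> CausalGraph:
        u, v = self.edge
        if self.kind == "add":
            return graph.add_edge(u, v)
        if self.kind == "delete":
            return graph.delete_edge(u, v)
        return graph.reverse_edge(u, v)


@dataclass(frozen=True)
class MoveEvaluation:
    """Outcome of scoring one candidate move."""

    move: Move
    l_b_star: float
    gain: float  # sum of local FCL gains over changed nodes
    margin: float  # gain - (#changed) * alpha; accepted iff > 0
    new_locals: tuple[tuple[int, float], ...]  # (node, new local score)


@dataclass(frozen=True)
class MoveRecord:
    kind: str
    edge: tuple[int, int]
    gain: float
    total_fcl: float


@dataclass
class SearchState:
    """Mutable state of a hill-climbing run."""

    data: Dataset
    graph: CausalGraph
    alpha: float
    cache: MechanismCache
    local_fcl: list[float]
    total_fcl: float
    threshold: float  # running total threshold alpha_k
    iteration: int = 0
    l_b_star: float = 0.0
    alpha_trace: list[float] = field(default_factory=list)
    move_log: list[MoveRecord] = field(default_factory=list)

    @classmethod
    def initial(
        cls,
        data: Dataset,
        alpha: float = 0.0,
        family: str = "linear",
        init: CausalGraph | None = None,
        cache: MechanismCache | None = None,
    ) -> "SearchState":
        if alpha < 0:
            raise ConfigurationError(f"alpha must be non-negative, got {alpha}")
        graph = init if init is not None else CausalGraph.empty(data.n)
        if not graph.is_acyclic():
            raise StructuralError("initial graph contains a cycle")
        if cache is None:
            cache = MechanismCache(data, family)
        locals_ = [
            local_score_fcl(cache.get(i, graph.parents(i)), data.m)
            for i in range(graph.n)
        ]
        state = cls(
            data=data,
            graph=graph,
            alpha=alpha,
            cache=cache,
            local_fcl=locals_,
            total_fcl=float(sum(locals_)),
            threshold=graph.n * alpha,
        )
        state.alpha_trace.append(state.threshold)
        return state

    @property
    def l_bar(self) -> float:
        """Current adjusted likelihood Lbar_B = total_fcl + alpha_k."""
        return self.total_fcl + self.threshold

    def to_structure(self, family: str | None = None) -> ScoredStructure:
        return score_structure(
            self.data, self.graph, self.alpha, family or self.cache.family, self.cache
        )


def legal_moves(
    graph: CausalGraph,
    allowed_pairs: set[frozenset[int]] | None = None,
) -> list[Move]:
    """All single-edge moves whose result is acyclic.

    Moves come in a deterministic order: lexicographic by kind
    (add < delete < reverse), then by edge. ``allowed_pairs`` restricts
    edge *additions* to the given unordered pairs (the correlation-screen
    skeleton); deletions and reversals of existing edges remain legal.
    """
    moves: list[Move] = []
    n = graph.n
    for u in range(n):
        for v in range(n):
            if u == v or graph.has_edge(u, v):
                continue
            if allowed_pairs is not None and frozenset((u, v)) not in allowed_pairs:
                continue
            if not graph.has_path(v, u):  # adding u->v keeps acyclicity
                moves.append(Move("add", (u, v)))
    for u, v in graph.edges():
        moves.append(Move("delete", (u, v)))
    for u, v in graph.edges():
        if not graph.delete_edge(u, v).has_path(u, v):
            moves.append(Move("reverse", (u, v)))
    moves.sort()
    return moves


def evaluate_move(state: SearchState, move: Move, data: Dataset) -> MoveEvaluation:
    """Score a candidate move, refitting only its changed nodes.

    Returns the iteration likelihood

        L_B* = sum_{i changed} L'_Bi(new) + sum_{i unchanged} (L'_Bi + alpha-share),

    i.e. changed nodes lose their alpha bonus while unchanged nodes keep
    it. Unchanged nodes reuse cached mechanisms.
    """
    if data is not state.data:
        raise ConfigurationError("evaluate_move must use the state's dataset")
    new_graph = move.apply(state.graph)
    changed = move.changed_nodes
    new_locals = []
    gain = 0.0
    for i in changed:
        mech = state.cache.get(i, new_graph.parents(i))
        li = local_score_fcl(mech, data.m)
        new_locals.append((i, li))
        gain += li - state.local_fcl[i]
    margin = gain - len(changed) * state.alpha
    l_b_star = state.l_bar + margin
    return MoveEvaluation(
        move=move,
        l_b_star=l_b_star,
        gain=gain,
        margin=margin,
        new_locals=tuple(new_locals),
    )


def accept_move(state: SearchState, candidate: MoveEvaluation) -> bool:
    """Apply the IFCL acceptance rule; mutate the state if accepted.

    Accepted iff L_B* > Lbar_B (strict), equivalently iff the summed
    local gain exceeds (#changed) * alpha. On acceptance the graph,
    local scores, running likelihood and total-threshold trace are
    updated so that Lbar_B becomes exactly the accepted L_B*.
    """
    state.l_b_star = candidate.l_b_star
    if not candidate.l_b_star > state.l_bar:
        return False
    state.graph = candidate.move.apply(state.graph)
    for i, li in candidate.new_locals:
        state.local_fcl[i] = li
    state.total_fcl += candidate.gain
    state.threshold -= len(candidate.move.changed_nodes) * state.alpha
    state.alpha_trace.append(state.threshold)
    state.move_log.append(
        MoveRecord(candidate.move.kind, candidate.move.edge, candidate.gain, state.total_fcl)
    )
    state.iteration += 1
    logger.info(
        "accepted %s %s: gain=%.4f total_fcl=%.4f",
        candidate.move.kind,
        candidate.move.edge,
        candidate.gain,
        state.total_fcl,
    )
    return True


def hill_climb(
    data: Dataset,
    alpha: float = 0.0,
    family: str = "linear",
    init: CausalGraph | None = None,
    seed: int | None = None,
    cache: MechanismCache | None = None,
    allowed_pairs: set[frozenset[int]] | None = None,
    max_iter: int | None = None,
) -> SearchState:
    """Greedy best-improvement search for the maximum-IFCL DAG.

    Starting from ``init`` (default: the empty graph), every legal
    single-edge move is evaluated each iteration; the move with the
    largest acceptance margin is applied if the margin is strictly
    positive (ties broken by the deterministic move ordering), and the
    search stops when no move is accepted. Each accepted move increases
    total_fcl by more than (#changed)*alpha >= 0 and total_fcl is
    bounded above for fixed data, so termination is guaranteed.

    ``seed`` is accepted for API uniformity; the search itself is fully
    deterministic given (data, alpha, family, init).
    """
    del seed  # deterministic search; kept for a uniform call signature
    state = SearchState.initial(data, alpha, family, init, cache)
    while max_iter is None or state.iteration < max_iter:
        best: MoveEvaluation | None = None
        for move in legal_moves(state.graph, allowed_pairs):
            ev = evaluate_move(state, move, data)
            if ev.margin > 0 and (best is None or ev.margin > best.margin):
                best = ev
        if best is None:
            break
        accept_move(state, best)
    return state


def enumerate_dags(n: int):
    """Yield every labelled DAG on n nodes as a CausalGraph.

    Enumerates all assignments of parent sets and keeps the acyclic
    ones (checked by Kahn elimination on bitmasks). Counts follow the
    labelled-DAG sequence 1, 3, 25, 543, 29281 for n = 1..5.
    """
    all_masks = [
        [mask for mask in range(1 << n) if not (mask >> i) & 1] for i in range(n)
    ]
    for masks in product(*all_masks):
        remaining = (1 << n) - 1
        while remaining:
            progressed = False
            for i in range(n):
                if (remaining >> i) & 1 and masks[i] & remaining == 0:
                    remaining &= ~(1 << i)
                    progressed = True
            if not progressed:
                break
        if remaining:
            continue
        yield CausalGraph(
            n,
            tuple(
                frozenset(p for p in range(n) if (masks[i] >> p) & 1)
                for i in range(n)
            ),
        )


def exhaustive_search(
    data: Dataset,
    alpha: float = 0.0,
    family: str = "linear",
    max_n: int = 5,
    cache: MechanismCache | None = None,
) -> ScoredStructure:
    """Score every DAG and return the global FCL maximizer.

    The oracle counterpart to :func:`hill_climb`, feasible only for
    small n (the number of labelled DAGs grows super-exponentially).
    Local scores are precomputed once per (node, parent set), so the
    cost is dominated by graph enumeration. Ties on the total score are
    broken lexicographically on the sorted edge list. Note alpha shifts
    every total by the same n*alpha and cannot change the maximizer.
    """
    n = data.n
    if n > max_n:
        raise CapabilityError(f"exhaustive search limited to n <= {max_n}, got {n}")
    if cache is None:
        cache = MechanismCache(data, family)
    local: list[dict[frozenset[int], float]] = []
    for i in range(n):
        others = [p for p in range(n) if p != i]
        scores: dict[frozenset[int], float] = {}
        for mask in range(1 << len(others)):
            ps = frozenset(others[k] for k in range(len(others)) if (mask >> k) & 1)
            scores[ps] = local_score_fcl(cache.get(i, ps), data.m)
        local.append(scores)
    best_graph: CausalGraph | None = None
    best_total = -float("inf")
    for graph in enumerate_dags(n):
        total = sum(local[i][graph.parents(i)] for i in range(n))
        if total > best_total or (
            total == best_total
            and best_graph is not None
            and graph.edges() < best_graph.edges()
        ):
            best_total = total
            best_graph = graph
    assert best_graph is not None
    return score_structure(data, best_graph, alpha, family, cache)
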