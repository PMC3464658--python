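"""Anchor chaining by minimum-cost flow.

Anchors are chained into t-chains: colinear anchor sequences whose two
projection intervals do not overlap and lie at most T apart. A weighted DAG
G1 is built over the anchors (vertex cost -m_a * score, where m_a is the
anchor's mean coverage; edge cost the rescaled dotplot distance
2*max(d0,d1) - min(d0,d1)), then turned into a unit-capacity transportation
network on which successive shortest paths (Busacker-Gowen) extract, per
weakly connected component, the cheapest set of vertex-disjoint chains.
Flow is increased one unit at a time until the component's chain set
satisfies the tandem conditions: each chain's projections disjoint with gap
at most T, and for every chain pair at least one of the two projection
pairs disjoint.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .anchoring import Anchor
from .seqio import Interval

logger = logging.getLogger(__name__)

_INF = float("inf")


def precedes(a: Anchor, b: Anchor) -> bool:
    """Strict successor relation on anchors (midpoint order on both axes).

    b can follow a iff they share the sign, a's first projection midpoint
    precedes b's, and the second-projection midpoints increase for sign +
    and decrease for sign - (reverse-strand chains run down the second
    axis).
    """
    if a.sign != b.sign:
        return False
    if a.a0.seq_name != b.a0.seq_name:
        return False
    if a.a0.midpoint2() >= b.a0.midpoint2():
        return False
    if a.sign == "+":
        return a.a1.midpoint2() < b.a1.midpoint2()
    return a.a1.midpoint2() > b.a1.midpoint2()


def _signed_gap(u: Interval, v: Interval) -> int:
    return v.start - u.end


def anchor_distance(a: Anchor, b: Anchor) -> int:
    """Dotplot distance between successive anchors: 2*max(d0,d1)-min(d0,d1).

    d0/d1 are the gaps between the anchors' projections in traversal order
    (for sign - the second-axis intervals are traversed in decreasing
    coordinate order). Slightly overlapping projections contribute a gap of
    0. Smaller when the facing extremities lie on the same diagonal.
    """
    if not precedes(a, b):
        raise ValueError(f"anchor {b.id} is not a successor of anchor {a.id}")
    d0 = max(0, _signed_gap(a.a0, b.a0))
    if a.sign == "+":
        d1 = max(0, _signed_gap(a.a1, b.a1))
    else:
        d1 = max(0, _signed_gap(b.a1, a.a1))
    return 2 * max(d0, d1) - min(d0, d1)


def coverage_profile(anchors: list[Anchor], seq_length: int) -> np.ndarray:
    """c(i): number of anchor intervals (either projection) covering base i."""
    prof = np.zeros(seq_length + 1, dtype=np.int64)
    for a in anchors:
        for iv in a.intervals():
            prof[iv.start] += 1
            prof[iv.end] -= 1
    return np.cumsum(prof)[:seq_length]


def mean_anchor_coverage(a: Anchor, profile: np.ndarray) -> float:
    """m_a: mean coverage over the anchor's two intervals."""
    tot = 0
    n = 0
    for iv in a.intervals():
        tot += int(profile[iv.start : iv.end].sum())
        n += iv.length()
    return tot / n


@dataclass
class Chain:
    """A t-chain: an ordered colinear run of anchors and its two projections."""

    anchors: list[Anchor]
    sign: str
    c0: Interval
    c1: Interval
    cost: float
    id: int = -1

    @classmethod
    def from_anchors(cls, anchors: list[Anchor], cost: float, id: int = -1) -> "Chain":
        name = anchors[0].a0.seq_name
        c0 = Interval(name, min(a.a0.start for a in anchors), max(a.a0.end for a in anchors))
        c1 = Interval(name, min(a.a1.start for a in anchors), max(a.a1.end for a in anchors))
        return cls(anchors=anchors, sign=anchors[0].sign, c0=c0, c1=c1, cost=cost, id=id)

    def projections(self) -> tuple[Interval, Interval]:
        return (self.c0, self.c1)

    def is_tandem(self, T: int) -> bool:
        return self.c0.end <= self.c1.start and self.c1.start - self.c0.end <= T


@dataclass
class AnchorGraph:
    """G1: anchors with coverage-weighted vertex costs and pruned,
    rescaled distance edges."""

    anchors: list[Anchor]
    vertex_cost: list[float]
    edges: dict[int, list[tuple[int, float]]]  # u -> [(v, scaled_cost)]
    raw_distance: dict[tuple[int, int], int]
    L: int
    T: int
    k: int
    scale: float


def build_anchor_graph(
    anchors: list[Anchor],
    L: int = 40_000,
    k: int = 15,
    T: int = 150_000,
    require_tandem: bool = True,
) -> AnchorGraph:
    """Build G1 over deduped tandem anchors.

    An edge (a, b) requires a ≺ b, distance(a, b) <= L and — when
    require_tandem — that the two-anchor chain is itself a t-chain (merged
    projections disjoint, gap <= T). Only the k lowest-distance out-edges of
    each vertex survive, then edge costs are rescaled so their mean equals
    the absolute value of the mean vertex cost. Reconstruction reuses the
    same graph with require_tandem=False for unit-vs-region hits, where the
    two axes are different sequences.
    """
    n = len(anchors)
    if L <= 0 or k < 1:
        raise ValueError("L must be > 0 and k >= 1")
    seq_len = 0
    for a in anchors:
        seq_len = max(seq_len, a.a0.end, a.a1.end)
    profile = coverage_profile(anchors, seq_len)
    vertex_cost = [-mean_anchor_coverage(a, profile) * a.score for a in anchors]

    # scan in midpoint order; edges only run forward in this order, and
    # distance <= L bounds how far ahead a successor's midpoint can lie
    order = sorted(range(n), key=lambda i: (anchors[i].a0.midpoint2(), anchors[i].id))
    max_len = max((a.a0.length() for a in anchors), default=0)
    window = 2 * (L + 2 * max_len)
    edges: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    raw: dict[tuple[int, int], int] = {}

    for ui in range(n):
        u = order[ui]
        a = anchors[u]
        cand: list[tuple[int, int]] = []  # (distance, v)
        for vi in range(ui + 1, n):
            v = order[vi]
            b = anchors[v]
            if b.a0.midpoint2() - a.a0.midpoint2() > window:
                break
            if not precedes(a, b):
                continue
            d = anchor_distance(a, b)
            if d > L:
                continue
            if require_tandem:
                c0e = max(a.a0.end, b.a0.end)
                c1s = min(a.a1.start, b.a1.start)
                if c0e > c1s or c1s - c0e > T:
                    continue
            cand.append((d, v))
        cand.sort()
        for d, vid in cand[:k]:
            edges[u].append((vid, float(d)))
            raw[(u, vid)] = d

    all_d = [d for _, d in raw.items()]
    mean_vc = float(np.mean(vertex_cost)) if vertex_cost else 0.0
    if all_d and float(np.mean(all_d)) > 0:
        scale = abs(mean_vc) / float(np.mean(all_d))
    else:
        scale = 1.0
        if anchors:
            logger.info("degenerate edge rescale (no edges or zero mean distance); scale=1")
    edges = {u: [(v, d * scale) for (v, d) in lst] for u, lst in edges.items()}
    return AnchorGraph(
        anchors=list(anchors),
        vertex_cost=vertex_cost,
        edges=edges,
        raw_distance=raw,
        L=L,
        T=T,
        k=k,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# consistency checks
# ---------------------------------------------------------------------------

def _pair_consistent(ci: Chain, cj: Chain) -> bool:
    """Property (5): at least one of the two projection pairs is disjoint."""
    return not (ci.c0.overlaps(cj.c0) and ci.c1.overlaps(cj.c1))


def check_chain_set(chains: list[Chain], T: int = 150_000) -> list[str]:
    """Return a description of every tandem-condition violation.

    Flags chains whose own projections overlap or are more than T apart,
    and chain pairs overlapping on both axes. An empty list means the set
    is a consistent set of t-chains.
    """
    out = []
    for c in chains:
        if c.c0.end > c.c1.start:
            out.append(f"chain {c.id}: projections overlap ({c.c0} vs {c.c1})")
        elif c.c1.start - c.c0.end > T:
            out.append(f"chain {c.id}: projection gap {c.c1.start - c.c0.end} > T={T}")
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            if not _pair_consistent(chains[i], chains[j]):
                out.append(
                    f"chains {chains[i].id},{chains[j].id}: both projection pairs overlap"
                )
    return out


# ---------------------------------------------------------------------------
# successive shortest path min-cost flow
# ---------------------------------------------------------------------------

class _FlowNetwork:
    """Unit-capacity transportation network over one component of G1.

    Every anchor splits into (in, out) joined by a unit-capacity arc
    carrying the vertex cost, so any integral flow of value i decomposes
    into i vertex-disjoint source->sink paths.
    """

    def __init__(self, node_ids: list[int], graph: AnchorGraph):
        self.node_ids = node_ids  # anchor indices of this component, topological
        self.graph = graph
        idx = {aid: t for t, aid in enumerate(node_ids)}
        n = len(node_ids)
        self.n_nodes = 2 * n + 2
        self.source = 2 * n
        self.sink = 2 * n + 1
        self.head: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.to: list[int] = []
        self.cap: list[int] = []
        self.cost: list[float] = []
        for t, aid in enumerate(node_ids):
            self._add(self.source, 2 * t, 0.0)
            self._add(2 * t, 2 * t + 1, graph.vertex_cost[aid])
            self._add(2 * t + 1, self.sink, 0.0)
        for t, aid in enumerate(node_ids):
            for v, c in graph.edges[aid]:
                if v in idx:
                    self._add(2 * t + 1, 2 * idx[v], c)

    def _add(self, u: int, v: int, cost: float):
        self.head[u].append(len(self.to))
        self.to.append(v)
        self.cap.append(1)
        self.cost.append(cost)
        self.head[v].append(len(self.to))
        self.to.append(u)
        self.cap.append(0)
        self.cost.append(-cost)

    def initial_potentials(self) -> list[float]:
        """Exact shortest distances on the acyclic base network, by
        relaxation in topological order (node_ids are topological w.r.t. ≺)."""
        dist = [_INF] * self.n_nodes
        dist[self.source] = 0.0
        node_order = [self.source]
        for t in range(len(self.node_ids)):
            node_order.extend((2 * t, 2 * t + 1))
        node_order.append(self.sink)
        for u in node_order:
            if dist[u] == _INF:
                continue
            for e in self.head[u]:
                if self.cap[e] > 0:
                    v = self.to[e]
                    nd = dist[u] + self.cost[e]
                    if nd < dist[v]:
                        dist[v] = nd
        return dist

    def shortest_path(self, pot: list[float]):
        """Dijkstra with reduced costs; returns (dist, parent_arc) or None."""
        dist = [_INF] * self.n_nodes
        parent = [-1] * self.n_nodes
        dist[self.source] = 0.0
        pq = [(0.0, self.source)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist[u] + 1e-12:
                continue
            for e in self.head[u]:
                if self.cap[e] <= 0:
                    continue
                v = self.to[e]
                rc = self.cost[e] + pot[u] - pot[v]
                nd = d + rc
                if nd < dist[v] - 1e-12:
                    dist[v] = nd
                    parent[v] = e
                    heapq.heappush(pq, (nd, v))
        if dist[self.sink] == _INF:
            return None
        return dist, parent

    def augment(self, parent: list[int]) -> float:
        """Push one unit along the parent-arc path; returns its real cost."""
        cost = 0.0
        v = self.sink
        while v != self.source:
            e = parent[v]
            self.cap[e] -= 1
            self.cap[e ^ 1] += 1
            cost += self.cost[e]
            v = self.to[e ^ 1]
        return cost

    def decompose(self) -> list[list[int]]:
        """Decompose the current flow into anchor-id paths (unique because
        of unit capacities)."""
        paths = []
        for e in self.head[self.source]:
            if e % 2 == 0 and self.cap[e] == 0:  # saturated forward source arc
                path = []
                u = self.to[e]
                while u != self.sink:
                    if u % 2 == 0:  # an in-node: record its anchor
                        path.append(self.node_ids[u // 2])
                    nxt = None
                    for e2 in self.head[u]:
                        if e2 % 2 == 0 and self.cap[e2] == 0 and self.to[e2 ^ 1] == u:
                            nxt = self.to[e2]
                            break
                    u = nxt
                paths.append(path)
        paths.sort(key=lambda p: p[0])
        return paths


@dataclass
class ChainingResult:
    chains: list[Chain]
    residual_anchors: list[Anchor]
    flow_values: dict[int, int] = field(default_factory=dict)  # component -> flow
    augmentation_costs: dict[int, list[float]] = field(default_factory=dict)
    dropped_chains: int = 0


def _path_cost(path: list[int], graph: AnchorGraph) -> float:
    cost = sum(graph.vertex_cost[a] for a in path)
    for u, v in zip(path, path[1:]):
        cost += dict(graph.edges[u])[v]
    return cost


def _components(graph: AnchorGraph) -> list[list[int]]:
    """Weakly connected components of G1, each topologically sorted."""
    n = len(graph.anchors)
    adj: list[set[int]] = [set() for _ in range(n)]
    for u, lst in graph.edges.items():
        for v, _ in lst:
            adj[u].add(v)
            adj[v].add(u)
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack = [s]
        seen[s] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comp.sort(key=lambda i: (graph.anchors[i].a0.midpoint2(), i))
        comps.append(comp)
    comps.sort(key=lambda c: c[0])
    return comps


def _greedy_consistent(cands: list[tuple[Chain, list[int]]], pair_check):
    """Keep a pairwise-consistent subset, preferring the cheapest chains."""
    cands = sorted(cands, key=lambda cp: (cp[0].cost, cp[0].c0.start, cp[0].c1.start))
    kept: list[tuple[Chain, list[int]]] = []
    for c, p in cands:
        if all(pair_check(c, kc) for kc, _ in kept):
            kept.append((c, p))
    return kept


def _schedule_pool(pool: dict[tuple, Chain], pair_check) -> list[list[int]]:
    """Maximum-weight set of disjoint candidate chains along the second axis.

    Classic weighted interval scheduling on the chains' second projections,
    with weight |cost| (every candidate has negative cost, so heavier
    chains carry more anchors/score); chains sharing an anchor necessarily
    overlap there, so the result is vertex-disjoint. `pair_check` is
    re-applied as a safety net for non-interval consistency notions.
    """
    items = sorted(
        ((c.c1.start, c.c1.end, -c.cost, p, c) for p, c in pool.items()),
        key=lambda t: (t[1], t[0], -t[2], t[3]),
    )
    n = len(items)
    if n == 0:
        return []
    import bisect

    ends = [it[1] for it in items]
    dp = [0.0] * (n + 1)
    take = [False] * (n + 1)
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        s, e, w, p, c = items[i - 1]
        j = bisect.bisect_right(ends, s, 0, i - 1)  # last item ending <= start
        prev[i] = j
        if dp[j] + w > dp[i - 1] + 1e-9:
            dp[i] = dp[j] + w
            take[i] = True
        else:
            dp[i] = dp[i - 1]
    chosen = []
    i = n
    while i > 0:
        if take[i]:
            chosen.append(items[i - 1])
            i = prev[i]
        else:
            i -= 1
    chosen.reverse()
    kept: list[tuple[Chain, tuple]] = []
    for s, e, w, p, c in chosen:
        if all(pair_check(c, kc) for kc, _ in kept):
            kept.append((c, p))
    return [list(p) for _, p in kept]


def min_cost_flow_chains(
    graph: AnchorGraph,
    chain_check=None,
    pair_check=_pair_consistent,
    mode: str = "first_consistent",
) -> ChainingResult:
    """Extract an optimal consistent chain set from G1 (or G3).

    Runs Busacker-Gowen successive shortest paths independently on every
    weakly connected component, raising that component's flow by one unit
    per iteration.

    mode="first_consistent" (G1): at each flow value the decomposed chain
    set is tested (per chain: t-chain conditions; per pair: property (5))
    and the first consistent value is kept. At maximum flow all chains are
    single anchors, which guarantees termination.

    mode="max_valid" (G3): the flow runs to completion; every chain that
    passes `chain_check` in any flow value's decomposition joins a
    candidate pool, and the returned set is the maximum-total-score subset
    of the pool that is disjoint along the second projection (weighted
    interval scheduling). This suits the unit re-search, where every copy of
    the unit should yield one chain and an unchained hit is a lost copy
    rather than a residual; the consistency there is disjointness along
    the region, so chains kept together never share a hit.

    A final global sweep resolves any remaining cross-component
    property-(5) violations by dropping the chain with the smaller |cost|
    (a no-op for deduped anchor sets).
    """
    T = graph.T
    if chain_check is None:
        chain_check = lambda c: c.is_tandem(T)
    if mode not in ("first_consistent", "max_valid"):
        raise ValueError(f"unknown mode {mode!r}")
    result = ChainingResult(chains=[], residual_anchors=[])
    chains: list[tuple[Chain, list[int]]] = []  # chain + anchor list-indices
    for ci, comp in enumerate(_components(graph)):
        if len(comp) == 1:
            aid = comp[0]
            c = Chain.from_anchors([graph.anchors[aid]], graph.vertex_cost[aid])
            path_set = [[aid]] if (mode == "first_consistent" or chain_check(c)) else []
            result.flow_values[ci] = 1
            result.augmentation_costs[ci] = [graph.vertex_cost[aid]]
        else:
            net = _FlowNetwork(comp, graph)
            pot = net.initial_potentials()
            costs: list[float] = []
            path_set: list[list[int]] = []
            pool: dict[tuple, Chain] = {}
            max_flow = len(comp)
            flow = 0
            while flow < max_flow:
                sp = net.shortest_path(pot)
                if sp is None:
                    break
                dist, parent = sp
                for v in range(net.n_nodes):
                    if dist[v] < _INF:
                        pot[v] += dist[v]
                costs.append(net.augment(parent))
                flow += 1
                decomp = net.decompose()
                cand = [
                    (Chain.from_anchors([graph.anchors[a] for a in p], _path_cost(p, graph)), p)
                    for p in decomp
                ]
                if mode == "first_consistent":
                    path_set = decomp
                    ok = all(chain_check(c) for c, _ in cand) and all(
                        pair_check(cand[i][0], cand[j][0])
                        for i in range(len(cand))
                        for j in range(i + 1, len(cand))
                    )
                    if ok:
                        break
                else:
                    for c, p in cand:
                        if chain_check(c):
                            pool.setdefault(tuple(p), c)
            if mode == "max_valid":
                path_set = _schedule_pool(pool, pair_check)
            result.flow_values[ci] = flow
            result.augmentation_costs[ci] = costs
        for p in path_set:
            c = Chain.from_anchors([graph.anchors[a] for a in p], _path_cost(p, graph))
            chains.append((c, p))

    # global property-(5) sweep across components
    chains.sort(key=lambda cp: (cp[0].cost, cp[0].c0.start, cp[0].c1.start))
    kept: list[tuple[Chain, list[int]]] = []
    for c, p in chains:
        if all(pair_check(c, kc) for kc, _ in kept):
            kept.append((c, p))
        else:
            result.dropped_chains += 1
    kept.sort(key=lambda cp: (cp[0].c0.start, cp[0].c0.end, cp[0].c1.start))
    in_chain: set[int] = set()
    for i, (c, p) in enumerate(kept):
        c.id = i
        in_chain.update(p)
    result.chains = [c for c, _ in kept]
    result.residual_anchors = [
        a for i, a in enumerate(graph.anchors) if i not in in_chain
    ]
    if result.dropped_chains:
        logger.info("dropped %d chains in global consistency sweep", result.dropped_chains)
    return result


def chain_anchors(
    anchors: list[Anchor],
    L: int = 40_000,
    k: int = 15,
    T: int = 150_000,
) -> ChainingResult:
    """Convenience wrapper: build G1 and run the flow chainer."""
    if not anchors:
        return ChainingResult(chains=[], residual_anchors=[])
    graph = build_anchor_graph(anchors, L=L, k=k, T=T)
    return min_cost_flow_chains(graph)
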