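"""Shared test utilities: random-instance generators and brute-force oracles.

The chaining oracle enumerates every set of vertex-disjoint paths of a given
cardinality over the pruned anchor graph and minimizes the summed path cost
— fully independent of the flow implementation it checks.
"""

from __future__ import annotations

import random

import numpy as np

from tandemdup.anchoring import Anchor
from tandemdup.chaining import AnchorGraph, _path_cost
from tandemdup.seqio import GenomeSequence, Interval

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def random_tandem_anchors(rnd: random.Random, max_anchors: int = 8) -> list[Anchor]:
    """Random valid tandem anchors with no pair overlapping on both axes.

    Mirrors the documented precondition of the flow chainer (deduped
    anchors): property (5) must be satisfiable by the max-flow fallback.
    """
    while True:
        m = rnd.randint(2, max_anchors)
        anchors = []
        for i in range(m):
            s0 = rnd.randint(0, 3000)
            l0 = rnd.randint(50, 200)
            gap = rnd.randint(0, 800)
            l1 = rnd.randint(50, 200)
            a0 = Interval("s", s0, s0 + l0)
            a1 = Interval("s", s0 + l0 + gap, s0 + l0 + gap + l1)
            sign = "+" if rnd.random() < 0.8 else "-"
            anchors.append(Anchor(a0=a0, a1=a1, sign=sign, score=rnd.randint(20, 120), id=i))
        ok = True
        for i in range(m):
            for j in range(i + 1, m):
                a, b = anchors[i], anchors[j]
                if a.a0.overlaps(b.a0) and a.a1.overlaps(b.a1):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return anchors


def random_connected_instance(
    rnd: random.Random, L: int = 1500, k: int = 3, T: int = 3000, max_anchors: int = 8
):
    """A random instance whose pruned anchor graph is weakly connected.

    Connectivity keeps the flow refinement loop responsible for the whole
    chain set, so its post-stopping cost is directly comparable to the
    exhaustive enumeration (no cross-component interactions).
    """
    from tandemdup.chaining import _components, build_anchor_graph

    while True:
        anchors = random_tandem_anchors(rnd, max_anchors)
        graph = build_anchor_graph(anchors, L=L, k=k, T=T)
        if len(_components(graph)) == 1:
            return anchors, graph


def enumerate_paths(graph: AnchorGraph, comp: list[int]) -> list[list[int]]:
    """Every simple path over the pruned edge set within one component."""
    comp_set = set(comp)
    succ = {u: [v for v, _ in graph.edges[u] if v in comp_set] for u in comp}
    paths: list[list[int]] = []

    def dfs(path: list[int]):
        paths.append(list(path))
        for v in succ[path[-1]]:
            path.append(v)
            dfs(path)
            path.pop()

    for s in comp:
        dfs([s])
    return paths


def brute_min_cost_disjoint(graph: AnchorGraph, comp: list[int], k: int) -> float:
    """Minimum total cost over all sets of k vertex-disjoint paths in comp."""
    paths = enumerate_paths(graph, comp)
    costs = [_path_cost(p, graph) for p in paths]
    sets = [frozenset(p) for p in paths]
    best = [float("inf")]

    def rec(idx: int, left: int, used: frozenset, acc: float):
        if left == 0:
            best[0] = min(best[0], acc)
            return
        if len(paths) - idx < left:
            return
        for j in range(idx, len(paths)):
            if used & sets[j]:
                continue
            rec(j + 1, left - 1, used | sets[j], acc + costs[j])

    rec(0, k, frozenset(), 0.0)
    return best[0]
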