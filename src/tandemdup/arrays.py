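"""Tandem array delineation and reference-unit extraction.

Chains and residual anchors that overlap sufficiently on either projection
axis belong to the same duplication event; the connected components of this
overlap graph (G2) define the tandem arrays. Each array's reference
duplication unit starts from the longest projection of its minimum-cost
chain and is trimmed until less than half of the candidate is self-similar,
so that a candidate spanning several copies converges to a single copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .anchoring import Anchor, ScoringScheme, find_anchors
from .chaining import Chain
from .seqio import GenomeSequence, Interval, overlap_fraction

logger = logging.getLogger(__name__)


@dataclass
class DuplicationUnit:
    """The minimal repeated sequence of an array."""

    interval: Interval
    residues: str
    source_chain: int  # chain id, or -1 for residual-anchor candidates
    unresolved: bool = False


@dataclass
class TandemArray:
    """A genomic region holding several copies of one duplication unit."""

    id: str
    region: Interval
    member_chains: list[Chain] = field(default_factory=list)
    member_anchors: list[Anchor] = field(default_factory=list)
    reference_unit: DuplicationUnit | None = None
    units: list = field(default_factory=list)  # TandemUnit, filled by reconstruction
    flags: set[str] = field(default_factory=set)

    def member_projections(self) -> list[Interval]:
        ivs = []
        for c in self.member_chains:
            ivs.extend(c.projections())
        for a in self.member_anchors:
            ivs.extend(a.intervals())
        return ivs


def build_overlap_graph(
    chains: list[Chain],
    residual_anchors: list[Anchor],
    min_overlap: float = 0.5,
) -> nx.Graph:
    """G2: vertices are chains and residual anchors; an edge joins two
    vertices when any projection of one overlaps any projection of the
    other by at least `min_overlap` of the smaller interval."""
    g = nx.Graph()
    items: list[tuple[tuple[str, int], list[Interval]]] = []
    for i, c in enumerate(chains):
        items.append((("c", i), list(c.projections())))
    for i, a in enumerate(residual_anchors):
        items.append((("a", i), list(a.intervals())))
    for node, ivs in items:
        g.add_node(node, projections=ivs)
    # sweep by interval start to avoid the full quadratic comparison
    flat = []
    for node, ivs in items:
        for iv in ivs:
            flat.append((iv.seq_name, iv.start, iv.end, node, iv))
    flat.sort(key=lambda t: (t[0], t[1], t[2]))
    active: list[tuple[str, int, int, tuple, Interval]] = []
    for rec in flat:
        seq, start, end, node, iv = rec
        active = [r for r in active if r[0] == seq and r[2] > start]
        for _, _, _, onode, oiv in active:
            if onode == node or g.has_edge(node, onode):
                continue
            if overlap_fraction(iv, oiv, "smaller") >= min_overlap:
                g.add_edge(node, onode)
        active.append(rec)
    return g


def delineate_arrays(
    graph: nx.Graph,
    L: int,
    seq: GenomeSequence,
    chains: list[Chain] | None = None,
    residual_anchors: list[Anchor] | None = None,
) -> list[TandemArray]:
    """One tandem array per connected component of G2.

    The array region is the smallest interval encompassing every member
    projection, enlarged by L on each side and clamped to the sequence.
    """
    chains = chains or []
    residual_anchors = residual_anchors or []
    arrays = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for comp in comps:
        ivs: list[Interval] = []
        member_chains: list[Chain] = []
        member_anchors: list[Anchor] = []
        for kind, idx in comp:
            if kind == "c":
                member_chains.append(chains[idx])
                ivs.extend(chains[idx].projections())
            else:
                member_anchors.append(residual_anchors[idx])
                ivs.extend(residual_anchors[idx].intervals())
        if len(ivs) < 2:
            continue
        start = min(iv.start for iv in ivs)
        end = max(iv.end for iv in ivs)
        region = Interval(seq.name, max(0, start - L), min(seq.length, end + L))
        member_chains.sort(key=lambda c: c.id)
        member_anchors.sort(key=lambda a: (a.a0.start, a.a1.start))
        ta = TandemArray(
            id="",
            region=region,
            member_chains=member_chains,
            member_anchors=member_anchors,
        )
        if not member_chains:
            ta.flags.add("anchors_only")
        arrays.append(ta)
    arrays.sort(key=lambda t: (t.region.seq_name, t.region.start, t.region.end))
    for i, ta in enumerate(arrays):
        ta.id = f"ta_{i:05d}"
    return arrays


def _self_hsps(residues: str, scheme: ScoringScheme) -> list[Anchor]:
    """Off-diagonal local self-alignments of a candidate unit."""
    seq = GenomeSequence("unit", residues)
    return find_anchors(seq, scheme, T=len(residues))


def self_similar_fraction(
    unit_residues: str, scheme: ScoringScheme | None = None, hsps: list[Anchor] | None = None
) -> float:
    """Fraction of candidate positions covered by off-diagonal self-alignments."""
    if not unit_residues:
        raise ValueError("empty candidate unit")
    scheme = scheme or ScoringScheme()
    if hsps is None:
        hsps = _self_hsps(unit_residues, scheme)
    if not hsps:
        return 0.0
    covered = [False] * len(unit_residues)
    for a in hsps:
        for iv in a.intervals():
            for i in range(iv.start, min(iv.end, len(covered))):
                covered[i] = True
    return sum(covered) / len(covered)


def _head_tail_duplication(
    hsps: list[Anchor], length: int, min_unit_length: int
) -> tuple[int, int] | None:
    """Aligned head of a candidate whose head re-occurs at its tail.

    Looks for the best-scoring HSP whose first interval starts within
    `eps` of the left extremity and whose second ends within `eps` of the
    right one: such a candidate still contains a whole internal
    duplication, and the HSP's first interval delimits one copy of it.
    Returns that interval in candidate-local coordinates, or None.
    """
    eps = max(100, int(0.05 * length))
    best = None
    for h in hsps:
        if h.a0.start <= eps and h.a1.end >= length - eps:
            if h.a0.length() >= min_unit_length and h.a0.length() < length - eps:
                if best is None or h.score > best[1]:
                    best = ((h.a0.start, h.a0.end), h.score)
    return best[0] if best else None


def select_reference_unit(
    array: TandemArray,
    seq: GenomeSequence,
    scheme: ScoringScheme | None = None,
    min_unit_length: int = 500,
) -> DuplicationUnit:
    """Pick and trim the reference duplication unit of an array.

    The candidate is the longest projection of the minimum-cost chain
    (cost ties broken by projection length, then chain id); arrays with no
    chains fall back to the longest residual-anchor interval.

    Two reductions alternate until the candidate is stable. First, a
    candidate whose head re-occurs at its tail (a self-HSP running from one
    extremity to the other) still contains a whole internal duplication —
    a tandem of 2k copies reads as k doubled copies — and is cut down to
    the HSP's own head interval, i.e. one copy of that duplication; this
    also phase-aligns the unit with the copy starts when copies are
    separated by spacers. Second, while at least half the candidate is
    self-similar, the
    candidate is trimmed past the inner boundary of the lowest-scoring HSP
    on whichever side lies closer to that HSP, which removes at least one
    copy per iteration. If trimming would shrink below the minimum unit
    length, the untrimmed candidate is kept and flagged unresolved.
    """
    scheme = scheme or ScoringScheme()
    if not array.member_chains and not array.member_anchors:
        raise ValueError(f"array {array.id} has no members")
    if array.member_chains:
        best = min(
            array.member_chains,
            key=lambda c: (c.cost, -max(c.c0.length(), c.c1.length()), c.id),
        )
        candidate = max(best.projections(), key=lambda iv: iv.length())
        source = best.id
    else:
        candidate = max(
            (iv for a in array.member_anchors for iv in a.intervals()),
            key=lambda iv: (iv.length(), -iv.start),
        )
        source = -1
    original = candidate
    while True:
        residues = seq.subsequence(candidate)
        hsps = _self_hsps(residues, scheme)
        frac = self_similar_fraction(residues, scheme, hsps=hsps)
        head = _head_tail_duplication(hsps, len(residues), min_unit_length)
        if head is not None:
            candidate = Interval(
                candidate.seq_name, candidate.start + head[0], candidate.start + head[1]
            )
            continue
        if frac < 0.5:
            return DuplicationUnit(interval=candidate, residues=residues, source_chain=source)
        worst = min(hsps, key=lambda a: (a.score, a.a0.start))
        d_left = worst.a0.start
        d_right = len(residues) - worst.a1.end
        if d_left <= d_right:
            new = (candidate.start + worst.a0.end, candidate.end)
        else:
            new = (candidate.start, candidate.start + worst.a1.start)
        if new[1] - new[0] < min_unit_length or new[1] - new[0] >= candidate.length():
            logger.info("array %s: unit trimming failed, keeping untrimmed candidate", array.id)
            return DuplicationUnit(
                interval=original,
                residues=seq.subsequence(original),
                source_chain=source,
                unresolved=True,
            )
        candidate = Interval(candidate.seq_name, new[0], new[1])
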