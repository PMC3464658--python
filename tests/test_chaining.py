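import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemdup.anchoring import Anchor
from tandemdup.chaining import (
    Chain,
    anchor_distance,
    build_anchor_graph,
    chain_anchors,
    check_chain_set,
    coverage_profile,
    mean_anchor_coverage,
    min_cost_flow_chains,
    precedes,
)
from tandemdup.seqio import Interval

from .helpers import random_tandem_anchors


def mk(a0, a1, sign="+", score=50, id=0):
    return Anchor(a0=Interval("s", *a0), a1=Interval("s", *a1), sign=sign, score=score, id=id)


def colinear_run(start, n, length=100, gap=50, offset=2000, score=50, id0=0):
    """n colinear anchors stepping along one diagonal."""
    out = []
    p = start
    for i in range(n):
        out.append(mk((p, p + length), (p + offset, p + offset + length), score=score, id=id0 + i))
        p += length + gap
    return out


class TestPrecedes:
    def test_plus_strand_ordered(self):
        a = mk((50, 150), (1050, 1150), id=0)
        b = mk((450, 550), (1450, 1550), id=1)
        assert precedes(a, b) and not precedes(b, a)

    def test_signs_must_match(self):
        a = mk((50, 150), (1050, 1150), sign="+")
        b = mk((450, 550), (1450, 1550), sign="-")
        assert not precedes(a, b) and not precedes(b, a)

    def test_minus_strand_requires_decreasing_second_axis(self):
        a = mk((50, 150), (1050, 1150), sign="-")
        b = mk((450, 550), (1450, 1550), sign="-")
        assert not precedes(a, b)
        b2 = mk((450, 550), (650, 750), sign="-")
        assert precedes(a, b2)

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strict_partial_order_axioms(self, data):
        def anchor():
            s0 = data.draw(st.integers(0, 500))
            l0 = data.draw(st.integers(10, 100))
            g = data.draw(st.integers(0, 200))
            l1 = data.draw(st.integers(10, 100))
            sign = data.draw(st.sampled_from("+-"))
            return mk((s0, s0 + l0), (s0 + l0 + g, s0 + l0 + g + l1), sign=sign)

        a, b, c = anchor(), anchor(), anchor()
        assert not precedes(a, a)  # irreflexive
        if precedes(a, b):
            assert not precedes(b, a)  # antisymmetric
        if precedes(a, b) and precedes(b, c):
            assert precedes(a, c)  # transitive


class TestAnchorDistance:
    @pytest.mark.parametrize(
        "d0, d1, expected",
        [(1000, 1000, 1000), (500, 1500, 2500), (0, 0, 0), (0, 150_000, 300_000), (150_000, 0, 300_000)],
    )
    def test_closed_form(self, d0, d1, expected):
        a = mk((0, 100), (300_000, 300_100))
        b = mk((100 + d0, 200 + d0), (300_100 + d1, 300_200 + d1))
        assert anchor_distance(a, b) == expected

    def test_rejects_non_successor(self):
        a = mk((0, 100), (300, 400))
        b = mk((0, 100), (300, 400))
        with pytest.raises(ValueError):
            anchor_distance(a, b)

    def test_minus_strand_gap_measured_in_traversal_order(self):
        a = mk((0, 100), (2000, 2100), sign="-")
        b = mk((200, 300), (1500, 1600), sign="-")
        # d0 = 100, d1 = 2000 - 1600 = 400
        assert anchor_distance(a, b) == 2 * 400 - 100


class TestCoverage:
    def test_single_anchor_unit_coverage(self):
        a = mk((10, 20), (30, 40))
        prof = coverage_profile([a], 100)
        assert prof[10:20].tolist() == [1] * 10
        assert prof[30:40].tolist() == [1] * 10
        assert prof.sum() == 20
        assert mean_anchor_coverage(a, prof) == 1.0

    def test_shared_interval_counts_twice(self):
        a = mk((10, 20), (30, 40), id=0)
        b = mk((10, 20), (50, 60), id=1)
        prof = coverage_profile([a, b], 100)
        assert prof[10:20].tolist() == [2] * 10
        assert mean_anchor_coverage(a, prof) == pytest.approx((20 + 10) / 20)

    def test_matches_bruteforce_recount(self):
        rnd = random.Random(5)
        anchors = random_tandem_anchors(rnd, max_anchors=8)
        anchors = anchors * 1
        length = max(a.a1.end for a in anchors) + 1
        prof = coverage_profile(anchors, length)
        brute = np.zeros(length)
        for a in anchors:
            for iv in a.intervals():
                brute[iv.start : iv.end] += 1
        assert np.array_equal(prof, brute)
        for a in anchors:
            expect = np.concatenate([brute[a.a0.start : a.a0.end], brute[a.a1.start : a.a1.end]]).mean()
            assert mean_anchor_coverage(a, prof) == pytest.approx(expect)


class TestBuildGraph:
    def test_distance_threshold_prunes_edges(self):
        anchors = colinear_run(0, 3, gap=10)
        # distances between consecutive anchors are small; make third far
        far = mk((5000, 5100), (7000, 7100), id=3)
        g = build_anchor_graph(anchors + [far], L=500, k=15, T=150_000)
        assert all(v != 3 for lst in (g.edges[i] for i in range(3)) for v, _ in lst)

    def test_out_degree_capped_at_k(self):
        anchors = [mk((0, 100), (3000, 3100), id=0)]
        for i in range(20):
            p = 200 + i * 120
            anchors.append(mk((p, p + 100), (3200 + i * 120, 3300 + i * 120), id=i + 1))
        g = build_anchor_graph(anchors, L=40_000, k=15, T=150_000)
        assert len(g.edges[0]) == 15
        dists = sorted(g.raw_distance[(0, v)] for v, _ in g.edges[0])
        all_d = sorted(
            anchor_distance(anchors[0], b)
            for b in anchors[1:]
            if precedes(anchors[0], b)
        )
        assert dists == all_d[:15]

    def test_edge_rescaling_matches_mean_vertex_cost(self):
        anchors = colinear_run(0, 5, gap=80)
        g = build_anchor_graph(anchors, L=40_000, k=15, T=150_000)
        mean_vc = np.mean(g.vertex_cost)
        scaled = [c for lst in g.edges.values() for _, c in lst]
        assert np.mean(scaled) == pytest.approx(abs(mean_vc))


class TestFlowChains:
    def test_two_disjoint_runs_reproduced(self):
        a_run = colinear_run(0, 3, id0=0)
        b_run = colinear_run(10_000, 3, id0=3)
        res = chain_anchors(a_run + b_run, L=2000, k=5, T=150_000)
        got = sorted(tuple(a.id for a in c.anchors) for c in res.chains)
        assert got == [(0, 1, 2), (3, 4, 5)]
        assert res.residual_anchors == []
        assert check_chain_set(res.chains) == []

    def test_single_anchor_chain(self):
        a = mk((0, 100), (300, 400))
        res = chain_anchors([a])
        assert len(res.chains) == 1
        assert res.chains[0].anchors == [a]
        assert res.chains[0].cost == pytest.approx(-50.0)

    def test_diagonal_crossing_run_is_split(self):
        # anchors chaining into a self-overlapping projection must be split
        # into consistent t-chains rather than returned as one chain
        anchors = [
            mk((0, 500), (1000, 1500), id=0),
            mk((1000, 1500), (2000, 2500), id=1),
            mk((2000, 2500), (3000, 3500), id=2),
        ]
        res = chain_anchors(anchors, L=40_000, k=5, T=150_000)
        assert check_chain_set(res.chains) == []
        assert all(c.c0.end <= c.c1.start for c in res.chains)

    def test_empty_input(self):
        res = chain_anchors([])
        assert res.chains == [] and res.residual_anchors == []

    def test_anchor_conservation(self):
        rnd = random.Random(99)
        for _ in range(20):
            anchors = random_tandem_anchors(rnd)
            res = chain_anchors(anchors, L=1500, k=3, T=3000)
            seen = [a.id for c in res.chains for a in c.anchors] + [
                a.id for a in res.residual_anchors
            ]
            assert sorted(seen) == sorted(a.id for a in anchors)
            assert len(set(a.id for c in res.chains for a in c.anchors)) == sum(
                len(c.anchors) for c in res.chains
            )

    def test_augmentation_costs_convex(self):
        rnd = random.Random(7)
        for _ in range(20):
            anchors = random_tandem_anchors(rnd)
            g = build_anchor_graph(anchors, L=1500, k=3, T=3000)
            res = min_cost_flow_chains(g)
            for costs in res.augmentation_costs.values():
                assert all(b >= a - 1e-6 for a, b in zip(costs, costs[1:]))


class TestCheckChainSet:
    def _chain(self, c0, c1, id=0):
        a = mk((c0[0], c0[1]), (c1[0], c1[1]))
        c = Chain.from_anchors([a], -1.0, id=id)
        return c

    def test_projection_overlap_flagged(self):
        # the dotplot square touching the main diagonal: c0 meets c1
        bad = Chain(
            anchors=[mk((0, 500), (400, 900))],
            sign="+",
            c0=Interval("s", 0, 500),
            c1=Interval("s", 400, 900),
            cost=-1.0,
            id=0,
        )
        out = check_chain_set([bad])
        assert len(out) == 1 and "overlap" in out[0]

    def test_gap_beyond_T_flagged(self):
        c = self._chain((0, 100), (200_000, 200_100))
        assert check_chain_set([c], T=150_000)
        assert not check_chain_set([c], T=300_000)

    def test_single_axis_overlap_is_consistent(self):
        c1 = self._chain((0, 100), (1000, 1100), id=0)
        c2 = self._chain((50, 150), (2000, 2100), id=1)
        assert check_chain_set([c1, c2]) == []

    def test_both_axis_overlap_flagged(self):
        c1 = self._chain((0, 100), (1000, 1100), id=0)
        c2 = self._chain((50, 150), (1050, 1150), id=1)
        out = check_chain_set([c1, c2])
        assert len(out) == 1 and "both projection pairs" in out[0]
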