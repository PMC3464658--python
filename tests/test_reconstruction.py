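import numpy as np
import pytest

from tandemdup.anchoring import ScoringScheme
from tandemdup.arrays import DuplicationUnit, TandemArray
from tandemdup.reconstruction import (
    TandemUnit,
    chain_unit_hits,
    enlarge_units,
    reconstruct_array,
    search_unit,
)
from tandemdup.seqio import GenomeSequence, Interval
from tandemdup.simulation import SimParams, _mutate

from .helpers import random_dna


def _unit(residues):
    return DuplicationUnit(
        interval=Interval("u", 0, len(residues)), residues=residues, source_chain=0
    )


def _cluster_count(hits, positions, unit_len):
    """How many planted positions are covered >= 50% by some hit."""
    n = 0
    for s, e in positions:
        cov = np.zeros(e - s, dtype=bool)
        for h in hits:
            lo, hi = max(h.a1.start, s), min(h.a1.end, e)
            if lo < hi:
                cov[lo - s : hi - s] = True
        if cov.mean() >= 0.5:
            n += 1
    return n


class TestSearchUnit:
    def test_three_diverged_copies_found(self, rng):
        unit = random_dna(rng, 900)
        params = SimParams(substitution_rate=0.02, indel_rate=0.0, seed=0)
        pieces, positions = [], []
        pieces.append(random_dna(rng, 1000))
        pos = 1000
        for _ in range(3):
            mut, _ = _mutate(rng, unit, params)
            positions.append((pos, pos + len(mut)))
            pieces.append(mut)
            pos += len(mut)
            sp = random_dna(rng, 500)
            pieces.append(sp)
            pos += 500
        region = "".join(pieces)
        hits = search_unit(_unit(unit), region, mode="translated")
        assert _cluster_count(hits, positions, 900) == 3

    def test_random_region_no_covering_hit(self, rng):
        unit = random_dna(rng, 900)
        region = random_dna(rng, 20_000)
        hits = search_unit(_unit(unit), region, mode="translated")
        assert all(h.a0.length() < 450 for h in hits)

    def test_translated_and_nucleotide_modes_agree_on_exact_copies(self, rng):
        unit = random_dna(rng, 900)
        region = random_dna(rng, 500) + unit + random_dna(rng, 400) + unit + random_dna(rng, 600)
        ht = search_unit(_unit(unit), region, mode="translated")
        hn = search_unit(_unit(unit), region, mode="nucleotide")
        big_t = sorted((h.a1.start, h.a1.end) for h in ht if h.a0.length() >= 450)
        big_n = sorted((h.a1.start, h.a1.end) for h in hn if h.a0.length() >= 450)
        assert len(big_t) == len(big_n) == 2
        for (ts, te), (ns, ne) in zip(big_t, big_n):
            assert abs(ts - ns) <= 3 and abs(te - ne) <= 3

    def test_inverted_copy_found_with_minus_sign(self, rng):
        from tandemdup.seqio import revcomp

        unit = random_dna(rng, 900)
        region = random_dna(rng, 600) + revcomp(unit) + random_dna(rng, 600)
        hits = search_unit(_unit(unit), region, mode="translated")
        minus = [h for h in hits if h.sign == "-" and h.a0.length() >= 450]
        assert minus
        assert abs(minus[0].a1.start - 600) <= 3

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            search_unit(_unit("ACGT" * 200), "ACGT" * 500, mode="bogus")


class TestChainUnitHits:
    def test_three_clean_copies_give_three_tus(self, rng):
        unit = random_dna(rng, 900)
        positions = []
        pieces = [random_dna(rng, 800)]
        pos = 800
        for _ in range(3):
            positions.append((pos, pos + 900))
            pieces.append(unit)
            pos += 900
            pieces.append(random_dna(rng, 700))
            pos += 700
        region = "".join(pieces)
        hits = search_unit(_unit(unit), region, mode="translated")
        tus = chain_unit_hits(hits, 900, min_unit_length=500)
        assert len(tus) == 3
        for tu, (s, e) in zip(tus, positions):
            inter = max(0, min(tu.interval.end, e) - max(tu.interval.start, s))
            assert inter / 900 >= 0.70

    def test_insufficient_unit_coverage_rejected(self):
        from tandemdup.anchoring import Anchor

        # one hit covering only 40% of the unit
        h = Anchor(a0=Interval("unit", 0, 400), a1=Interval("region", 0, 400), sign="+", score=300, id=0)
        assert chain_unit_hits([h], 1000, min_unit_fraction=0.5, min_unit_length=100) == []

    def test_zero_hits_zero_tus(self):
        assert chain_unit_hits([], 1000) == []


class TestEnlargeUnits:
    def _tu(self, s, e):
        return TandemUnit(interval=Interval("s", s, e), array_id="ta_0", score=1.0)

    def _array(self, s=0, e=100_000):
        return TandemArray(id="ta_0", region=Interval("s", s, e))

    def test_lone_unit_gains_quarter_each_side(self):
        (out,) = enlarge_units([self._tu(10_000, 11_000)], 0.25, self._array())
        assert (out.interval.start, out.interval.end) == (9750, 11_250)
        assert out.enlarged

    def test_abutting_units_unchanged_at_junction(self):
        a, b = self._tu(10_000, 11_000), self._tu(11_000, 12_000)
        oa, ob = enlarge_units([a, b], 0.25, self._array())
        assert oa.interval.end == 11_000 and ob.interval.start == 11_000
        assert oa.interval.start == 9750 and ob.interval.end == 12_250

    def test_narrow_gap_split_equally(self):
        a, b = self._tu(10_000, 11_000), self._tu(11_200, 12_200)
        oa, ob = enlarge_units([a, b], 0.25, self._array())
        assert oa.interval.end == 11_100 and ob.interval.start == 11_100

    def test_clamped_to_array_region(self):
        (out,) = enlarge_units([self._tu(100, 1100)], 0.25, self._array(0, 1200))
        assert (out.interval.start, out.interval.end) == (0, 1200)

    def test_no_overlaps_after_enlargement(self, rng):
        tus = []
        pos = 1000
        for _ in range(6):
            ln = int(rng.integers(600, 1500))
            tus.append(self._tu(pos, pos + ln))
            pos += ln + int(rng.integers(0, 800))
        out = enlarge_units(tus, 0.25, self._array())
        for a, b in zip(out, out[1:]):
            assert a.interval.end <= b.interval.start


class TestReconstructArray:
    def _setup(self, rng, n_copies=3):
        unit = random_dna(rng, 900)
        pieces = [random_dna(rng, 2000)]
        pos = 2000
        positions = []
        for _ in range(n_copies):
            positions.append((pos, pos + 900))
            pieces.append(unit)
            pos += 900
            pieces.append(random_dna(rng, 600))
            pos += 600
        pieces.append(random_dna(rng, 1500))
        seq = GenomeSequence("s", "".join(pieces))
        ta = TandemArray(id="ta_0", region=Interval("s", 0, seq.length))
        ta.reference_unit = DuplicationUnit(
            interval=Interval("s", positions[0][0], positions[0][1]),
            residues=unit,
            source_chain=0,
        )
        return seq, ta, positions

    def test_units_fill_array_and_stay_inside(self, rng):
        seq, ta, positions = self._setup(rng)
        units = reconstruct_array(ta, seq, min_unit_length=500)
        assert len(units) == 3
        for u in units:
            assert ta.region.contains(u.interval)
            assert u.interval.length() >= 500
        for a, b in zip(units, units[1:]):
            assert a.interval.end <= b.interval.start

    def test_idempotent_on_own_output(self, rng):
        seq, ta, _ = self._setup(rng)
        first = reconstruct_array(ta, seq, min_unit_length=500)
        again = reconstruct_array(ta, seq, min_unit_length=500)
        assert [(u.interval.start, u.interval.end) for u in first] == [
            (u.interval.start, u.interval.end) for u in again
        ]

    def test_array_without_unit_rejected(self, rng):
        seq = GenomeSequence("s", random_dna(rng, 5000))
        ta = TandemArray(id="x", region=Interval("s", 0, 5000))
        with pytest.raises(ValueError):
            reconstruct_array(ta, seq)

    def test_no_hits_flags_unit_only(self, rng):
        seq = GenomeSequence("s", random_dna(rng, 4000))
        ta = TandemArray(id="x", region=Interval("s", 0, 4000))
        ta.reference_unit = DuplicationUnit(
            interval=Interval("s", 0, 900), residues=random_dna(rng, 900), source_chain=0
        )
        units = reconstruct_array(ta, seq, min_unit_length=500)
        assert units == [] and "unit_only" in ta.flags
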