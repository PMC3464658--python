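"""Self-alignment anchors constrained to the tandem (upper-half-plane) geometry.

An anchor is one local self-alignment of the genome: a signed pair of
non-overlapping intervals with an alignment score — one segment of the
self-comparison dotplot. By symmetry only the upper half-plane is kept
(a0.start < a1.start), the two intervals of an anchor may not overlap, and
after tandem filtering their gap is at most T.

The built-in aligner is seed-and-extend: exact k-mer seeds (unmasked
positions only, both strands), greedy clustering of seeds along dotplot
diagonals, ungapped X-drop extension of the cluster ends, and exact
rescoring of the paired substrings under the nucleotide scheme via an edlib
global alignment. Diagonal runs that would make an anchor overlap itself —
the signature of a tandem period shorter than the run — are split into
consecutive period-length anchors instead of being discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
from intervaltree import IntervalTree

from .seqio import GenomeSequence, Interval, interval_gap, overlap_fraction, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide alignment scoring; defaults follow the standard scheme
    match +1, mismatch -3, gap open/extend -5/-2 (a gap run of length g
    costs gap_open + g*gap_extend)."""

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_anchor_score: int = 30
    seed_k: int = 12
    xdrop: int = 20

    def __post_init__(self):
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("match must be > 0 and penalties < 0")


@dataclass(frozen=True)
class Anchor:
    """A signed pair of genomic intervals with an alignment score.

    For genome self-alignment anchors a0 is the interval with the smaller
    start and the two intervals never overlap. Reconstruction reuses this
    record for unit-vs-region hits, where axis 0 is the duplication unit;
    those cross-axis anchors are not subject to the tandem invariants, which
    are therefore enforced by `filter_tandem_anchors`, not the constructor.
    """

    a0: Interval
    a1: Interval
    sign: str
    score: int
    id: int = -1

    def __post_init__(self):
        if self.sign not in "+-":
            raise ValueError(f"sign must be + or -, got {self.sign!r}")

    def gap(self) -> int:
        return interval_gap(self.a0, self.a1)

    def intervals(self) -> tuple[Interval, Interval]:
        return (self.a0, self.a1)

    def is_valid_tandem(self, T: int) -> bool:
        return (
            self.a0.seq_name == self.a1.seq_name
            and self.a0.start < self.a1.start
            and self.a0.end <= self.a1.start
            and self.a1.start - self.a0.end <= T
            and self.score > 0
        )


# ---------------------------------------------------------------------------
# scoring helpers
# ---------------------------------------------------------------------------

def _cigar_runs(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def alignment_score(s0: str, s1: str, scheme: ScoringScheme) -> int:
    """Score of a global alignment of s0 vs s1 under the scheme.

    The alignment path is computed by edlib (unit costs) and rescored
    exactly; for the near-identical substrings produced by seed clustering
    the unit-cost path is the relevant one.
    """
    if not s0 or not s1:
        return 0
    res = edlib.align(s0, s1, mode="NW", task="path")
    cigar = res["cigar"]
    if cigar is None:
        return 0
    score = 0
    p0 = p1 = 0
    for run, op in _cigar_runs(cigar):
        if op in "=XM":
            x = s0[p0 : p0 + run]
            y = s1[p1 : p1 + run]
            matches = sum(1 for a, b in zip(x, y) if a == b and a in "ACGT")
            score += matches * scheme.match + (run - matches) * scheme.mismatch
            p0 += run
            p1 += run
        elif op == "I":  # edlib: I consumes the query (s0)
            score += scheme.gap_open + run * scheme.gap_extend
            p0 += run
        elif op == "D":  # D consumes the target (s1)
            score += scheme.gap_open + run * scheme.gap_extend
            p1 += run
    return score


# ---------------------------------------------------------------------------
# seeding and clustering
# ---------------------------------------------------------------------------

def _valid_seed_starts(residues: str, k: int) -> np.ndarray:
    """Boolean array: position i starts an unmasked exact-ACGT k-mer."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    ok = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(ok)))
    n = len(residues)
    valid = np.zeros(n, dtype=bool)
    if n >= k:
        valid[: n - k + 1] = (cs[k:] - cs[: n - k + 1]) == k
    return valid


def _kmer_index(residues: str, k: int, max_occ: int) -> dict[str, list[int]]:
    valid = _valid_seed_starts(residues, k)
    index: dict[str, list[int]] = {}
    for i in np.flatnonzero(valid):
        i = int(i)
        index.setdefault(residues[i : i + k], []).append(i)
    # drop hyper-repetitive words outright
    return {w: ps for w, ps in index.items() if len(ps) <= max_occ}


class _Cluster:
    __slots__ = ("diag", "i_min", "i_max", "j_min", "j_max", "last_i", "n")

    def __init__(self, diag, i, j):
        self.diag = diag
        self.i_min = self.i_max = i
        self.j_min = self.j_max = j
        self.last_i = i
        self.n = 1

    def add(self, diag, i, j):
        self.diag = diag
        self.i_max = max(self.i_max, i)
        self.i_min = min(self.i_min, i)
        self.j_max = max(self.j_max, j)
        self.j_min = min(self.j_min, j)
        self.last_i = i
        self.n += 1


def _cluster_seeds(seeds, band: int, max_gap: int):
    """Greedy single-linkage clustering of (diag_const, i, j) seeds.

    Seeds must be sorted by i; two seeds join the same cluster when their
    diagonal constants differ by at most `band` and their i starts by at
    most `max_gap`.
    """
    buckets: dict[int, list[_Cluster]] = {}
    done: list[_Cluster] = []
    for diag, i, j in seeds:
        key = diag // band
        best = None
        for kk in (key - 1, key, key + 1):
            for cl in buckets.get(kk, ()):
                if abs(diag - cl.diag) <= band and i - cl.last_i <= max_gap:
                    if best is None or cl.last_i > best.last_i:
                        best = cl
        if best is None:
            cl = _Cluster(diag, i, j)
            buckets.setdefault(key, []).append(cl)
        else:
            old_key = best.diag // band
            best.add(diag, i, j)
            new_key = best.diag // band
            if new_key != old_key:
                buckets[old_key].remove(best)
                buckets.setdefault(new_key, []).append(best)
        # retire stale clusters occasionally to keep buckets small
        if len(buckets.get(key, ())) > 8:
            alive = []
            for cl in buckets[key]:
                if i - cl.last_i > max_gap:
                    done.append(cl)
                else:
                    alive.append(cl)
            buckets[key] = alive
    for lst in buckets.values():
        done.extend(lst)
    return done


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------

def _xdrop_extend_plus(res: str, i0, i1, j0, j1, scheme: ScoringScheme):
    """Ungapped X-drop extension of a forward-strand segment pair.

    Extension never crosses the self-overlap boundary (a0.end <= a1.start).
    """
    n = len(res)
    # leftwards: moves i0 and j0 down together
    score = best = 0
    t = 0
    best_t = 0
    while i0 - t - 1 >= 0 and j0 - t - 1 > i1:
        t += 1
        a, b = res[i0 - t].upper(), res[j0 - t].upper()
        score += scheme.match if (a == b and a in "ACGT") else scheme.mismatch
        if score > best:
            best, best_t = score, t
        elif best - score > scheme.xdrop:
            break
    i0 -= best_t
    j0 -= best_t
    # rightwards: moves i1 and j1 up together
    score = best = 0
    t = 0
    best_t = 0
    while j1 + t + 1 <= n and i1 + t + 1 <= j0:
        a, b = res[i1 + t].upper(), res[j1 + t].upper()
        t += 1
        score += scheme.match if (a == b and a in "ACGT") else scheme.mismatch
        if score > best:
            best, best_t = score, t
        elif best - score > scheme.xdrop:
            break
    i1 += best_t
    j1 += best_t
    return i0, i1, j0, j1


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _xdrop_extend_minus(res: str, i0, i1, j0, j1, scheme: ScoringScheme):
    """Ungapped X-drop extension of a reverse-strand pair.

    a0 position x pairs with a1 position i0+j1-1-x; extending a0 left
    extends a1 right and vice versa.
    """
    n = len(res)
    score = best = 0
    t = 0
    best_t = 0
    while i0 - t - 1 >= 0 and j1 + t + 1 <= n:
        a = res[i0 - t - 1].upper()
        b = res[j1 + t].upper()
        t += 1
        hit = a in _COMP and _COMP[a] == b
        score += scheme.match if hit else scheme.mismatch
        if score > best:
            best, best_t = score, t
        elif best - score > scheme.xdrop:
            break
    i0 -= best_t
    j1 += best_t
    score = best = 0
    t = 0
    best_t = 0
    while j0 - t - 1 > i1 + t:  # keep a0 strictly before a1
        a = res[i1 + t].upper()
        b = res[j0 - t - 1].upper()
        t += 1
        hit = a in _COMP and _COMP[a] == b
        score += scheme.match if hit else scheme.mismatch
        if score > best:
            best, best_t = score, t
        elif best - score > scheme.xdrop:
            break
    i1 += best_t
    j0 -= best_t
    return i0, i1, j0, j1


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def find_anchors(
    seq: GenomeSequence,
    scheme: ScoringScheme | None = None,
    T: int = 150_000,
    max_occ: int = 100,
    band: int = 25,
    max_seed_gap: int = 200,
) -> list[Anchor]:
    """Self-align one sequence and return its tandem-filtered anchors.

    The main dotplot diagonal is excluded by construction (ordered seed
    pairs only) and self-overlapping diagonal runs are split at the period,
    so every reported anchor already satisfies the non-self-overlap
    condition; the gap <= T condition is applied by `filter_tandem_anchors`.
    """
    scheme = scheme or ScoringScheme()
    res = seq.residues
    k = scheme.seed_k
    if seq.length < 2 * k:
        return []
    index = _kmer_index(res, k, max_occ)
    pad = 2_000

    fwd_seeds = []  # (diag=j-i, i, j)
    rev_seeds = []  # (antidiag=i+j, i, j)
    for w, ps in index.items():
        rw = revcomp(w)
        # forward pairs
        if len(ps) >= 2:
            for x in range(len(ps)):
                i = ps[x]
                for y in range(x + 1, len(ps)):
                    j = ps[y]
                    if j - i - k > T + pad:
                        break
                    fwd_seeds.append((j - i, i, j))
        # reverse-complement pairs (handle each unordered word pair once)
        if rw > w:
            continue
        if rw == w:
            qs = ps
            for x in range(len(qs)):
                for y in range(x + 1, len(qs)):
                    i, j = qs[x], qs[y]
                    if j - i - k <= T + pad:
                        rev_seeds.append((i + j, i, j))
        elif rw in index:
            for i in index[w]:
                for j in index[rw]:
                    if i == j:
                        continue
                    lo, hi = (i, j) if i < j else (j, i)
                    if hi - lo - k <= T + pad:
                        rev_seeds.append((lo + hi, lo, hi))

    fwd_seeds.sort(key=lambda s: (s[1], s[0]))
    rev_seeds.sort(key=lambda s: (s[1], s[0]))

    raw: list[Anchor] = []
    for cl in _cluster_seeds(fwd_seeds, band, max_seed_gap):
        raw.extend(_plus_cluster_anchors(seq, cl, k, scheme))
    for cl in _cluster_seeds(rev_seeds, band, max_seed_gap):
        raw.extend(_minus_cluster_anchors(seq, cl, k, scheme))

    raw = [a for a in raw if a.score >= scheme.min_anchor_score]
    raw = filter_tandem_anchors(raw, T)
    raw.sort(key=lambda a: (a.a0.start, a.a0.end, a.a1.start, a.a1.end, a.sign))
    return [replace(a, id=i) for i, a in enumerate(raw)]


def _score_anchor(seq: GenomeSequence, name: str, i0, i1, j0, j1, sign, scheme) -> Anchor | None:
    if i1 - i0 < scheme.seed_k or j1 - j0 < scheme.seed_k:
        return None
    s0 = seq.residues[i0:i1].upper()
    s1 = seq.residues[j0:j1].upper()
    if sign == "-":
        s1 = revcomp(s1)
    score = alignment_score(s0, s1, scheme)
    if score <= 0:
        return None
    return Anchor(
        a0=Interval(name, i0, i1), a1=Interval(name, j0, j1), sign=sign, score=score
    )


def _plus_cluster_anchors(seq: GenomeSequence, cl: _Cluster, k: int, scheme) -> list[Anchor]:
    i0, i1 = cl.i_min, cl.i_max + k
    j0, j1 = cl.j_min, cl.j_max + k
    name = seq.name
    out = []
    if i1 <= j0:
        i0, i1, j0, j1 = _xdrop_extend_plus(seq.residues, i0, i1, j0, j1, scheme)
        a = _score_anchor(seq, name, i0, i1, j0, j1, "+", scheme)
        return [a] if a else []
    # self-overlapping run: tandem period p, split into consecutive unit pairs
    p = j0 - i0
    if p < k:
        return []
    x = i0
    while x + p < j1:
        e2 = min(x + 2 * p, j1)
        if e2 - (x + p) >= k:
            a = _score_anchor(seq, name, x, x + p, x + p, e2, "+", scheme)
            if a:
                out.append(a)
        x += p
    return out


def _minus_cluster_anchors(seq: GenomeSequence, cl: _Cluster, k: int, scheme) -> list[Anchor]:
    i0, i1 = cl.i_min, cl.i_max + k
    j0, j1 = cl.j_min, cl.j_max + k
    if i1 > j0:  # palindrome touching itself: trim both sides to the midpoint
        mid = (i1 + j0) // 2
        i1, j0 = mid, mid
        if i1 - i0 < k or j1 - j0 < k:
            return []
    i0, i1, j0, j1 = _xdrop_extend_minus(seq.residues, i0, i1, j0, j1, scheme)
    a = _score_anchor(seq, seq.name, i0, i1, j0, j1, "-", scheme)
    return [a] if a else []


def filter_tandem_anchors(anchors: list[Anchor], T: int) -> list[Anchor]:
    """Keep exactly the anchors whose intervals do not overlap and whose gap
    is at most T; stable order."""
    kept = []
    for a in anchors:
        if a.a0.end <= a.a1.start and a.a1.start - a.a0.end <= T:
            kept.append(a)
    return kept


def dedupe_anchors(anchors: list[Anchor], max_mutual_overlap: float = 0.5) -> list[Anchor]:
    """Drop anchors that duplicate a better anchor on both projections.

    Two anchors conflict when their a0 intervals AND their a1 intervals each
    overlap by more than `max_mutual_overlap` of the smaller interval; the
    higher-scoring anchor wins (ties: the longer, then the earlier id).
    Greedy in priority order, so a conflict chain a>b>c with a,c compatible
    keeps a and c.
    """
    order = sorted(
        anchors,
        key=lambda a: (-a.score, -(a.a0.length() + a.a1.length()), a.id),
    )
    kept: list[Anchor] = []
    trees: dict[str, IntervalTree] = {}
    for a in order:
        tree = trees.get(a.a0.seq_name)
        conflict = False
        if tree is not None:
            for hit in tree.overlap(a.a0.start, a.a0.end):
                b = hit.data
                if (
                    overlap_fraction(a.a0, b.a0) > max_mutual_overlap
                    and a.a1.overlaps(b.a1)
                    and overlap_fraction(a.a1, b.a1) > max_mutual_overlap
                ):
                    conflict = True
                    break
        if conflict:
            continue
        kept.append(a)
        if tree is None:
            tree = trees[a.a0.seq_name] = IntervalTree()
        tree.addi(a.a0.start, a.a0.end, a)
    kept.sort(key=lambda a: a.id)
    n_dropped = len(anchors) - len(kept)
    if n_dropped:
        logger.info("dedupe dropped %d of %d anchors", n_dropped, len(anchors))
    return kept
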