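"""Genome I/O, interval algebra and low-complexity masking.

All in-memory coordinates are 0-based half-open. On-disk formats keep their
native conventions (GFF3 and the anchor table are 1-based inclusive, BED is
0-based half-open); conversions happen only in the readers and writers here.

Soft-masking uses lowercase residues, so masked positions stay addressable
and downstream coordinates are unaffected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTNacgtn")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# char -> sanitized char: keep ACGTN (both cases), everything else becomes N/n
_SANITIZE = {}
for _c in range(256):
    ch = chr(_c)
    if ch in _ALLOWED:
        _SANITIZE[_c] = ch
    elif ch.isalpha():
        _SANITIZE[_c] = "n" if ch.islower() else "N"
_SANITIZE_TABLE = str.maketrans(_SANITIZE)


def revcomp(s: str) -> str:
    """Reverse complement, preserving case (soft masking survives)."""
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open.

    Sorting order is (seq_name, start, end), which is the emission order used
    by every writer in this package.
    """

    seq_name: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_name!r}"
            )

    def length(self) -> int:
        return self.end - self.start

    def midpoint2(self) -> int:
        """Twice the midpoint (kept integral to avoid float ties)."""
        return self.start + self.end

    def intersection_length(self, other: "Interval") -> int:
        if self.seq_name != other.seq_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "Interval") -> bool:
        return self.intersection_length(other) > 0

    def contains(self, other: "Interval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start <= other.start
            and other.end <= self.end
        )


def interval_gap(u: Interval, v: Interval) -> int:
    """Distance d(u, v) = v.start - u.end between ordered non-overlapping intervals.

    0 means the intervals abut in half-open coordinates.
    """
    if u.seq_name != v.seq_name:
        raise ValueError(f"intervals on different sequences: {u.seq_name} vs {v.seq_name}")
    if u.end > v.start:
        raise ValueError(f"intervals overlap or are wrongly ordered: {u} !< {v}")
    return v.start - u.end


def overlap_fraction(u: Interval, v: Interval, denominator: str = "smaller") -> float:
    """|u ∩ v| divided by the length of `first`, `second` or the `smaller` interval."""
    if u.seq_name != v.seq_name:
        raise ValueError("intervals on different sequences")
    inter = u.intersection_length(v)
    if inter == 0:
        return 0.0
    if denominator == "first":
        denom = u.length()
    elif denominator == "second":
        denom = v.length()
    elif denominator == "smaller":
        denom = min(u.length(), v.length())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return inter / denom


@dataclass(frozen=True)
class GenomeSequence:
    """One sequence of the genome; lowercase residues are soft-masked."""

    name: str
    residues: str

    def __post_init__(self):
        if len(self.residues) == 0:
            raise ValueError(f"empty sequence {self.name!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def subsequence(self, iv: Interval) -> str:
        if iv.end > self.length:
            raise ValueError(f"{iv} exceeds sequence length {self.length}")
        return self.residues[iv.start : iv.end]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA; non-ACGTN residues are mapped to N with a warning."""
    seqs: list[GenomeSequence] = []
    names = set()
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in names:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        names.add(rec.id)
        residues = str(rec.seq)
        arr = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
        ok = np.isin(arr, np.frombuffer(b"ACGTNacgtn", dtype=np.uint8))
        bad = int((~ok).sum())
        if bad:
            n_replaced += bad
            residues = residues.translate(_SANITIZE_TABLE)
        seqs.append(GenomeSequence(rec.id, residues))
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    if n_replaced:
        logger.warning("%d non-ACGTN residues mapped to N while reading %s", n_replaced, path)
    return seqs


def write_fasta(seqs: Iterable[GenomeSequence], path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.name, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# DUST low-complexity masking
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _dust_segment_windows(codes: Sequence[int], window: int, threshold: float):
    """Yield (start, end) of windows whose DUST score exceeds the threshold.

    The score of a window is 10 * sum_t c_t(c_t-1)/2 / (n_triplets - 1), the
    classic triplet-repetition statistic; the published defaults are
    window=64, threshold=20.
    """
    n = len(codes)
    if n < 5:  # need at least 3 triplets for a meaningful score
        return
    w = min(window, n)
    ntrip_full = w - 2
    trip = [codes[i] * 16 + codes[i + 1] * 4 + codes[i + 2] for i in range(n - 2)]
    counts = [0] * 64
    s = 0
    # prime the first window's triplets
    for t in trip[:ntrip_full]:
        s += counts[t]
        counts[t] += 1
    denom = ntrip_full - 1
    if 10.0 * s / denom > threshold:
        yield (0, w)
    for i in range(1, n - w + 1):
        t_out = trip[i - 1]
        counts[t_out] -= 1
        s -= counts[t_out]
        t_in = trip[i + ntrip_full - 1]
        s += counts[t_in]
        counts[t_in] += 1
        if 10.0 * s / denom > threshold:
            yield (i, i + w)


def mask_low_complexity(
    seq: GenomeSequence, window: int = 64, threshold: float = 20.0
) -> GenomeSequence:
    """Soft-mask low-complexity regions with a DUST-style triplet score.

    Positions inside any window whose score exceeds the threshold are
    lowercased. Ns and already-masked residues split the sequence into
    independently scored segments.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    res = seq.residues
    mask = np.zeros(len(res), dtype=bool)
    # segments of consecutive upper-case ACGT
    seg_start = None
    segments = []
    for i, ch in enumerate(res):
        if ch in _BASE_CODE:
            if seg_start is None:
                seg_start = i
        else:
            if seg_start is not None:
                segments.append((seg_start, i))
                seg_start = None
    if seg_start is not None:
        segments.append((seg_start, len(res)))
    for a, b in segments:
        codes = [_BASE_CODE[c] for c in res[a:b]]
        last_end = a
        for ws, we in _dust_segment_windows(codes, window, threshold):
            lo, hi = a + ws, a + we
            mask[max(lo, last_end) : hi] = True
            last_end = max(last_end, hi)
    if not mask.any():
        return seq
    out = [c.lower() if m else c for c, m in zip(res, mask)]
    masked = GenomeSequence(seq.name, "".join(out))
    logger.info("masked %d/%d bp of %s", int(mask.sum()), len(res), seq.name)
    return masked


# ---------------------------------------------------------------------------
# Anchor table
# ---------------------------------------------------------------------------

ANCHOR_TABLE_HEADER = "#seq_name\ta0_start\ta0_end\ta1_start\ta1_end\tsign\tscore"


def read_anchor_table(path, T: int | None = None) -> list:
    """Read a tab-separated anchor table (1-based inclusive on disk).

    Anchors are normalized so the lower-coordinate interval comes first; rows
    whose two intervals overlap, or whose gap exceeds T when T is given, are
    dropped with a logged count.
    """
    from .anchoring import Anchor  # deferred to avoid an import cycle

    anchors = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                seq = parts[0]
                a0s, a0e, a1s, a1e = (int(x) for x in parts[1:5])
                sign = parts[5]
                score = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            if sign not in "+-":
                raise ValueError(f"{path}:{lineno}: sign must be + or -, got {sign!r}")
            try:
                i0 = Interval(seq, a0s - 1, a0e)
                i1 = Interval(seq, a1s - 1, a1e)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if i1.start < i0.start:
                i0, i1 = i1, i0
            if i0.end > i1.start or (T is not None and i1.start - i0.end > T):
                dropped += 1
                continue
            anchors.append(Anchor(a0=i0, a1=i1, sign=sign, score=score, id=len(anchors)))
    if dropped:
        logger.warning("dropped %d anchors violating tandem constraints in %s", dropped, path)
    return anchors


def write_anchor_table(anchors: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write(ANCHOR_TABLE_HEADER + "\n")
        for a in anchors:
            fh.write(
                f"{a.a0.seq_name}\t{a.a0.start + 1}\t{a.a0.end}\t"
                f"{a.a1.start + 1}\t{a.a1.end}\t{a.sign}\t{a.score}\n"
            )


# ---------------------------------------------------------------------------
# Feature output (GFF3 / BED)
# ---------------------------------------------------------------------------

def _clip_score(x) -> int:
    return int(min(1000, max(0, round(abs(float(x))))))


def write_features(arrays: Sequence, units: Sequence, path, format: str = "gff3") -> None:
    """Write tandem arrays and tandem units as GFF3 or BED6.

    GFF3 is 1-based inclusive with types tandem_array/tandem_unit and units
    carrying Parent= attributes; BED6 is 0-based half-open with the array id
    as name. Records are ordered by (seq, start, end) so output is
    deterministic.
    """
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown format {format!r}")
    arrays = sorted(arrays, key=lambda a: (a.region.seq_name, a.region.start, a.region.end, a.id))
    units = sorted(units, key=lambda u: (u.interval.seq_name, u.interval.start, u.interval.end))
    lines = []
    if format == "gff3":
        lines.append("##gff-version 3")
        for ta in arrays:
            r = ta.region
            lines.append(
                f"{r.seq_name}\ttandemdup\ttandem_array\t{r.start + 1}\t{r.end}\t"
                f".\t.\t.\tID={ta.id}"
            )
        for tu in units:
            r = tu.interval
            lines.append(
                f"{r.seq_name}\ttandemdup\ttandem_unit\t{r.start + 1}\t{r.end}\t"
                f"{_clip_score(tu.score)}\t.\t.\tID={tu.id};Parent={tu.array_id}"
            )
    else:
        for ta in arrays:
            r = ta.region
            lines.append(f"{r.seq_name}\t{r.start}\t{r.end}\t{ta.id}\t0\t.")
        for tu in units:
            r = tu.interval
            lines.append(
                f"{r.seq_name}\t{r.start}\t{r.end}\t{tu.array_id}\t{_clip_score(tu.score)}\t."
            )
    Path(path).write_text("\n".join(lines) + "\n")
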