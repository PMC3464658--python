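"""Final reconstruction: re-search each array with its reference unit.

The reference duplication unit is searched against the whole array region —
by default with an internal translated (six-frame, BLOSUM62) seeded search,
optionally at the nucleotide level or through an external TBLASTX binary —
and the resulting unit-vs-region hits are chained in a local graph G3 with
the same machinery as G1. Each extracted chain whose unit-axis projection
covers enough of the unit becomes one tandem unit (TU); TUs are finally
enlarged by up to 25% of their own length on each side without creating
overlaps or leaving the array region.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .anchoring import Anchor, ScoringScheme, dedupe_anchors, find_anchors
from .arrays import DuplicationUnit, TandemArray
from .chaining import build_anchor_graph, min_cost_flow_chains
from .seqio import GenomeSequence, Interval, revcomp

logger = logging.getLogger(__name__)

UNIT_AXIS = "unit"
REGION_AXIS = "region"

# a G3 chain may not stretch further along the region than this multiple of
# the unit length: one chain is supposed to be one copy of the unit
MAX_TU_STRETCH = 1.5


@dataclass
class TandemUnit:
    """One called copy of the duplication unit inside a tandem array."""

    interval: Interval
    array_id: str
    score: float
    enlarged: bool = False
    id: str = ""


_BLOSUM = substitution_matrices.load("BLOSUM62")
_BLOSUM_ALPHABET = set(str(_BLOSUM.alphabet))


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _sanitize_protein(p: str) -> str:
    return "".join(c if c in _BLOSUM_ALPHABET and c != "*" else "X" for c in p)


def _translate_frames(nt: str) -> list[tuple[int, str]]:
    """The three forward reading frames of a nucleotide string."""
    nt = nt.upper()
    out = []
    for f in range(3):
        sub = nt[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        if len(sub) >= 3:
            out.append((f, _sanitize_protein(str(Seq(sub).translate()))))
    return out


def _aa_seed_index(prot: str, w: int = 3) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(prot) - w + 1):
        word = prot[i : i + w]
        if "X" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def _cluster_aa_seeds(pairs: list[tuple[int, int]], band: int = 12, max_gap: int = 60):
    """Single-linkage clustering of (qpos, tpos) seeds along aa diagonals."""
    pairs.sort(key=lambda p: (p[0] - p[1], p[0]))
    clusters: list[list[tuple[int, int]]] = []
    for q, t in pairs:
        d = q - t
        placed = False
        if clusters:
            last = clusters[-1][-1]
            if abs(d - (last[0] - last[1])) <= band and abs(q - last[0]) <= max_gap:
                clusters[-1].append((q, t))
                placed = True
        if not placed:
            clusters.append([(q, t)])
    return [c for c in clusters if len(c) >= 2]


def _translated_hits(
    unit_res: str, region_res: str, min_hit_score: float, word: int = 3
) -> list[Anchor]:
    """Seeded six-frame protein-level search of unit vs region."""
    aligner = _protein_aligner()
    unit_frames = _translate_frames(unit_res)
    n_region = len(region_res)
    hits: list[Anchor] = []

    def add_hit(q_nt0: int, q_nt1: int, r_nt0: int, r_nt1: int, sign: str, score: float):
        if q_nt1 - q_nt0 < 3 or r_nt1 - r_nt0 < 3:
            return
        hits.append(
            Anchor(
                a0=Interval(UNIT_AXIS, q_nt0, q_nt1),
                a1=Interval(REGION_AXIS, max(0, r_nt0), min(n_region, r_nt1)),
                sign=sign,
                score=int(round(score)),
            )
        )

    for strand, reg_nt in (("+", region_res), ("-", revcomp(region_res))):
        for fr, reg_prot in _translate_frames(reg_nt):
            reg_index = _aa_seed_index(reg_prot, word)
            for fu, unit_prot in unit_frames:
                pairs: list[tuple[int, int]] = []
                for qi in range(len(unit_prot) - word + 1):
                    wrd = unit_prot[qi : qi + word]
                    if "X" in wrd:
                        continue
                    for ti in reg_index.get(wrd, ()):
                        pairs.append((qi, ti))
                for cl in _cluster_aa_seeds(pairs):
                    q_lo = max(0, min(q for q, _ in cl) - 20)
                    q_hi = min(len(unit_prot), max(q for q, _ in cl) + word + 20)
                    t_lo = max(0, min(t for _, t in cl) - 20)
                    t_hi = min(len(reg_prot), max(t for _, t in cl) + word + 20)
                    sub_q = unit_prot[q_lo:q_hi]
                    sub_t = reg_prot[t_lo:t_hi]
                    try:
                        aln = aligner.align(sub_q, sub_t)[0]
                    except (IndexError, ValueError):
                        continue
                    if aln.score < min_hit_score:
                        continue
                    q0 = q_lo + int(aln.aligned[0][0][0])
                    q1 = q_lo + int(aln.aligned[0][-1][1])
                    t0 = t_lo + int(aln.aligned[1][0][0])
                    t1 = t_lo + int(aln.aligned[1][-1][1])
                    q_nt0, q_nt1 = fu + 3 * q0, fu + 3 * q1
                    r_nt0, r_nt1 = fr + 3 * t0, fr + 3 * t1
                    if strand == "-":
                        r_nt0, r_nt1 = n_region - r_nt1, n_region - r_nt0
                    add_hit(q_nt0, q_nt1, r_nt0, r_nt1, strand, aln.score)
    return hits


def _nucleotide_hits(
    unit_res: str, region_res: str, scheme: ScoringScheme
) -> list[Anchor]:
    """Cross-sequence hits through the nucleotide self-aligner.

    Unit and region are joined by an unalignable N spacer; anchors whose
    first interval lies in the unit part and second in the region part are
    the cross hits."""
    spacer = 50
    combined = GenomeSequence("q", unit_res.upper() + "N" * spacer + region_res.upper())
    offset = len(unit_res) + spacer
    hits = []
    for a in find_anchors(combined, scheme, T=combined.length):
        if a.a0.end <= len(unit_res) and a.a1.start >= offset:
            hits.append(
                Anchor(
                    a0=Interval(UNIT_AXIS, a.a0.start, a.a0.end),
                    a1=Interval(REGION_AXIS, a.a1.start - offset, a.a1.end - offset),
                    sign=a.sign,
                    score=a.score,
                )
            )
    return hits


def _external_hits(unit_res: str, region_res: str) -> list[Anchor]:
    exe = shutil.which("tblastx")
    if exe is None:
        raise RuntimeError(
            "external mode requires a tblastx executable on PATH; "
            "use mode='translated' for the built-in search"
        )
    with tempfile.TemporaryDirectory() as tmp:
        qp, sp = Path(tmp, "q.fa"), Path(tmp, "s.fa")
        qp.write_text(f">unit\n{unit_res}\n")
        sp.write_text(f">region\n{region_res}\n")
        out = subprocess.run(
            [exe, "-query", str(qp), "-subject", str(sp), "-outfmt",
             "6 qstart qend sstart send evalue bitscore"],
            capture_output=True, text=True, check=True,
        ).stdout
    hits = []
    for line in out.splitlines():
        qs, qe, ss, se, _ev, bits = line.split("\t")
        qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
        sign = "+" if ss <= se else "-"
        if ss > se:
            ss, se = se, ss
        if qs > qe:
            qs, qe = qe, qs
        hits.append(
            Anchor(
                a0=Interval(UNIT_AXIS, qs - 1, qe),
                a1=Interval(REGION_AXIS, ss - 1, se),
                sign=sign,
                score=int(round(float(bits))),
            )
        )
    return hits


def search_unit(
    unit: DuplicationUnit,
    array_region_residues: str,
    mode: str = "translated",
    scheme: ScoringScheme | None = None,
    min_hit_score: float = 50.0,
) -> list[Anchor]:
    """Search the reference unit against its array region.

    Returns unit-vs-region hits as anchors in region-local coordinates,
    unit on axis 0, deduplicated and deterministically ordered/numbered.
    """
    scheme = scheme or ScoringScheme()
    if mode == "translated":
        hits = _translated_hits(unit.residues, array_region_residues, min_hit_score)
    elif mode == "nucleotide":
        hits = _nucleotide_hits(unit.residues, array_region_residues, scheme)
    elif mode == "external":
        hits = _external_hits(unit.residues, array_region_residues)
    else:
        raise ValueError(f"unknown search mode {mode!r}")
    hits.sort(key=lambda a: (a.a1.start, a.a1.end, a.a0.start, a.a0.end, a.sign))
    hits = [replace(a, id=i) for i, a in enumerate(hits)]
    hits = dedupe_anchors(hits)
    hits = [replace(a, id=i) for i, a in enumerate(hits)]
    return hits


def chain_unit_hits(
    hits: list[Anchor],
    unit_length: int,
    L: int = 40_000,
    min_unit_fraction: float = 0.5,
    min_unit_length: int = 500,
    k: int = 15,
) -> list[TandemUnit]:
    """Chain unit-vs-region hits (graph G3) into tandem units.

    The same flow chainer as G1 runs with G3's consistency tests: a chain's
    region projection must stay within MAX_TU_STRETCH of the unit length
    (one chain = one copy) and chains must be pairwise disjoint along the
    region. Chains covering at least `min_unit_fraction` of the unit on the
    unit axis and at least the minimum unit length on the region axis
    become TUs, in region-local coordinates.
    """
    if not hits:
        return []
    graph = build_anchor_graph(hits, L=L, k=k, T=2 * L, require_tandem=False)
    max_len = MAX_TU_STRETCH * unit_length

    def chain_check(c):
        return (
            c.c1.length() <= max_len
            and c.c1.length() >= min_unit_length
            and c.c0.length() >= min_unit_fraction * unit_length
        )

    result = min_cost_flow_chains(
        graph,
        chain_check=chain_check,
        pair_check=lambda ci, cj: not ci.c1.overlaps(cj.c1),
        mode="max_valid",
    )
    units = []
    for c in result.chains:
        score = sum(a.score for a in c.anchors)
        units.append(TandemUnit(interval=c.c1, array_id="", score=score))
    units.sort(key=lambda u: (u.interval.start, u.interval.end))
    return units


def enlarge_units(
    units: list[TandemUnit], max_fraction: float = 0.25, array: TandemArray | None = None
) -> list[TandemUnit]:
    """Extend each TU by up to `max_fraction` of its own length per side.

    Adjacent TUs split an insufficient gap equally; TUs never overlap and
    never leave the array region.
    """
    if not units:
        return []
    units = sorted(units, key=lambda u: (u.interval.start, u.interval.end))
    region = array.region if array is not None else None
    name = units[0].interval.seq_name
    lo_bound = region.start if region else 0
    n = len(units)
    grants_left = [0] * n
    grants_right = [0] * n
    for i, u in enumerate(units):
        want = int(max_fraction * u.interval.length())
        grants_left[i] = want
        grants_right[i] = want
    out = []
    for i, u in enumerate(units):
        if i > 0:
            gap = u.interval.start - units[i - 1].interval.end
            wl, wr = grants_right[i - 1], grants_left[i]
            if wl + wr <= gap:
                gl, gr = wl, wr
            else:
                gl = min(wl, gap // 2)
                gr = min(wr, gap - gl)
                gl = min(wl, gap - gr)
            grants_right[i - 1] = gl
            grants_left[i] = gr
    for i, u in enumerate(units):
        start = u.interval.start - grants_left[i]
        end = u.interval.end + grants_right[i]
        if region is not None:
            start = max(start, region.start)
            end = min(end, region.end)
        else:
            start = max(start, 0)
        if i == 0:
            start = max(start, lo_bound)
        enlarged = start < u.interval.start or end > u.interval.end
        out.append(
            TandemUnit(
                interval=Interval(name, start, end),
                array_id=u.array_id,
                score=u.score,
                enlarged=enlarged,
                id=u.id,
            )
        )
    return out


def reconstruct_array(
    array: TandemArray,
    seq: GenomeSequence,
    mode: str = "translated",
    scheme: ScoringScheme | None = None,
    L: int = 40_000,
    min_unit_fraction: float = 0.5,
    min_unit_length: int = 500,
    k: int = 15,
    max_enlarge: float = 0.25,
) -> list[TandemUnit]:
    """Run the re-search for one array and fill in its tandem units."""
    unit = array.reference_unit
    if unit is None:
        raise ValueError(f"array {array.id} has no reference unit")
    region_res = seq.subsequence(array.region)
    hits = search_unit(unit, region_res, mode=mode, scheme=scheme)
    local = chain_unit_hits(
        hits,
        unit_length=len(unit.residues),
        L=L,
        min_unit_fraction=min_unit_fraction,
        min_unit_length=min_unit_length,
        k=k,
    )
    if not local:
        array.flags.add("unit_only")
        array.units = []
        return []
    shifted = [
        TandemUnit(
            interval=Interval(
                seq.name,
                array.region.start + u.interval.start,
                array.region.start + u.interval.end,
            ),
            array_id=array.id,
            score=u.score,
        )
        for u in local
    ]
    shifted = enlarge_units(shifted, max_fraction=max_enlarge, array=array)
    array.units = shifted
    return shifted
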