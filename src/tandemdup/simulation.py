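"""Synthetic genomes with planted tandem arrays and exact ground truth.

The generator emulates the structure the detector targets: arrays of 2+
copies of a duplication unit, each copy independently mutated (substitutions
and short geometric indels, optionally inverted), copies separated by
spacers shorter than T, arrays embedded in i.i.d. background at a plant-like
GC content. The sequence is assembled left to right, so every copy's final
coordinates are known exactly; no post-hoc coordinate tracking is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import GenomeSequence, Interval, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Study conditions for the planted-array benchmark.

    Defaults: a 300 kb genome carrying 8 arrays of 2-6 copies of a
    600-3000 bp unit at 3% substitutions and 0.5% indels — units longer
    than the 500 bp minimum, spacers far below T, divergence well inside
    the detectable range.
    """

    genome_length: int = 300_000
    n_arrays: int = 8
    unit_length_range: tuple[int, int] = (600, 3000)
    copies_range: tuple[int, int] = (2, 6)
    spacer_range: tuple[int, int] = (200, 2_000)
    substitution_rate: float = 0.03
    indel_rate: float = 0.005
    indel_length_geometric_p: float = 0.7
    max_indel_length: int = 50
    inversion_prob: float = 0.05
    gc_content: float = 0.36
    seed: int = 0
    T: int = 150_000

    def __post_init__(self):
        for r in (self.substitution_rate, self.indel_rate, self.inversion_prob):
            if not (0 <= r < 1):
                raise ValueError("rates must lie in [0, 1)")
        if self.spacer_range[1] + self.unit_length_range[1] > self.T:
            raise ValueError("spacer + unit maximum must stay below T")


@dataclass
class TruthRecord:
    """Ground truth for one planted array."""

    array_id: str
    copies: list[Interval]
    divergences: list[float]  # realized per-copy substitution fraction
    inverted: list[bool]
    unit_length: int


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, params: SimParams) -> tuple[str, float]:
    """Substitutions then indels; returns (mutated, realized substitution rate)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    sub_mask = rng.random(n) < params.substitution_rate
    n_subs = int(sub_mask.sum())
    if n_subs:
        # replace with a uniformly chosen different base
        codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in np.flatnonzero(sub_mask):
            choices = codes[codes != arr[i]]
            arr[i] = rng.choice(choices)
    out = arr.tobytes().decode()
    if params.indel_rate > 0:
        pieces = []
        pos = 0
        indel_sites = np.flatnonzero(rng.random(n) < params.indel_rate)
        for site in indel_sites:
            if site < pos:
                continue
            length = min(int(rng.geometric(params.indel_length_geometric_p)), params.max_indel_length)
            pieces.append(out[pos:site])
            if rng.random() < 0.5:  # insertion
                pieces.append(_random_seq(rng, length, params.gc_content))
                pos = site
            else:  # deletion
                pos = site + length
        pieces.append(out[pos:])
        out = "".join(pieces)
    return out, (n_subs / n if n else 0.0)


def simulate_genome(params: SimParams) -> tuple[GenomeSequence, list[TruthRecord]]:
    """Generate one sequence with planted tandem arrays plus exact truth.

    `genome_length` is the background budget; the emitted sequence is that
    plus the planted copies, shifted by the net indel drift. Deterministic
    under `params.seed`.
    """
    rng = np.random.default_rng(params.seed)
    units = [
        _random_seq(rng, int(rng.integers(*params.unit_length_range, endpoint=True)), params.gc_content)
        for _ in range(params.n_arrays)
    ]
    n_copies = [int(rng.integers(*params.copies_range, endpoint=True)) for _ in range(params.n_arrays)]
    # background split into n_arrays+1 gaps, each large enough to keep
    # arrays separated and inside the sequence
    min_gap = 2_000
    n_gaps = params.n_arrays + 1
    budget = params.genome_length
    if budget < n_gaps * min_gap:
        raise ValueError(
            f"arrays cannot fit: background budget {budget} < {n_gaps} gaps of {min_gap}"
        )
    cuts = np.sort(rng.random(n_gaps - 1))
    free = budget - n_gaps * min_gap
    gap_sizes = [min_gap + int(free * w) for w in np.diff(np.concatenate(([0.0], cuts, [1.0])))]
    gap_sizes[-1] += budget - sum(gap_sizes)

    pieces = []
    pos = 0
    truth: list[TruthRecord] = []
    name = "sim"
    for ai in range(params.n_arrays):
        g = _random_seq(rng, gap_sizes[ai], params.gc_content)
        pieces.append(g)
        pos += len(g)
        copies = []
        divs = []
        invs = []
        for ci in range(n_copies[ai]):
            if ci > 0:
                sp = _random_seq(
                    rng, int(rng.integers(*params.spacer_range, endpoint=True)), params.gc_content
                )
                pieces.append(sp)
                pos += len(sp)
            mut, div = _mutate(rng, units[ai], params)
            inv = bool(rng.random() < params.inversion_prob)
            if inv:
                mut = revcomp(mut)
            pieces.append(mut)
            copies.append(Interval(name, pos, pos + len(mut)))
            divs.append(div)
            invs.append(inv)
            pos += len(mut)
        truth.append(
            TruthRecord(
                array_id=f"planted_{ai:03d}",
                copies=copies,
                divergences=divs,
                inverted=invs,
                unit_length=len(units[ai]),
            )
        )
    pieces.append(_random_seq(rng, gap_sizes[-1], params.gc_content))
    genome = GenomeSequence(name, "".join(pieces))
    for rec in truth:
        for iv, nxt in zip(rec.copies, rec.copies[1:]):
            assert nxt.start - iv.end <= params.T
    logger.info(
        "simulated %d bp genome with %d arrays (%d copies total)",
        genome.length,
        len(truth),
        sum(len(r.copies) for r in truth),
    )
    return genome, truth


def write_truth_bed(truth: list[TruthRecord], path) -> None:
    lines = []
    for rec in truth:
        for i, iv in enumerate(rec.copies):
            strand = "-" if rec.inverted[i] else "+"
            lines.append(
                f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{rec.array_id}_copy{i}\t0\t{strand}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_annotation(
    truth: list[TruthRecord],
    genome: GenomeSequence,
    params: SimParams,
    gff_path,
    hits_path,
    n_decoys: int | None = None,
) -> None:
    """Emit a gene annotation and protein-hit table matching the truth.

    One gene per planted copy, decoy genes in the background, and a hit
    table where copies of the same array hit each other (e-value 1e-10,
    coverages drawn in [0.7, 1.0]) — enough to rebuild the reference tandem
    gene arrays without any protein search.
    """
    rng = np.random.default_rng(params.seed + 1)
    if n_decoys is None:
        n_decoys = params.n_arrays
    occupied = sorted((iv.start, iv.end) for rec in truth for iv in rec.copies)

    def in_background(s, e):
        return all(e <= a or s >= b for a, b in occupied)

    genes = []  # (gene_id, start, end, kind)
    for rec in truth:
        for i, iv in enumerate(rec.copies):
            genes.append((f"{rec.array_id}_g{i}", iv.start, iv.end, "gene"))
    placed = 0
    attempts = 0
    while placed < n_decoys and attempts < 1000:
        attempts += 1
        s = int(rng.integers(0, max(1, genome.length - 1200)))
        e = s + 1000
        if in_background(s, e) and all(e <= gs or s >= ge for _, gs, ge, _ in genes):
            genes.append((f"decoy_{placed:03d}", s, e, "gene"))
            placed += 1
    genes.sort(key=lambda g: g[1])
    lines = ["##gff-version 3"]
    for gid, s, e, kind in genes:
        lines.append(
            f"{genome.name}\tsim\t{kind}\t{s + 1}\t{e}\t.\t+\t.\tID={gid};Name={gid}"
        )
    Path(gff_path).write_text("\n".join(lines) + "\n")

    hit_lines = ["#query\tsubject\tevalue\tquery_coverage\tsubject_coverage"]
    for rec in truth:
        ids = [f"{rec.array_id}_g{i}" for i in range(len(rec.copies))]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                qc = 0.7 + 0.3 * rng.random()
                sc = 0.7 + 0.3 * rng.random()
                hit_lines.append(f"{ids[i]}\t{ids[j]}\t1e-10\t{qc:.3f}\t{sc:.3f}")
    Path(hits_path).write_text("\n".join(hit_lines) + "\n")
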