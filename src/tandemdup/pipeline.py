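"""End-to-end orchestration: anchors → chains → arrays → reconstruction.

Each stage writes its artifact to the output directory and the run manifest
records the configuration and per-stage counts, so genome-scale runs are
auditable and reruns are byte-identical (the detection pipeline is fully
deterministic; only the simulator consumes the seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .anchoring import Anchor, dedupe_anchors, find_anchors
from .arrays import (
    TandemArray,
    build_overlap_graph,
    delineate_arrays,
    select_reference_unit,
)
from .chaining import Chain, chain_anchors, check_chain_set
from .config import Config
from .reconstruction import TandemUnit, reconstruct_array
from .seqio import (
    GenomeSequence,
    mask_low_complexity,
    read_fasta,
    write_anchor_table,
    write_fasta,
    write_features,
)

logger = logging.getLogger(__name__)


def write_chain_table(chains: list[Chain], path) -> None:
    lines = ["#chain_id\tseq\tsign\tc0_start\tc0_end\tc1_start\tc1_end\tcost\tanchor_ids"]
    for c in chains:
        ids = ",".join(str(a.id) for a in c.anchors)
        lines.append(
            f"{c.id}\t{c.c0.seq_name}\t{c.sign}\t{c.c0.start}\t{c.c0.end}\t"
            f"{c.c1.start}\t{c.c1.end}\t{c.cost:.3f}\t{ids}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class StageResult:
    anchors: dict[str, list[Anchor]] = field(default_factory=dict)
    chains: dict[str, list[Chain]] = field(default_factory=dict)
    residuals: dict[str, list[Anchor]] = field(default_factory=dict)
    arrays: list[TandemArray] = field(default_factory=list)
    units: list[TandemUnit] = field(default_factory=list)


def detect(genome: list[GenomeSequence], config: Config | None = None) -> StageResult:
    """Run the full detection pipeline in memory, per sequence."""
    config = config or Config()
    res = StageResult()
    all_arrays: list[TandemArray] = []
    for seq in genome:
        work = mask_low_complexity(seq, config.dust_window, config.dust_threshold) if config.mask else seq
        anchors = find_anchors(work, config.scoring, T=config.max_copy_gap)
        anchors = dedupe_anchors(anchors)
        res.anchors[seq.name] = anchors
        chaining = chain_anchors(
            anchors, L=config.max_chain_gap, k=config.max_out_edges, T=config.max_copy_gap
        )
        res.chains[seq.name] = chaining.chains
        res.residuals[seq.name] = chaining.residual_anchors
        violations = check_chain_set(chaining.chains, config.max_copy_gap)
        if violations:
            raise AssertionError(f"inconsistent chain set on {seq.name}: {violations[:3]}")
        g2 = build_overlap_graph(chaining.chains, chaining.residual_anchors, config.min_overlap)
        arrays = delineate_arrays(
            g2, config.max_chain_gap, work,
            chains=chaining.chains, residual_anchors=chaining.residual_anchors,
        )
        kept = []
        for ta in arrays:
            unit = select_reference_unit(
                ta, work, config.scoring, config.min_unit_length
            )
            if len(unit.residues) < config.min_unit_length:
                logger.info("discarding array %s: unit below minimum length", ta.id)
                continue
            ta.reference_unit = unit
            if unit.unresolved:
                ta.flags.add("unresolved_unit")
            kept.append(ta)
        for ta in kept:
            reconstruct_array(
                ta,
                work,
                mode=config.search_mode,
                scheme=config.scoring,
                L=config.max_chain_gap,
                min_unit_fraction=config.min_unit_fraction,
                min_unit_length=config.min_unit_length,
                k=config.max_out_edges,
                max_enlarge=config.max_enlarge,
            )
        all_arrays.extend(kept)
    all_arrays.sort(key=lambda t: (t.region.seq_name, t.region.start, t.region.end))
    units: list[TandemUnit] = []
    for i, ta in enumerate(all_arrays):
        ta.id = f"ta_{i:05d}"
        for u in ta.units:
            u.array_id = ta.id
        units.extend(ta.units)
    units.sort(key=lambda u: (u.interval.seq_name, u.interval.start, u.interval.end))
    for i, u in enumerate(units):
        u.id = f"tu_{i:05d}"
    res.arrays = all_arrays
    res.units = units
    return res


def run_pipeline(config: Config, genome_path, out_dir) -> dict:
    """Run detection on a FASTA and write every artifact plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(genome_path)
    result = detect(genome, config)

    anchors_flat = [a for seq in genome for a in result.anchors[seq.name]]
    chains_flat = [c for seq in genome for c in result.chains[seq.name]]
    write_anchor_table(anchors_flat, out / "anchors.tsv")
    # re-number chains globally for the serialized table
    for i, c in enumerate(chains_flat):
        c.id = i
    write_chain_table(chains_flat, out / "chains.tsv")
    write_features(result.arrays, result.units, out / "predictions.gff3", "gff3")
    write_features(result.arrays, result.units, out / "predictions.bed", "bed")
    unit_seqs = [
        GenomeSequence(f"{ta.id}_unit", ta.reference_unit.residues)
        for ta in result.arrays
        if ta.reference_unit is not None
    ]
    if unit_seqs:
        write_fasta(unit_seqs, out / "units.fa")

    summary_lines = ["#array_id\tseq\tregion_start\tregion_end\tn_tus\tmean_tu_length"]
    for ta in result.arrays:
        mean_len = (
            sum(u.interval.length() for u in ta.units) / len(ta.units) if ta.units else 0.0
        )
        summary_lines.append(
            f"{ta.id}\t{ta.region.seq_name}\t{ta.region.start}\t{ta.region.end}\t"
            f"{len(ta.units)}\t{mean_len:.1f}"
        )
    (out / "summary.tsv").write_text("\n".join(summary_lines) + "\n")

    genome_len = sum(s.length for s in genome)
    ta_cov = _coverage(((ta.region.seq_name, ta.region.start, ta.region.end) for ta in result.arrays))
    tu_cov = _coverage(((u.interval.seq_name, u.interval.start, u.interval.end) for u in result.units))
    n_anchors = len(anchors_flat)
    n_chains = len(chains_flat)
    manifest = {
        "version": __version__,
        "config": _jsonable(config.to_dict()),
        "counts": {
            "n_sequences": len(genome),
            "genome_length": genome_len,
            "n_anchors": n_anchors,
            "n_chains": n_chains,
            "mean_anchors_per_chain": (
                round(sum(len(c.anchors) for c in chains_flat) / n_chains, 3) if n_chains else 0.0
            ),
            "n_tandem_arrays": len(result.arrays),
            "n_tandem_units": len(result.units),
            "ta_genome_fraction": round(ta_cov / genome_len, 4),
            "tu_genome_fraction": round(tu_cov / genome_len, 4),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _coverage(items) -> int:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq, s, e in items:
        by_seq.setdefault(seq, []).append((s, e))
    total = 0
    for ivs in by_seq.values():
        ivs.sort()
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
    return total


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x
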