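"""Evaluation against annotation-derived reference tandem gene arrays.

The truth set is built the way protein-based tandem-duplication surveys
build theirs: genes longer than 500 bp whose proteins hit each other
(e-value <= 1e-5, both coverages >= 70%) and that lie less than T apart are
connected; connected components with 2+ genes are tandem gene arrays (TGA)
whose members are tandem gene units (TGU). Detection criteria: a TGU is
detected when a single predicted TU covers at least 70% of it; a TGA is
detected when a TA covers strictly more than 70% of its span AND at least
one member TGU is detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
import networkx as nx
import pandas as pd

from .seqio import Interval, overlap_fraction

logger = logging.getLogger(__name__)

DETECTION_THRESHOLD = 0.70  # TGU/feature coverage: >= ; TGA span coverage: strict >
MIN_GENE_LENGTH = 500
MAX_EVALUE = 1e-5
MIN_HIT_COVERAGE = 0.70


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: Interval
    reference_transcript_id: str = ""
    protein_length: int = 0


@dataclass
class ReferenceTGA:
    tga_id: str
    genes: list[GeneRecord]
    span: Interval


@dataclass(frozen=True)
class ProteinHit:
    query_gene: str
    subject_gene: str
    evalue: float
    query_coverage: float
    subject_coverage: float

    def __post_init__(self):
        if not (0 <= self.query_coverage <= 1 and 0 <= self.subject_coverage <= 1):
            raise ValueError("coverages must lie in [0, 1]")
        if self.query_gene == self.subject_gene:
            raise ValueError("self-hit")


def read_genes_gff3(path, min_length: int = MIN_GENE_LENGTH) -> list[GeneRecord]:
    """Gene records from a GFF3 (features of type gene, length > min_length)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for f in db.features_of_type("gene"):
        iv = Interval(f.seqid, f.start - 1, f.end)
        if iv.length() <= min_length:
            continue
        gid = f.attributes.get("ID", [f.id])[0]
        genes.append(GeneRecord(gene_id=gid, interval=iv))
    genes.sort(key=lambda g: (g.interval.seq_name, g.interval.start))
    return genes


def read_feature_classes(path) -> list[tuple[str, Interval]]:
    """(feature class, interval) for every feature in a GFF3."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for f in db.all_features():
        out.append((f.featuretype, Interval(f.seqid, f.start - 1, f.end)))
    return out


def read_protein_hits(path) -> list[ProteinHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            q, s, ev, qc, sc = parts
            hits.append(ProteinHit(q, s, float(ev), float(qc), float(sc)))
    return hits


def build_reference_tgas(
    genes: list[GeneRecord], hits: list[ProteinHit], T: int = 150_000
) -> list[ReferenceTGA]:
    """Connect genes by qualifying protein hits; components of 2+ genes are TGAs.

    An edge requires e-value <= 1e-5, both coverages >= 0.70 and a gene gap
    below T.
    """
    by_id = {g.gene_id: g for g in genes}
    unknown = sorted(
        {h.query_gene for h in hits if h.query_gene not in by_id}
        | {h.subject_gene for h in hits if h.subject_gene not in by_id}
    )
    if unknown:
        raise ValueError(f"hits reference unknown genes: {', '.join(unknown)}")
    g = nx.Graph()
    g.add_nodes_from(by_id)
    for h in hits:
        if h.evalue > MAX_EVALUE:
            continue
        if h.query_coverage < MIN_HIT_COVERAGE or h.subject_coverage < MIN_HIT_COVERAGE:
            continue
        a, b = by_id[h.query_gene], by_id[h.subject_gene]
        if a.interval.seq_name != b.interval.seq_name:
            continue
        u, v = sorted((a.interval, b.interval))
        gap = max(0, v.start - u.end)
        if gap >= T:
            continue
        g.add_edge(h.query_gene, h.subject_gene)
    tgas = []
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g) if len(c) >= 2),
        key=lambda c: by_id[c[0]].interval,
    )
    for i, comp in enumerate(comps):
        members = sorted((by_id[gid] for gid in comp), key=lambda x: x.interval)
        span = Interval(
            members[0].interval.seq_name,
            min(m.interval.start for m in members),
            max(m.interval.end for m in members),
        )
        tgas.append(ReferenceTGA(tga_id=f"tga_{i:04d}", genes=members, span=span))
    return tgas


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _covered_by_single(target: Interval, predictions: list[Interval], frac: float, strict: bool) -> bool:
    for p in predictions:
        cov = overlap_fraction(target, p, "first")
        if (cov > frac) if strict else (cov >= frac):
            return True
    return False


def score_detection(
    tgas: list[ReferenceTGA], arrays: list, units: list
) -> pd.DataFrame:
    """Sensitivity table: detected TGAs and TGUs with percentages.

    A TGU is detected when one TU covers >= 70% of it; a TGA when one TA
    covers > 70% (strict) of its span and at least one member TGU is
    detected.
    """
    tu_ivs = [u.interval for u in units]
    ta_ivs = [a.region for a in arrays]
    n_tga = len(tgas)
    n_tgu = sum(len(t.genes) for t in tgas)
    det_tga = 0
    det_tgu = 0
    for tga in tgas:
        member_detected = []
        for gene in tga.genes:
            d = _covered_by_single(gene.interval, tu_ivs, DETECTION_THRESHOLD, strict=False)
            member_detected.append(d)
            det_tgu += int(d)
        span_ok = _covered_by_single(tga.span, ta_ivs, DETECTION_THRESHOLD, strict=True)
        if span_ok and any(member_detected):
            det_tga += 1
    rows = [
        ("TGA", n_tga, det_tga, round(100.0 * det_tga / n_tga, 1) if n_tga else 0.0),
        ("TGU", n_tgu, det_tgu, round(100.0 * det_tgu / n_tgu, 1) if n_tgu else 0.0),
    ]
    return pd.DataFrame(rows, columns=["class", "total", "detected", "percent"])


def annotation_overlap_report(units: list, features: list[tuple[str, Interval]]) -> pd.DataFrame:
    """Per-feature-class detection table (class, total, detected, percent).

    A feature is detected when a single TU covers at least 70% of it."""
    tu_ivs = [u.interval for u in units]
    classes: dict[str, list[int]] = {}
    for ftype, iv in features:
        tot_det = classes.setdefault(ftype, [0, 0])
        tot_det[0] += 1
        if _covered_by_single(iv, tu_ivs, DETECTION_THRESHOLD, strict=False):
            tot_det[1] += 1
    rows = [
        (ftype, td[0], td[1], round(100.0 * td[1] / td[0], 1))
        for ftype, td in sorted(classes.items())
    ]
    return pd.DataFrame(rows, columns=["class", "total", "detected", "percent"])


def orphan_stats(arrays: list, units: list, features: list[tuple[str, Interval]]) -> pd.DataFrame:
    """Orphan vs other TA statistics.

    A TU is orphan when it neither covers 70% of any feature nor is itself
    covered 70% by one; a TA is orphan when every one of its TUs is orphan.
    Reports counts, mean TU size and mean TUs per TA for both groups."""
    f_ivs = [iv for _, iv in features]

    def tu_orphan(iv: Interval) -> bool:
        for f in f_ivs:
            if overlap_fraction(f, iv, "first") >= DETECTION_THRESHOLD:
                return False
            if overlap_fraction(iv, f, "first") >= DETECTION_THRESHOLD:
                return False
        return True

    groups = {"orphan": [], "other": []}
    for ta in arrays:
        tus = [u for u in units if u.array_id == ta.id]
        if not tus:
            continue
        orphan = all(tu_orphan(u.interval) for u in tus)
        groups["orphan" if orphan else "other"].append(tus)
    rows = []
    for label in ("orphan", "other"):
        tas = groups[label]
        n_tus = sum(len(t) for t in tas)
        mean_size = (
            sum(u.interval.length() for t in tas for u in t) / n_tus if n_tus else 0.0
        )
        mean_n = n_tus / len(tas) if tas else 0.0
        rows.append((label, len(tas), n_tus, round(mean_size, 1), round(mean_n, 2)))
    return pd.DataFrame(
        rows, columns=["group", "n_tas", "n_tus", "mean_tu_size", "mean_tus_per_ta"]
    )
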