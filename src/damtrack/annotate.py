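"""Peak annotation against a gene model: nearest TSS and feature class.

Peaks are classified at their midpoint with precedence
promoter > exon > intron > downstream > distal_intergenic.  The promoter
window defaults to 5 kb either side of the TSS (DamID peaks are broad —
their resolution is set by GATC density — so a generous promoter window is
the field's convention); the downstream window past a gene's 3' end
defaults to 3 kb.  Nearest-TSS ties break lexicographically by gene_id so
annotation is deterministic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

FEATURE_CLASSES = ("promoter", "exon", "intron", "downstream", "distal_intergenic")


class AnnotationError(ValueError):
    pass


@dataclass
class Gene:
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    start: int  # 0-based half-open
    end: int
    exons: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneModel:
    genes: List[Gene]

    def __post_init__(self) -> None:
        self.by_contig: Dict[str, List[Gene]] = {}
        for g in self.genes:
            self.by_contig.setdefault(g.contig, []).append(g)


@dataclass
class PeakAnnotation:
    peak: object
    nearest_gene_id: str
    nearest_gene_name: str
    signed_distance_to_tss: int  # negative = upstream of the TSS w.r.t. gene strand
    feature_class: str


def parse_gtf(path) -> GeneModel:
    """Parse gene and exon features from a GTF (1-based closed -> 0-based
    half-open).  Genes without exon records are treated as single-exon;
    duplicate gene_ids and malformed attribute fields are hard errors naming
    the line."""
    genes: Dict[str, Gene] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as handle:
        for i, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"malformed GTF line {i} in {path}: expected 9 fields")
            contig, _, feature, start, end, _, strand, _, attrs = parts
            if feature not in ("gene", "exon"):
                continue
            attr_map = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr_map:
                raise AnnotationError(f"malformed GTF attributes on line {i} in {path}: no gene_id")
            gid = attr_map["gene_id"]
            s0, e0 = int(start) - 1, int(end)
            if feature == "gene":
                if gid in genes:
                    raise AnnotationError(f"duplicate gene_id {gid!r} (GTF line {i})")
                genes[gid] = Gene(
                    gene_id=gid,
                    gene_name=attr_map.get("gene_name", gid),
                    contig=contig,
                    strand=strand,
                    start=s0,
                    end=e0,
                )
            else:
                exons.setdefault(gid, []).append((s0, e0))
    for gid, ex in exons.items():
        if gid in genes:
            genes[gid].exons = sorted(ex)
        else:
            raise AnnotationError(f"exon for unknown gene_id {gid!r} in {path}")
    for g in genes.values():
        if not g.exons:
            g.exons = [(g.start, g.end)]
    if not genes:
        raise AnnotationError(f"no gene features in {path}")
    return GeneModel(genes=sorted(genes.values(), key=lambda g: g.gene_id))


def annotate_peak(
    peak,
    model: GeneModel,
    promoter_window: int = 5000,
    downstream_window: int = 3000,
) -> PeakAnnotation:
    """Annotate one peak: nearest TSS from the peak midpoint (ties break to
    the lexicographically smaller gene_id) and feature class with precedence
    promoter > exon > intron > downstream > distal_intergenic."""
    mid = (peak.start + peak.end) // 2
    genes = model.by_contig.get(peak.contig)
    if not genes:
        logger.warning("annotate_peak: contig %r absent from gene model", peak.contig)
        return PeakAnnotation(peak, "", "", 0, "distal_intergenic")
    nearest = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
    raw = mid - nearest.tss
    signed = raw if nearest.strand == "+" else -raw
    if abs(signed) <= promoter_window:
        feature = "promoter"
    else:
        containing = [g for g in genes if g.start <= mid < g.end]
        if containing:
            in_exon = any(s <= mid < e for g in containing for s, e in g.exons)
            feature = "exon" if in_exon else "intron"
        else:
            downstream = False
            for g in genes:
                if g.strand == "+" and g.end <= mid < g.end + downstream_window:
                    downstream = True
                elif g.strand == "-" and g.start - downstream_window <= mid < g.start:
                    downstream = True
            feature = "downstream" if downstream else "distal_intergenic"
    return PeakAnnotation(
        peak=peak,
        nearest_gene_id=nearest.gene_id,
        nearest_gene_name=nearest.gene_name,
        signed_distance_to_tss=int(signed),
        feature_class=feature,
    )


def annotate_peaks(
    peaks: Sequence, model: GeneModel, promoter_window: int = 5000, downstream_window: int = 3000
) -> List[PeakAnnotation]:
    return [annotate_peak(p, model, promoter_window, downstream_window) for p in peaks]


def feature_distribution(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    """Counts and proportions per feature class (proportions sum to 1)."""
    if not annotations:
        raise AnnotationError("no annotations")
    counts = {fc: 0 for fc in FEATURE_CLASSES}
    for a in annotations:
        counts[a.feature_class] += 1
    total = len(annotations)
    return pd.DataFrame(
        {
            "feature_class": list(counts),
            "count": list(counts.values()),
            "proportion": [c / total for c in counts.values()],
        }
    )


def annotations_to_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "contig": a.peak.contig,
                "start": a.peak.start,
                "end": a.peak.end,
                "nearest_gene_id": a.nearest_gene_id,
                "nearest_gene_name": a.nearest_gene_name,
                "distance_to_tss": a.signed_distance_to_tss,
                "feature_class": a.feature_class,
            }
        )
    return pd.DataFrame(rows)
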