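"""Alignment ingest: SAM/BAM parsing, quality/decoy filtering, and
reconstruction of DamID fragments from single-end reads.

DamID amplicons span the interval between two methylated GATC sites, so a
short single-end read only covers the 5' portion of the molecule it came
from.  Following common DamID practice, single-end reads are extended in
their 3' direction to 300 bp or the nearest GATC fragment boundary,
whichever comes first, to approximate the original fragment.  Paired-end
proper pairs already delimit the template and pass through unmodified.

Reads that match the Dam-fusion expression construct (transfected plasmid)
can dominate libraries through self-targeting; an optional decoy filter
drops any read sharing an exact k-mer (k >= 11, default 21) with a decoy
sequence or its reverse complement.  This is a deterministic, conservative
stand-in for alignment-based pre-filtering; users wanting true
alignment-based decoy removal should pre-filter upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .genome import GatcFragmentMap


class IngestError(ValueError):
    pass


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignedRead:
    contig: str
    start: int  # 0-based leftmost
    end: int  # half-open rightmost
    strand: str  # '+' or '-'
    mapq: int
    is_paired: bool = False
    is_proper_pair: bool = False
    template_length: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IngestError(f"read with start >= end: {self.contig}:{self.start}-{self.end}")


@dataclass
class ExtendedFragment:
    """A reconstructed DamID fragment (extended read or paired-end template)."""

    contig: str
    start: int
    end: int
    source_strand: str = "+"
    was_extended: bool = False
    clipped_at_gatc: bool = False


class DecoyIndex:
    """Exact shared-k-mer screen against decoy sequences (plasmid / fusion construct).

    A read is flagged iff it shares at least one length-k exact k-mer with any
    decoy sequence or its reverse complement.
    """

    def __init__(self, decoys: Dict[str, str], k: int = 21):
        if k < 11:
            raise IngestError("decoy_seed_length must be >= 11")
        self.k = k
        self.kmers: set = set()
        for seq in decoys.values():
            seq = seq.upper()
            for s in (seq, reverse_complement(seq)):
                for i in range(len(s) - k + 1):
                    self.kmers.add(s[i : i + k])

    def matches(self, read_seq: str) -> bool:
        if read_seq is None:
            return False
        read_seq = read_seq.upper()
        k = self.k
        for i in range(len(read_seq) - k + 1):
            if read_seq[i : i + k] in self.kmers:
                return True
        return False


def decoy_filter(read_seq: str, decoys: DecoyIndex) -> bool:
    """Return True if the read should be KEPT (no shared k-mer with a decoy)."""
    return not decoys.matches(read_seq)


@dataclass
class ReadFilterConfig:
    min_mapq: int = 30
    decoys: Optional[DecoyIndex] = None

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise IngestError("min_mapq must be >= 0")


@dataclass
class AlignmentStats:
    sample_id: str = ""
    total: int = 0
    kept: int = 0
    dropped: Dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def rate(self) -> float:
        return self.kept / self.total if self.total else 0.0


def parse_alignments(
    path,
    filter_config: Optional[ReadFilterConfig] = None,
    known_contigs: Optional[Iterable[str]] = None,
    sample_id: str = "",
) -> Tuple[List[AlignedRead], AlignmentStats]:
    """Parse a SAM/BAM file, dropping unmapped / secondary / supplementary /
    low-MAPQ / decoy-matching records.

    Returns the kept primary records and per-reason drop counts (the input
    to the alignment-rate QC table).  If *known_contigs* is given, a header
    contig absent from it is a hard error (fragment-map mismatch).
    """
    cfg = filter_config or ReadFilterConfig()
    stats = AlignmentStats(sample_id=sample_id)
    kept: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        if known_contigs is not None:
            known = set(known_contigs)
            for ref in handle.references:
                if ref not in known:
                    raise IngestError(
                        f"contig {ref!r} in alignment header absent from the fragment map"
                    )
        for rec in handle:
            stats.total += 1
            if rec.is_unmapped:
                stats.drop("unmapped")
                continue
            if rec.is_secondary:
                stats.drop("secondary")
                continue
            if rec.is_supplementary:
                stats.drop("supplementary")
                continue
            if rec.mapping_quality < cfg.min_mapq:
                stats.drop("low_mapq")
                continue
            if cfg.decoys is not None and cfg.decoys.matches(rec.query_sequence):
                stats.drop("decoy")
                continue
            stats.kept += 1
            kept.append(
                AlignedRead(
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    is_paired=rec.is_paired,
                    is_proper_pair=rec.is_proper_pair,
                    template_length=rec.template_length,
                )
            )
    return kept, stats


def extend_single_end(
    read: AlignedRead, fmap: GatcFragmentMap, target_length: int = 300
) -> ExtendedFragment:
    """Extend a single-end read in its 3' direction to *target_length* bp or
    the nearest GATC fragment boundary, whichever comes first.

    Reads already >= target_length are left unextended. The extension never
    crosses a fragment boundary on the 3' side and is clipped to the contig.
    """
    if read.contig not in fmap.boundaries:
        raise IngestError(f"read on contig {read.contig!r} absent from fragment map")
    b = fmap.boundaries[read.contig]
    length = fmap.lengths[read.contig]
    if read.start < 0 or read.end > length:
        raise IngestError(
            f"read outside contig bounds: {read.contig}:{read.start}-{read.end} (len {length})"
        )
    read_len = read.end - read.start
    if read_len >= target_length:
        return ExtendedFragment(read.contig, read.start, read.end, read.strand, False, False)
    if read.strand == "+":
        # nearest boundary at or beyond the current 3' end
        i = int(np.searchsorted(b, read.end, side="left"))
        boundary = int(b[i]) if i < len(b) else length
        new_end = min(read.start + target_length, boundary)
        return ExtendedFragment(
            read.contig,
            read.start,
            new_end,
            "+",
            was_extended=new_end > read.end,
            clipped_at_gatc=new_end == boundary,
        )
    else:
        i = int(np.searchsorted(b, read.start, side="right")) - 1
        boundary = int(b[i]) if i >= 0 else 0
        new_start = max(read.end - target_length, boundary)
        return ExtendedFragment(
            read.contig,
            new_start,
            read.end,
            "-",
            was_extended=new_start < read.start,
            clipped_at_gatc=new_start == boundary,
        )


def reads_to_fragments(
    reads: Iterable[AlignedRead],
    fmap: GatcFragmentMap,
    paired: bool = False,
    target_length: int = 300,
    stats: Optional[AlignmentStats] = None,
) -> List[ExtendedFragment]:
    """Convert kept alignments into DamID fragments.

    Single-end mode extends each read (see :func:`extend_single_end`).
    Paired mode emits one fragment per proper pair, spanning leftmost start
    to rightmost end (taken from the leftmost mate, template_length > 0);
    discordant pairs are dropped and counted.
    """
    fragments: List[ExtendedFragment] = []
    for read in reads:
        if paired:
            if not (read.is_paired and read.is_proper_pair):
                if stats is not None:
                    stats.drop("discordant")
                continue
            if read.template_length <= 0:
                continue  # rightmost mate of the pair; fragment emitted from leftmost
            fragments.append(
                ExtendedFragment(
                    read.contig,
                    read.start,
                    read.start + read.template_length,
                    read.strand,
                    False,
                    False,
                )
            )
        else:
            fragments.append(extend_single_end(read, fmap, target_length))
    return fragments


def alignment_rate_summary(stats_list: Iterable[AlignmentStats]) -> pd.DataFrame:
    """Tabulate per-sample totals, kept fraction, and drop reasons."""
    stats_list = list(stats_list)
    reasons = sorted({r for s in stats_list for r in s.dropped})
    rows = []
    for s in stats_list:
        row = {
            "sample_id": s.sample_id,
            "total": s.total,
            "kept": s.kept,
            "rate": s.rate,
            "warning": s.total == 0,
        }
        for r in reasons:
            row[f"dropped_{r}"] = s.dropped.get(r, 0)
        rows.append(row)
    return pd.DataFrame(rows)
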