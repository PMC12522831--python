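"""Genome handling for DamID-seq: FASTA I/O, masking, GATC motif scanning and
the GATC fragment map.

DamID signal has GATC-site resolution: the Dam methyltransferase marks
adenines in GATC motifs, and the sequenced amplicons are the genomic
intervals between consecutive methylated sites.  All downstream
quantification in this package is therefore expressed over the *GATC
fragment map*: the partition of each contig into intervals bounded by GATC
motifs.  Fragment boundaries are placed at motif midpoints (position ``p+2``
for a motif starting at ``p``): the palindromic GATC is cut within the motif,
and the midpoint convention assigns half the motif to each flank and is
strand-symmetric.  The convention is recorded in the map's metadata.

All coordinates are 0-based half-open, matching BED.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
MOTIF = "GATC"

#: boundary convention identifier stored in GatcFragmentMap.metadata
BOUNDARY_CONVENTION = "motif_midpoint"


class GenomeError(ValueError):
    """Raised for invalid genome input (empty FASTA, duplicate contigs, ...)."""


@dataclass
class GenomeSequence:
    """An in-memory genome: ordered mapping of contig name -> uppercase sequence.

    Sequences are over the alphabet {A, C, G, T, N}.
    """

    contigs: Dict[str, str]

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __post_init__(self) -> None:
        for name in self.contigs:
            if not name:
                raise GenomeError("empty contig name")


@dataclass
class MaskSpec:
    """Regions to be hard-masked (replaced by N), e.g. the Dam-fusion gene locus.

    Masking the investigated gene prevents self-targeting reads from the
    expression construct from contributing signal at its genomic locus.
    Intervals are (contig, start, end), 0-based half-open.
    """

    regions: List[Tuple[str, int, int]] = field(default_factory=list)

    def validate(self, genome: GenomeSequence) -> None:
        lengths = genome.lengths
        for contig, start, end in self.regions:
            if contig not in lengths:
                raise GenomeError(f"mask interval on unknown contig: ({contig}, {start}, {end})")
            if not (0 <= start < end <= lengths[contig]):
                raise GenomeError(
                    f"mask interval out of bounds for {contig} "
                    f"(length {lengths[contig]}): ({contig}, {start}, {end})"
                )


@dataclass
class GatcIndex:
    """Per-contig sorted 0-based start positions of the GATC motif."""

    sites: Dict[str, np.ndarray]

    def n_sites(self) -> int:
        return int(sum(len(v) for v in self.sites.values()))


@dataclass
class GatcFragmentMap:
    """The genome partitioned into GATC fragments.

    ``boundaries[contig]`` is a strictly increasing array starting at 0 and
    ending at the contig length; fragment *i* of a contig is
    ``[boundaries[i], boundaries[i+1])``.  Fragment ids are global, assigned
    in (contig order, start) order.
    """

    boundaries: Dict[str, np.ndarray]
    lengths: Dict[str, int]
    metadata: Dict[str, str] = field(default_factory=lambda: {"boundary_convention": BOUNDARY_CONVENTION})

    def __post_init__(self) -> None:
        offset = 0
        self._id_offsets: Dict[str, int] = {}
        for contig, b in self.boundaries.items():
            b = np.asarray(b, dtype=np.int64)
            self.boundaries[contig] = b
            if b[0] != 0 or b[-1] != self.lengths[contig]:
                raise GenomeError(f"fragment boundaries of {contig} do not span the contig")
            if np.any(np.diff(b) <= 0):
                raise GenomeError(f"fragment boundaries of {contig} not strictly increasing")
            self._id_offsets[contig] = offset
            offset += len(b) - 1
        self._n_fragments = offset

    @property
    def n_fragments(self) -> int:
        return self._n_fragments

    def id_offset(self, contig: str) -> int:
        return self._id_offsets[contig]

    def n_contig_fragments(self, contig: str) -> int:
        return len(self.boundaries[contig]) - 1

    def iter_fragments(self) -> Iterator[Tuple[str, int, int, int]]:
        """Yield (contig, start, end, fragment_id) in id order."""
        for contig, b in self.boundaries.items():
            off = self._id_offsets[contig]
            for i in range(len(b) - 1):
                yield contig, int(b[i]), int(b[i + 1]), off + i

    def fragment_intervals(self) -> "np.ndarray":
        """(n_fragments, 2) array of start/end; contig via id_offset ranges."""
        out = np.empty((self.n_fragments, 2), dtype=np.int64)
        for contig, b in self.boundaries.items():
            off = self._id_offsets[contig]
            out[off : off + len(b) - 1, 0] = b[:-1]
            out[off : off + len(b) - 1, 1] = b[1:]
        return out


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> GenomeSequence:
    """Read a (optionally gzipped) FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased (soft-masking is discarded); characters outside
    {A,C,G,T,N} are mapped to N, with the replacement count logged.
    Duplicate contig names and empty files are hard errors.
    """
    contigs: Dict[str, str] = {}
    n_replaced = 0
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in contigs:
                raise GenomeError(f"duplicate contig name in FASTA: {record.id}")
            seq = str(record.seq).upper()
            if not set(seq) <= _VALID:
                cleaned = []
                for ch in seq:
                    if ch in _VALID:
                        cleaned.append(ch)
                    else:
                        cleaned.append("N")
                        n_replaced += 1
                seq = "".join(cleaned)
            contigs[record.id] = seq
    if not contigs:
        raise GenomeError(f"no FASTA records in {path}")
    if n_replaced:
        logger.warning("read_fasta: replaced %d non-ACGTN characters with N", n_replaced)
    return GenomeSequence(contigs=contigs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with _open_maybe_gzip(path, "wt") as out:
        for name, seq in genome.contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def mask_genome(genome: GenomeSequence, mask: MaskSpec) -> GenomeSequence:
    """Return a copy of *genome* with all bases in *mask* replaced by N.

    The input genome is not mutated; overlapping mask intervals behave as
    their union. Idempotent.
    """
    mask.validate(genome)
    per_contig: Dict[str, List[Tuple[int, int]]] = {}
    for contig, start, end in mask.regions:
        per_contig.setdefault(contig, []).append((start, end))
    new_contigs: Dict[str, str] = {}
    for name, seq in genome.contigs.items():
        if name not in per_contig:
            new_contigs[name] = seq
            continue
        buf = bytearray(seq, "ascii")
        for start, end in per_contig[name]:
            buf[start:end] = b"N" * (end - start)
        new_contigs[name] = buf.decode("ascii")
    return GenomeSequence(contigs=new_contigs)


def scan_motif(seq: str, motif: str = MOTIF) -> np.ndarray:
    """Exact-match positions of *motif* in *seq*, overlap-aware.

    GATC cannot overlap itself, but the scanner steps by one so that any
    motif is handled correctly. N never matches (N is not part of the motif
    and exact matching is used).
    """
    positions: List[int] = []
    pos = seq.find(motif)
    while pos != -1:
        positions.append(pos)
        pos = seq.find(motif, pos + 1)
    return np.asarray(positions, dtype=np.int64)


def scan_gatc_sites(genome: GenomeSequence) -> GatcIndex:
    """Locate every GATC motif per contig (sorted 0-based starts)."""
    return GatcIndex(sites={name: scan_motif(seq) for name, seq in genome.contigs.items()})


def build_fragment_map(index: GatcIndex, lengths: Dict[str, int]) -> GatcFragmentMap:
    """Partition contigs into GATC fragments with boundaries at motif midpoints.

    A contig with *k* motifs yields *k+1* fragments; with no motif, a single
    fragment spanning the contig.
    """
    boundaries: Dict[str, np.ndarray] = {}
    for contig, length in lengths.items():
        sites = index.sites.get(contig, np.empty(0, dtype=np.int64))
        if len(sites) and (sites[0] < 0 or sites[-1] + len(MOTIF) > length):
            raise GenomeError(f"GATC site out of bounds on {contig}")
        b = np.concatenate(([0], np.asarray(sites, dtype=np.int64) + 2, [length]))
        boundaries[contig] = b
    return GatcFragmentMap(boundaries=boundaries, lengths=dict(lengths))


def write_gatc_sites_bed(index: GatcIndex, path) -> None:
    """Write GATC motif occurrences as 4 bp BED intervals."""
    with open(path, "w") as out:
        for contig, sites in index.sites.items():
            for p in sites:
                out.write(f"{contig}\t{p}\t{p + len(MOTIF)}\n")


def read_gatc_sites_bed(path) -> GatcIndex:
    sites: Dict[str, List[int]] = {}
    with open(path) as handle:
        for i, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeError(f"malformed BED line {i} in {path}")
            sites.setdefault(parts[0], []).append(int(parts[1]))
    return GatcIndex(sites={c: np.asarray(sorted(v), dtype=np.int64) for c, v in sites.items()})


def write_fragments_bed(fmap: GatcFragmentMap, path) -> None:
    """Write the fragment map as BED4 (name = global fragment id)."""
    with open(path, "w") as out:
        for contig, start, end, fid in fmap.iter_fragments():
            out.write(f"{contig}\t{start}\t{end}\tfrag_{fid}\n")


def read_fragments_bed(path) -> GatcFragmentMap:
    """Reconstruct a fragment map from its BED4 representation."""
    per_contig: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as handle:
        for i, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeError(f"malformed BED line {i} in {path}")
            per_contig.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    boundaries: Dict[str, np.ndarray] = {}
    lengths: Dict[str, int] = {}
    for contig, ivals in per_contig.items():
        ivals.sort()
        starts = [s for s, _ in ivals]
        boundaries[contig] = np.asarray(starts + [ivals[-1][1]], dtype=np.int64)
        lengths[contig] = ivals[-1][1]
    return GatcFragmentMap(boundaries=boundaries, lengths=lengths)


def read_mask_bed(path) -> MaskSpec:
    regions: List[Tuple[str, int, int]] = []
    with open(path) as handle:
        for i, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeError(f"malformed BED line {i} in {path}")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return MaskSpec(regions=regions)
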