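"""Synthetic DamID-seq data with ground truth.

The generator emulates the assay's data model: a small multi-contig genome
with controllable GATC motif density; a per-fragment accessibility
background (log-normal, capturing the heavy-tailed coverage untethered Dam
produces on open chromatin); planted binding intervals where Dam-fusion
samples are enriched by a multiplicative fold; and short reads that start
at GATC fragment 5' boundaries, as DamID amplicons begin at DpnI cut sites.
Reads starting at fragment boundaries also make single-end extension
exactly recover fragments, giving the extension logic a sharp test.

Defaults mirror a desk-scale DamID experiment: 2 x 100 kb contigs, ~4 GATC
motifs per kb (the genome-wide ~1/256 bp expectation for a 4-mer), 3
Dam-fusion + 2 Dam-only samples, 8-fold enrichment at planted sites, and
200,000 50 bp single-end reads per sample.

All randomness flows from ``SimulationConfig.rng_seed``; per-sample streams
are derived deterministically, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from .genome import (
    GatcFragmentMap,
    GatcIndex,
    GenomeSequence,
    build_fragment_map,
    scan_gatc_sites,
    scan_motif,
    write_fasta,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_contigs: int = 2
    contig_length: int = 100_000
    gatc_density: float = 4.0  # expected motifs per kb
    n_sites: int = 16  # planted binding intervals across the genome
    site_width: int = 1000
    enrichment_fold: float = 8.0
    background_sigma: float = 0.5  # log-normal accessibility spread
    n_reads: int = 200_000
    read_length: int = 50
    paired: bool = False
    n_fusion_samples: int = 3
    n_dam_samples: int = 2
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "n_contigs",
            "contig_length",
            "n_sites",
            "site_width",
            "n_reads",
            "read_length",
            "n_fusion_samples",
            "n_dam_samples",
        ):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.enrichment_fold < 1:
            raise SimulationError("enrichment_fold must be >= 1")
        if self.gatc_density < 0:
            raise SimulationError("gatc_density must be >= 0")
        if self.gatc_density > 250:
            raise SimulationError("gatc_density infeasible: motifs are 4 bp")
        if self.n_sites * self.site_width > self.n_contigs * self.contig_length // 2:
            raise SimulationError("planted sites would cover more than half the genome")


def preset(name: str) -> SimulationConfig:
    """Named configurations: 'small' (the documented study conditions) and
    'tiny' (fast unit-test scale)."""
    if name == "small":
        return SimulationConfig()
    if name == "tiny":
        return SimulationConfig(
            n_contigs=1,
            contig_length=20_000,
            n_sites=4,
            site_width=800,
            n_reads=20_000,
            n_fusion_samples=2,
            n_dam_samples=1,
        )
    raise SimulationError(f"unknown preset {name!r}")


@dataclass
class SimulationTruth:
    """Ground truth of a simulation: planted binding sites, per-fragment
    accessibility background, planted GATC positions, and per-sample read
    provenance counts."""

    sites: List[Tuple[str, int, int]]
    background: np.ndarray  # per-fragment accessibility weight
    site_fragment_mask: np.ndarray  # fragment overlaps a planted site
    planted_gatc: Dict[str, np.ndarray]
    read_counts: Dict[str, np.ndarray] = field(default_factory=dict)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _destroy_motifs(seq: bytearray) -> None:
    """Mutate away every GATC occurrence (A at offset 1 -> C), rescanning
    until none remain (mutation cannot loop: it only removes A's)."""
    while True:
        positions = scan_motif(seq.decode("ascii"))
        if len(positions) == 0:
            return
        for p in positions:
            seq[p + 1] = ord("C")


def simulate_genome(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[GenomeSequence, GatcIndex, Dict[str, np.ndarray]]:
    """Generate a random genome with GATC motifs planted at Poisson-spaced
    positions to reach the target density.

    Spontaneous motifs are first mutated away so the achieved density tracks
    the target; planting can in rare cases create additional motifs at
    junctions, so the returned index is an exact re-scan of the final
    sequence and the planted positions are guaranteed to be a subset of it.
    """
    rng = rng or np.random.default_rng(cfg.rng_seed)
    contigs: Dict[str, str] = {}
    planted: Dict[str, np.ndarray] = {}
    for ci in range(cfg.n_contigs):
        name = f"chr{ci + 1}"
        L = cfg.contig_length
        seq = bytearray(_BASES[rng.integers(0, 4, size=L)].tobytes())
        _destroy_motifs(seq)
        n_plant = int(rng.poisson(cfg.gatc_density * L / 1000.0))
        positions: List[int] = []
        taken = np.zeros(L, dtype=bool)
        attempts = 0
        while len(positions) < n_plant and attempts < 50 * max(n_plant, 1):
            attempts += 1
            p = int(rng.integers(0, L - 3))
            lo, hi = max(0, p - 3), min(L, p + 4)
            if taken[lo:hi].any():
                continue  # collision: re-draw
            taken[p : p + 4] = True
            positions.append(p)
        positions.sort()
        for p in positions:
            seq[p : p + 4] = b"GATC"
        contigs[name] = seq.decode("ascii")
        planted[name] = np.asarray(positions, dtype=np.int64)
    genome = GenomeSequence(contigs=contigs)
    index = scan_gatc_sites(genome)
    return genome, index, planted


def plant_sites(
    cfg: SimulationConfig, lengths: Dict[str, int], rng: np.random.Generator
) -> List[Tuple[str, int, int]]:
    """Draw non-overlapping binding intervals, spread over contigs."""
    names = list(lengths)
    sites: List[Tuple[str, int, int]] = []
    per_contig = {n: [] for n in names}
    for i in range(cfg.n_sites):
        contig = names[i % len(names)]
        L = lengths[contig]
        if cfg.site_width >= L:
            raise SimulationError("site_width exceeds contig length")
        for _ in range(1000):
            s = int(rng.integers(0, L - cfg.site_width))
            e = s + cfg.site_width
            if all(e <= s2 or s >= e2 for s2, e2 in per_contig[contig]):
                per_contig[contig].append((s, e))
                sites.append((contig, s, e))
                break
        else:
            raise SimulationError("could not place non-overlapping sites")
    return sorted(sites)


def make_truth(
    cfg: SimulationConfig,
    fmap: GatcFragmentMap,
    planted_gatc: Dict[str, np.ndarray],
    rng: np.random.Generator,
) -> SimulationTruth:
    """Plant binding sites and draw the per-fragment accessibility background."""
    sites = plant_sites(cfg, fmap.lengths, rng)
    background = rng.lognormal(mean=0.0, sigma=cfg.background_sigma, size=fmap.n_fragments)
    mask = np.zeros(fmap.n_fragments, dtype=bool)
    for contig, s, e in sites:
        b = fmap.boundaries[contig]
        off = fmap.id_offset(contig)
        i0 = int(np.searchsorted(b, s, side="right")) - 1
        i1 = int(np.searchsorted(b, e, side="left")) - 1
        mask[off + i0 : off + i1 + 1] = True
    return SimulationTruth(
        sites=sites, background=background, site_fragment_mask=mask, planted_gatc=planted_gatc
    )


def _sample_rng(cfg: SimulationConfig, role: str, sample_index: int) -> np.random.Generator:
    role_code = {"fusion": 0, "dam_only": 1}[role]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(cfg.rng_seed, role_code, sample_index))
    )


def fragment_weights(cfg: SimulationConfig, truth: SimulationTruth, role: str) -> np.ndarray:
    """Sampling weight per GATC fragment: accessibility background times the
    enrichment fold on site-overlapping fragments for fusion samples."""
    w = truth.background.copy()
    if role == "fusion":
        w[truth.site_fragment_mask] *= cfg.enrichment_fold
    return w


def simulate_reads(
    genome: GenomeSequence,
    fmap: GatcFragmentMap,
    truth: SimulationTruth,
    cfg: SimulationConfig,
    role: str,
    sample_index: int,
    path,
) -> np.ndarray:
    """Draw reads for one sample and write a coordinate-sorted SAM.

    Fragments are drawn with replacement proportionally to their weight; per
    draw a read of ``read_length`` is emitted at the fragment's 5' boundary
    on a random strand (a proper pair spanning the fragment when
    ``cfg.paired``).  Returns the per-fragment draw counts (read provenance).
    """
    if role not in ("fusion", "dam_only"):
        raise SimulationError(f"unknown role {role!r}")
    rng = _sample_rng(cfg, role, sample_index)
    w = fragment_weights(cfg, truth, role)
    p = w / w.sum()
    draws = rng.multinomial(cfg.n_reads, p)
    strands = rng.integers(0, 2, size=cfg.n_reads)  # 0 = forward
    intervals = fmap.fragment_intervals()
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": L} for c, L in fmap.lengths.items()],
        }
    )
    sample_name = f"{role}{sample_index}"
    truth.read_counts[sample_name] = draws
    read_no = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for contig, b in fmap.boundaries.items():
            off = fmap.id_offset(contig)
            n = fmap.n_contig_fragments(contig)
            seq = genome.contigs[contig]
            records: List[Tuple[int, int, bool, int]] = []  # start, end, reverse, frag id
            for i in range(n):
                c = int(draws[off + i])
                if c == 0:
                    continue
                fs, fe = int(intervals[off + i, 0]), int(intervals[off + i, 1])
                rl = min(cfg.read_length, fe - fs)
                for _ in range(c):
                    reverse = bool(strands[read_no % cfg.n_reads])
                    read_no += 1
                    if cfg.paired:
                        records.append((fs, fe, reverse, off + i))
                    elif not reverse:
                        records.append((fs, fs + rl, False, off + i))
                    else:
                        records.append((fe - rl, fe, True, off + i))
            records.sort(key=lambda r: (r[0], r[1]))
            for k, (s, e, reverse, fid) in enumerate(records):
                if cfg.paired:
                    rl = min(cfg.read_length, e - s)
                    qname = f"{sample_name}_{contig}_{k}"
                    a1 = pysam.AlignedSegment(header)
                    a1.query_name = qname
                    a1.reference_name = contig
                    a1.reference_start = s
                    a1.cigartuples = [(0, rl)]
                    a1.query_sequence = seq[s : s + rl]
                    a1.mapping_quality = 60
                    a1.flag = 0x1 | 0x2 | 0x40 | (0x20 if True else 0)
                    a1.next_reference_name = contig
                    a1.next_reference_start = e - rl
                    a1.template_length = e - s
                    a2 = pysam.AlignedSegment(header)
                    a2.query_name = qname
                    a2.reference_name = contig
                    a2.reference_start = e - rl
                    a2.cigartuples = [(0, rl)]
                    a2.query_sequence = seq[e - rl : e]
                    a2.mapping_quality = 60
                    a2.flag = 0x1 | 0x2 | 0x80 | 0x10
                    a2.next_reference_name = contig
                    a2.next_reference_start = s
                    a2.template_length = -(e - s)
                    out.write(a1)
                    out.write(a2)
                else:
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"{sample_name}_{contig}_{k}"
                    a.reference_name = contig
                    a.reference_start = s
                    a.cigartuples = [(0, e - s)]
                    a.query_sequence = seq[s:e]
                    a.mapping_quality = 60
                    a.flag = 0x10 if reverse else 0
                    out.write(a)
    return draws


def write_truth_bed(truth: SimulationTruth, path) -> None:
    with open(path, "w") as out:
        for i, (contig, s, e) in enumerate(truth.sites):
            out.write(f"{contig}\t{s}\t{e}\tsite_{i}\n")


def _toy_gtf(truth: SimulationTruth, lengths: Dict[str, int], path) -> None:
    """Toy gene models: one gene spanning each planted site (alternating
    strand), so annotation has promoters near true binding."""
    with open(path, "w") as out:
        for i, (contig, s, e) in enumerate(truth.sites):
            strand = "+" if i % 2 == 0 else "-"
            gs = max(0, s - 500)
            ge = min(lengths[contig], e + 500)
            attrs = f'gene_id "sim_gene_{i}"; gene_name "SIM{i}";'
            out.write(f"{contig}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}\n")
            out.write(f"{contig}\tsim\texon\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def end_to_end_fixture(cfg: SimulationConfig, outdir, force: bool = False) -> Dict:
    """Write a self-contained workspace: genome FASTA, toy GTF, per-sample
    SAMs, truth BED, sample sheet, YAML config and a checksum manifest."""
    import yaml

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise SimulationError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.rng_seed)
    genome, index, planted = simulate_genome(cfg, rng)
    fmap = build_fragment_map(index, genome.lengths)
    truth = make_truth(cfg, fmap, planted, rng)

    write_fasta(genome, outdir / "genome.fa")
    _toy_gtf(truth, genome.lengths, outdir / "genes.gtf")
    write_truth_bed(truth, outdir / "truth_sites.bed")

    samples = []
    for i in range(cfg.n_fusion_samples):
        name = f"fusion{i}"
        sam = outdir / f"{name}.sam"
        simulate_reads(genome, fmap, truth, cfg, "fusion", i, sam)
        samples.append((name, "fusion", "group1", sam.name))
    for i in range(cfg.n_dam_samples):
        name = f"dam_only{i}"
        sam = outdir / f"{name}.sam"
        simulate_reads(genome, fmap, truth, cfg, "dam_only", i, sam)
        samples.append((name, "dam_only", "group1", sam.name))
    with open(outdir / "samplesheet.tsv", "w") as out:
        out.write("sample_id\trole\tgroup\tpath\n")
        for row in samples:
            out.write("\t".join(row) + "\n")
    config = {
        "paths": {
            "fasta": "genome.fa",
            "gtf": "genes.gtf",
            "sample_sheet": "samplesheet.tsv",
            "out_dir": "results",
        },
        "ingest": {"paired": cfg.paired},
        "peaks": {"rng_seed": cfg.rng_seed},
    }
    with open(outdir / "config.yaml", "w") as out:
        yaml.safe_dump(config, out)
    files = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": asdict(cfg),
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2)
    return manifest
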