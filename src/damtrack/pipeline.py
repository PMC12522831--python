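"""End-to-end workflow: index -> ingest -> count -> pair -> normalise ->
call peaks -> consensus -> annotate -> QC, with checksum-based caching and a
machine-readable run report.

Each stage's signature is the SHA-256 of its parameters plus its input
files' digests; a stage re-runs only when its signature changes or a
declared output is missing, so re-running an unchanged workflow performs no
recomputation and deleting an intermediate recomputes only from that stage
onward.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .annotate import annotate_peaks, annotations_to_frame, feature_distribution, parse_gtf
from .config import ConfigError, SampleSheet, dump_config
from .genome import (
    build_fragment_map,
    mask_genome,
    read_fasta,
    read_fragments_bed,
    read_mask_bed,
    scan_gatc_sites,
    write_fragments_bed,
    write_gatc_sites_bed,
)
from .ingest import (
    AlignmentStats,
    DecoyIndex,
    ReadFilterConfig,
    alignment_rate_summary,
    parse_alignments,
    reads_to_fragments,
)
from .normalize import (
    FragmentCounts,
    count_reads_per_fragment,
    enumerate_pairings,
    mean_track,
    normalize_pair,
    quantile_normalize,
    read_bedgraph,
    write_bedgraph,
    write_counts_tsv,
)
from .peaks import (
    PeakCallConfig,
    call_peaks_ratio,
    consensus_peaks,
    frip,
    read_peaks_bed,
    write_consensus_bed,
    write_peaks_bed,
)
from .qc import pca_samples, plot_correlation_heatmap, plot_pca, spearman_correlation_matrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _signature(name: str, params: Dict, inputs: List[Path]) -> str:
    h = hashlib.sha256()
    h.update(name.encode())
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    for p in inputs:
        h.update(str(p.name).encode())
        h.update(_sha256_file(p).encode())
    return h.hexdigest()


class _Cache:
    def __init__(self, path: Path):
        self.path = path
        self.data: Dict[str, str] = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def fresh(self, stage: str, sig: str, outputs: List[Path]) -> bool:
        return self.data.get(stage) == sig and all(p.exists() for p in outputs)

    def record(self, stage: str, sig: str) -> None:
        self.data[stage] = sig
        self.path.write_text(json.dumps(self.data, indent=2))


def run_pipeline(cfg: Dict, sheet: SampleSheet, base_dir: Optional[Path] = None) -> Path:
    """Execute the full workflow; returns the output directory.

    The run report (``report.json``) records per-stage parameters, seeds,
    counts and whether each stage was served from cache; together with the
    resolved config copy it suffices to reproduce the run.
    """
    base = Path(base_dir) if base_dir else Path.cwd()
    outdir = Path(cfg["paths"]["out_dir"])
    if not outdir.is_absolute():
        outdir = base / outdir
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, outdir / "config_resolved.yaml")
    cache = _Cache(outdir / ".cache.json")
    report: Dict = {
        "tool": "damtrack",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def _resolve(p: Optional[str]) -> Optional[Path]:
        if p is None:
            return None
        path = Path(p)
        return path if path.is_absolute() else base / path

    fasta = _resolve(cfg["paths"]["fasta"])
    if fasta is None or not fasta.exists():
        raise PipelineError(f"genome FASTA not found: {fasta}")

    # ---- stage: index -------------------------------------------------
    mask_bed = _resolve(cfg["paths"]["mask_bed"])
    idx_inputs = [fasta] + ([mask_bed] if mask_bed else [])
    idx_sig = _signature("index", {}, idx_inputs)
    sites_bed = outdir / "gatc_sites.bed"
    frags_bed = outdir / "gatc_fragments.bed"
    cached = cache.fresh("index", idx_sig, [sites_bed, frags_bed])
    if not cached:
        genome = read_fasta(fasta)
        if mask_bed:
            genome = mask_genome(genome, read_mask_bed(mask_bed))
        index = scan_gatc_sites(genome)
        fmap = build_fragment_map(index, genome.lengths)
        write_gatc_sites_bed(index, sites_bed)
        write_fragments_bed(fmap, frags_bed)
        cache.record("index", idx_sig)
    else:
        fmap = read_fragments_bed(frags_bed)
    report["stages"]["index"] = {"cached": cached, "n_fragments": fmap.n_fragments}

    # ---- stage: ingest + count ---------------------------------------
    ing = cfg["ingest"]
    decoy_fasta = _resolve(cfg["paths"]["decoy_fasta"])
    decoys = None
    if decoy_fasta:
        decoys = DecoyIndex(read_fasta(decoy_fasta).contigs, k=ing["decoy_seed_length"])
    filt = ReadFilterConfig(min_mapq=ing["min_mapq"], decoys=decoys)
    counts_tsv = outdir / "fragment_counts.tsv"
    rates_tsv = outdir / "alignment_rates.tsv"
    sample_inputs = [Path(sheet.path(sid)) for sid in sheet.sample_ids]
    count_sig = _signature("count", {**ing, "decoy": bool(decoys)}, [frags_bed] + sample_inputs)
    cached = cache.fresh("count", count_sig, [counts_tsv, rates_tsv])
    counts_by_sample: Dict[str, FragmentCounts] = {}
    frip_fragments: Dict[str, list] = {}
    if not cached:
        stats_list: List[AlignmentStats] = []
        for sid in sheet.sample_ids:
            reads, stats = parse_alignments(
                sheet.path(sid), filt, known_contigs=fmap.lengths, sample_id=sid
            )
            fragments = reads_to_fragments(
                reads, fmap, paired=ing["paired"], target_length=ing["extend_to"], stats=stats
            )
            frip_fragments[sid] = fragments
            counts_by_sample[sid] = count_reads_per_fragment(
                fragments, fmap, sample_id=sid, role=sheet.role(sid)
            )
            stats_list.append(stats)
        write_counts_tsv(list(counts_by_sample.values()), fmap, counts_tsv)
        alignment_rate_summary(stats_list).to_csv(rates_tsv, sep="\t", index=False)
        cache.record("count", count_sig)
    else:
        import pandas as pd

        matrix = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        for sid in sheet.sample_ids:
            counts_by_sample[sid] = FragmentCounts(
                sample_id=sid, role=sheet.role(sid), counts=matrix[sid].to_numpy()
            )
    report["stages"]["count"] = {
        "cached": cached,
        "samples": {sid: float(c.total) for sid, c in counts_by_sample.items()},
    }

    # ---- stage: normalise --------------------------------------------
    norm = cfg["normalize"]
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    pair_list = []
    for group in sheet.groups:
        pair_list.extend(enumerate_pairings(sheet.fusion_ids(group), sheet.dam_ids(group)))
    norm_sig = _signature("normalize", norm, [counts_tsv])
    track_paths = {label: tracks_dir / f"{label}.bedgraph" for _, _, label in pair_list}
    cached = cache.fresh("normalize", norm_sig, list(track_paths.values()))
    tracks = {}
    if not cached:
        raw_tracks = []
        for fus, dam, label in pair_list:
            raw_tracks.append(
                normalize_pair(
                    counts_by_sample[fus],
                    counts_by_sample[dam],
                    pseudocount=norm["pseudocount"],
                    offset_method=norm["offset_method"],
                    pair_label=label,
                    exclude_mode=norm["exclude_mode"],
                )
            )
        if norm["quantile_normalize"] and len(raw_tracks) >= 2:
            raw_tracks = quantile_normalize(raw_tracks)
        for t in raw_tracks:
            write_bedgraph(t, fmap, track_paths[t.pair_label])
            tracks[t.pair_label] = t
        mean = mean_track(raw_tracks, label="mean_all_pairs")
        write_bedgraph(mean, fmap, tracks_dir / "mean_all_pairs.bedgraph")
        cache.record("normalize", norm_sig)
    else:
        for label, path in track_paths.items():
            tracks[label] = read_bedgraph(path, fmap, pair_label=label)
    report["stages"]["normalize"] = {
        "cached": cached,
        "n_pairs": len(pair_list),
        "quantile_normalize": norm["quantile_normalize"],
        "offset_method": norm["offset_method"],
    }

    # ---- stage: peak calling -----------------------------------------
    pk = cfg["peaks"]
    peak_cfg = PeakCallConfig(
        min_score_threshold=pk["min_score_threshold"],
        min_fragments=pk["min_fragments"],
        merge_gap=pk["merge_gap"],
        n_permutations=pk["n_permutations"],
        fdr_threshold=pk["fdr_threshold"],
        rng_seed=pk["rng_seed"],
    )
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    peak_sig = _signature("callpeaks", pk, sorted(track_paths.values()))
    peak_paths = {label: peaks_dir / f"{label}.peaks.bed" for label in track_paths}
    cached = cache.fresh("callpeaks", peak_sig, list(peak_paths.values()))
    peak_sets = {}
    if not cached:
        for label, track in tracks.items():
            called = call_peaks_ratio(track, fmap, peak_cfg)
            write_peaks_bed(called, peak_paths[label], seed=pk["rng_seed"])
            peak_sets[label] = called
        cache.record("callpeaks", peak_sig)
    else:
        for label, path in peak_paths.items():
            peak_sets[label] = read_peaks_bed(path, sample_label=label)
    report["stages"]["callpeaks"] = {
        "cached": cached,
        "rng_seed": pk["rng_seed"],
        "n_peaks": {label: len(v) for label, v in peak_sets.items()},
    }

    # ---- stage: consensus --------------------------------------------
    cons = cfg["consensus"]
    consensus_bed = outdir / "consensus_peaks.bed"
    cons_sig = _signature("consensus", cons, sorted(peak_paths.values()))
    cached = cache.fresh("consensus", cons_sig, [consensus_bed])
    labels = sorted(peak_sets)
    if not cached:
        consensus = consensus_peaks(
            [peak_sets[label] for label in labels],
            min_support=cons["min_support"],
            extra_extension=cons["extra_extension"],
            lengths=fmap.lengths,
            sample_labels=labels,
        )
        write_consensus_bed(consensus, consensus_bed)
        cache.record("consensus", cons_sig)
    else:
        consensus = []
        for p in read_peaks_bed(consensus_bed):
            consensus.append(p)
    n_consensus = sum(1 for _ in open(consensus_bed)) if consensus_bed.exists() else 0
    report["stages"]["consensus"] = {
        "cached": cached,
        "min_support": cons["min_support"],
        "n_consensus_peaks": n_consensus,
    }

    # ---- stage: annotate ---------------------------------------------
    gtf = _resolve(cfg["paths"]["gtf"])
    if gtf and gtf.exists():
        ann = cfg["annotate"]
        ann_tsv = outdir / "peak_annotation.tsv"
        dist_tsv = outdir / "feature_distribution.tsv"
        ann_sig = _signature("annotate", ann, [gtf, consensus_bed])
        cached = cache.fresh("annotate", ann_sig, [ann_tsv, dist_tsv])
        if not cached:
            model = parse_gtf(gtf)
            cons_peaks = read_peaks_bed(consensus_bed)
            annotations = annotate_peaks(
                cons_peaks,
                model,
                promoter_window=ann["promoter_window"],
                downstream_window=ann["downstream_window"],
            )
            annotations_to_frame(annotations).to_csv(ann_tsv, sep="\t", index=False)
            if annotations:
                feature_distribution(annotations).to_csv(dist_tsv, sep="\t", index=False)
            else:
                dist_tsv.write_text("feature_class\tcount\tproportion\n")
            cache.record("annotate", ann_sig)
        report["stages"]["annotate"] = {"cached": cached}

    # ---- stage: qc ----------------------------------------------------
    qc_dir = outdir / "qc"
    qc_dir.mkdir(exist_ok=True)
    import pandas as pd

    matrix = pd.DataFrame({sid: counts_by_sample[sid].counts for sid in sheet.sample_ids})
    qc_report: Dict = {}
    if matrix.shape[1] >= 2 and matrix.shape[0] >= 3:
        corr, order = spearman_correlation_matrix(matrix)
        corr.to_csv(qc_dir / "spearman_correlation.tsv", sep="\t")
        plot_correlation_heatmap(corr, order, qc_dir / "spearman_heatmap.png")
        coords, var_pct = pca_samples(matrix)
        coords.to_csv(qc_dir / "pca_coordinates.tsv", sep="\t")
        np.savetxt(qc_dir / "pca_variance_pct.tsv", var_pct, fmt="%.4f")
        plot_pca(coords, var_pct, qc_dir / "pca.png")
        qc_report["clustering_order"] = order
    if frip_fragments:
        cons_peaks = read_peaks_bed(consensus_bed)
        frips = {}
        for sid, frags in frip_fragments.items():
            frips[sid] = frip(frags, cons_peaks) if cons_peaks and frags else 0.0
        pd.Series(frips, name="frip").to_csv(qc_dir / "frip.tsv", sep="\t", header=True)
        qc_report["frip"] = frips
    report["stages"]["qc"] = qc_report

    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return outdir
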