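"""Peak calling on ratio tracks and consensus peak derivation.

The per-replicate caller is a run-threshold algorithm with an empirical
permutation FDR: candidate peaks are maximal runs of consecutive
non-excluded GATC fragments whose log2 ratio exceeds a score threshold.
A null ensemble is built by permuting the non-excluded fragment values.
Every run (observed or permuted) is ranked by its joint (length, score)
extremeness: m = 1 + the number of pooled null runs at least as long AND as
high-scoring.  A candidate's q-value is the larger of (a) the empirical-FDR
ratio — pseudocounted expected null runs at least as extreme divided by the
observed count of such runs — and (b) a Westfall–Young-style permutation
p-value: the fraction of permutations containing at least as many runs at
least as extreme as the candidate.  The min-p construction collapses the
many run-length "channels" into a single exchangeable comparison, so on
signal-free tracks the probability of any call at FDR 0.05 stays near the
nominal 5%, while jointly long-and-high runs in signal tracks remain
powerful.  Externally called peaks (e.g. MACS narrowPeak) can be imported
and fed into the consensus step instead.

Consensus peaks follow the multi-intersection strategy: the genome is
partitioned by all peak boundaries, cells covered by at least ``min_support``
distinct samples are merged into core intervals, and each core is extended
to the left-most and right-most boundaries of the individual peaks that
contributed to it.  Each consensus peak carries the number of supporting
samples so users can filter by reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .genome import GatcFragmentMap
from .normalize import RatioTrack


class PeakError(ValueError):
    pass


@dataclass
class Peak:
    contig: str
    start: int
    end: int
    score: float  # mean log2 ratio over constituent fragments
    n_fragments: int
    fdr_q: float
    sample_label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PeakError(f"peak with start >= end: {self.contig}:{self.start}-{self.end}")


@dataclass
class ConsensusPeak:
    contig: str
    start: int
    end: int
    support: int
    contributing_samples: List[str]
    core_start: int
    core_end: int


@dataclass
class PeakCallConfig:
    min_score_threshold: float = 0.0
    min_fragments: int = 2
    merge_gap: int = 0  # bp of excluded fragments a run may bridge
    n_permutations: int = 100
    fdr_threshold: float = 0.05
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_permutations < 10:
            raise PeakError("n_permutations must be >= 10")
        if not np.isfinite(self.min_score_threshold) or not np.isfinite(self.fdr_threshold):
            raise PeakError("thresholds must be finite")


def _find_runs_fast(values: np.ndarray, above: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal runs of True in *above*; returns (start_idx, end_idx_exclusive, score)."""
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]
    if len(starts) == 0:
        return starts, ends, np.empty(0)
    cs = np.concatenate(([0.0], np.cumsum(np.where(above, values, 0.0))))
    scores = (cs[ends] - cs[starts]) / (ends - starts)
    return starts, ends, scores


def _contig_runs(
    values: np.ndarray,
    excluded: np.ndarray,
    boundaries: np.ndarray,
    thr: float,
    min_fragments: int,
    merge_gap: int,
) -> List[Tuple[int, int, int, float]]:
    """Candidate runs on one contig: (first_frag, last_frag_exclusive, n_included, score).

    With merge_gap == 0 any excluded or sub-threshold fragment breaks a run;
    with merge_gap > 0 runs may bridge excluded fragments spanning at most
    merge_gap bp (sub-threshold non-excluded fragments always break).
    """
    if merge_gap == 0:
        above = (~excluded) & (values > thr)
        starts, ends, scores = _find_runs_fast(np.nan_to_num(values), above)
        return [
            (int(s), int(e), int(e - s), float(sc))
            for s, e, sc in zip(starts, ends, scores)
            if e - s >= min_fragments
        ]
    runs: List[Tuple[int, int, int, float]] = []
    cur: List[int] = []
    gap_bp = 0
    for i in range(len(values)):
        if excluded[i]:
            if cur:
                gap_bp += int(boundaries[i + 1] - boundaries[i])
                if gap_bp > merge_gap:
                    if len(cur) >= min_fragments:
                        runs.append(_close_run(cur, values))
                    cur, gap_bp = [], 0
            continue
        if values[i] > thr:
            cur.append(i)
            gap_bp = 0
        else:
            if len(cur) >= min_fragments:
                runs.append(_close_run(cur, values))
            cur, gap_bp = [], 0
    if len(cur) >= min_fragments:
        runs.append(_close_run(cur, values))
    return runs


def _close_run(idx: List[int], values: np.ndarray) -> Tuple[int, int, int, float]:
    arr = np.asarray(idx)
    return int(arr[0]), int(arr[-1] + 1), len(arr), float(values[arr].mean())


def _all_runs(
    values: np.ndarray,
    excluded: np.ndarray,
    fmap: GatcFragmentMap,
    cfg: PeakCallConfig,
) -> List[Tuple[str, int, int, int, float]]:
    """Runs over all contigs: (contig, first_frag_local, last_frag_local_excl, n, score)."""
    out: List[Tuple[str, int, int, int, float]] = []
    for contig, b in fmap.boundaries.items():
        off = fmap.id_offset(contig)
        n = fmap.n_contig_fragments(contig)
        sl = slice(off, off + n)
        for s, e, k, sc in _contig_runs(
            values[sl], excluded[sl], b, cfg.min_score_threshold, cfg.min_fragments, cfg.merge_gap
        ):
            out.append((contig, s, e, k, sc))
    return out


def _dominance_counts(
    cand_len: np.ndarray, cand_score: np.ndarray, pool_len: np.ndarray, pool_score: np.ndarray
) -> np.ndarray:
    """For each candidate run, count pool runs with length >= L and score >= s."""
    counts = np.zeros(len(cand_len), dtype=np.int64)
    for ell in np.unique(cand_len):
        pool_scores_ell = np.sort(pool_score[pool_len >= ell])
        sel = cand_len == ell
        counts[sel] = len(pool_scores_ell) - np.searchsorted(
            pool_scores_ell, cand_score[sel], side="left"
        )
    return counts


def call_peaks_ratio(
    track: RatioTrack, fmap: GatcFragmentMap, cfg: Optional[PeakCallConfig] = None
) -> List[Peak]:
    """Call enriched runs of GATC fragments on one ratio track with a
    permutation-based empirical FDR.

    The null permutes the non-excluded fragment values uniformly at random
    (``cfg.n_permutations`` times, seeded).  Two complementary measures are
    combined: (a) an empirical-FDR ratio on the joint (length, score)
    extremeness rank m = 1 + pooled null runs at least as long AND as
    high-scoring, with the null count taken at its Garwood 95% Poisson upper
    bound; and (b) a k-FWER permutation p-value on the scalar run sum
    T = length x score (k = number of observed runs at that level, collapsed
    to the max-test for counts <= 2), taken at its Clopper-Pearson 95% upper
    bound.  The q-value is the larger of the two, capped at 1 and monotone
    non-increasing in extremeness.  Acting through upper confidence bounds
    keeps decisions honest at the default 100 permutations.  Candidate
    boundaries depend only on the data; the seed perturbs only q-values.
    """
    cfg = cfg or PeakCallConfig()
    excluded = track.excluded_mask
    n_defined = int((~excluded).sum())
    if n_defined < 10:
        raise PeakError("degenerate track: fewer than 10 non-excluded fragments")
    values = track.values
    candidates = _all_runs(values, excluded, fmap, cfg)
    if not candidates:
        return []
    cand_len = np.asarray([c[3] for c in candidates])
    cand_score = np.asarray([c[4] for c in candidates])

    rng = np.random.default_rng(cfg.rng_seed)
    defined_vals = values[~excluded]
    null_len: List[int] = []
    null_score: List[float] = []
    null_perm: List[int] = []
    perm_values = values.copy()
    idx_defined = np.flatnonzero(~excluded)
    for pi in range(cfg.n_permutations):
        perm_values[idx_defined] = rng.permutation(defined_vals)
        for _, _, _, k, sc in _all_runs(perm_values, excluded, fmap, cfg):
            null_len.append(k)
            null_score.append(sc)
            null_perm.append(pi)
    null_len_arr = np.asarray(null_len, dtype=np.int64)
    null_score_arr = np.asarray(null_score)
    null_perm_arr = np.asarray(null_perm, dtype=np.int64)

    # (a) joint-extremeness rank m = 1 + pooled null dominators (length AND
    # score) for the empirical-FDR ratio; the null count is replaced by its
    # 95% Poisson upper confidence bound (Garwood) so that FDR estimates
    # based on a handful of null events are not spuriously small
    from scipy.stats import chi2

    cand_m = 1 + _dominance_counts(cand_len, cand_score, null_len_arr, null_score_arr)
    cand_m_sorted = np.sort(cand_m)
    obs_m_counts = np.searchsorted(cand_m_sorted, cand_m, side="right")
    null_ucb = chi2.ppf(0.95, 2 * cand_m) / 2.0  # cand_m = observed nulls + 1
    ratio_fdr = (null_ucb / cfg.n_permutations) / obs_m_counts

    # (b) k-FWER permutation p on the scalar run sum T = length * score:
    # fraction of permutations holding at least as many runs at T' >= T as
    # the observed track does
    cand_t = cand_len * cand_score
    null_t = null_len_arr * null_score_arr
    cand_t_sorted = np.sort(cand_t)
    obs_t_counts = len(cand_t) - np.searchsorted(cand_t_sorted, cand_t, side="left")
    # discovery credit k: with only 1-2 runs at a level, FDR control at 5%
    # tolerates no false run, so the family-wise max-test applies; larger
    # discovery counts are credited (k-FWER with k = observed count)
    k_credit = np.where(obs_t_counts >= 3, obs_t_counts, 1)
    b = np.zeros(len(cand_t), dtype=np.int64)
    for pi in range(cfg.n_permutations):
        pt = np.sort(null_t[null_perm_arr == pi])
        counts_in_perm = len(pt) - np.searchsorted(pt, cand_t, side="left")
        b += counts_in_perm >= k_credit
    # Clopper-Pearson 95% upper bound of the permutation fraction: with only
    # P permutations a raw (1+b)/(1+P) estimate is too uncertain to act on
    from scipy.stats import beta as beta_dist

    fwer_p = beta_dist.ppf(0.95, b + 1, np.maximum(cfg.n_permutations - b, 1))

    fdr = np.minimum(np.maximum(ratio_fdr, fwer_p), 1.0)
    # conservative monotonisation: q non-increasing in either extremeness order
    order = np.argsort(cand_m, kind="stable")
    fdr[order] = np.maximum.accumulate(fdr[order])
    order_t = np.argsort(-cand_t, kind="stable")
    fdr[order_t] = np.maximum.accumulate(fdr[order_t])

    contig_order = {c: i for i, c in enumerate(fmap.boundaries)}
    peaks: List[Peak] = []
    for (contig, s, e, k, sc), q in zip(candidates, fdr):
        if q <= cfg.fdr_threshold:
            b = fmap.boundaries[contig]
            peaks.append(
                Peak(
                    contig=contig,
                    start=int(b[s]),
                    end=int(b[e]),
                    score=sc,
                    n_fragments=k,
                    fdr_q=float(q),
                    sample_label=track.pair_label,
                )
            )
    peaks.sort(key=lambda p: (contig_order[p.contig], p.start))
    return peaks


# ---------------------------------------------------------------------------
# consensus peaks


def _merge_extended(
    intervals: List[Tuple[int, int, int, Set[str], int, int]]
) -> List[Tuple[int, int, int, Set[str], int, int]]:
    """Merge strictly overlapping (start, end, support, samples, core_s, core_e)
    intervals to a fixed point; merged support is the max, samples the union,
    core the min/max envelope of the merged cores."""
    intervals = sorted(intervals, key=lambda x: (x[0], x[1]))
    out: List[Tuple[int, int, int, Set[str], int, int]] = []
    for iv in intervals:
        if out and iv[0] < out[-1][1]:  # strict overlap (abutting intervals stay separate)
            s, e, sup, smp, cs, ce = out[-1]
            out[-1] = (
                s,
                max(e, iv[1]),
                max(sup, iv[2]),
                smp | iv[3],
                min(cs, iv[4]),
                max(ce, iv[5]),
            )
        else:
            out.append(iv)
    return out


def consensus_peaks(
    peak_sets: Sequence[Sequence[Peak]],
    min_support: int,
    extra_extension: int = 0,
    lengths: Optional[Dict[str, int]] = None,
    sample_labels: Optional[Sequence[str]] = None,
) -> List[ConsensusPeak]:
    """Derive consensus peaks supported by >= *min_support* distinct samples.

    Algorithm: partition each contig by all peak boundaries; merge adjacent
    cells covered by >= min_support samples into core intervals; extend each
    core to the envelope (min start, max end) of every individual peak
    overlapping it; merge extended intervals that overlap (support = max,
    samples = union); apply the optional symmetric *extra_extension*,
    clipped to contig bounds, and re-merge.
    """
    n_sets = len(peak_sets)
    if not (1 <= min_support <= n_sets):
        raise PeakError(f"min_support must be in [1, {n_sets}], got {min_support}")
    if sample_labels is None:
        sample_labels = [f"sample_{i}" for i in range(n_sets)]
    per_contig: Dict[str, List[Tuple[int, int, int]]] = {}  # (start, end, sample_idx)
    for si, peaks in enumerate(peak_sets):
        for p in peaks:
            per_contig.setdefault(p.contig, []).append((p.start, p.end, si))
    results: List[ConsensusPeak] = []
    for contig, ivals in per_contig.items():
        bounds = sorted({x for s, e, _ in ivals for x in (s, e)})
        cell_ok: List[Tuple[int, int]] = []
        for cs, ce in zip(bounds[:-1], bounds[1:]):
            covering = {si for s, e, si in ivals if s <= cs and e >= ce}
            if len(covering) >= min_support:
                cell_ok.append((cs, ce))
        # merge adjacent qualifying cells into cores
        cores: List[Tuple[int, int]] = []
        for cs, ce in cell_ok:
            if cores and cores[-1][1] == cs:
                cores[-1] = (cores[-1][0], ce)
            else:
                cores.append((cs, ce))
        extended: List[Tuple[int, int, int, Set[str], int, int]] = []
        for cs, ce in cores:
            overlapping = [(s, e, si) for s, e, si in ivals if s < ce and e > cs]
            samples = {si for _, _, si in overlapping}
            env_s = min(s for s, _, _ in overlapping)
            env_e = max(e for _, e, _ in overlapping)
            extended.append((env_s, env_e, len(samples), {sample_labels[si] for si in samples}, cs, ce))
        merged = _merge_extended(extended)
        if extra_extension:
            clip_hi = lengths[contig] if lengths else None
            stretched = []
            for s, e, sup, smp, cs, ce in merged:
                ns = max(0, s - extra_extension)
                ne = e + extra_extension if clip_hi is None else min(clip_hi, e + extra_extension)
                stretched.append((ns, ne, sup, smp, cs, ce))
            merged = _merge_extended(stretched)
        for s, e, sup, smp, cs, ce in merged:
            results.append(
                ConsensusPeak(
                    contig=contig,
                    start=s,
                    end=e,
                    support=sup,
                    contributing_samples=sorted(smp),
                    core_start=cs,
                    core_end=ce,
                )
            )
    results.sort(key=lambda c: (c.contig, c.start))
    return results


def extend_and_clip(
    peaks: Sequence[Peak], bp: int, lengths: Dict[str, int]
) -> List[Peak]:
    """Extend peaks symmetrically by *bp*, clip to contig bounds, merge overlaps."""
    if bp < 0:
        raise PeakError("extension must be >= 0")
    by_contig: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append(p)
    out: List[Peak] = []
    for contig, plist in by_contig.items():
        stretched = sorted(
            (max(0, p.start - bp), min(lengths[contig], p.end + bp), p) for p in plist
        )
        merged: List[List] = []
        for s, e, p in stretched:
            if merged and s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2].append(p)
            else:
                merged.append([s, e, [p]])
        for s, e, sources in merged:
            best = max(sources, key=lambda p: p.score)
            out.append(
                Peak(
                    contig=contig,
                    start=s,
                    end=e,
                    score=best.score,
                    n_fragments=sum(p.n_fragments for p in sources),
                    fdr_q=min(p.fdr_q for p in sources),
                    sample_label=best.sample_label,
                )
            )
    out.sort(key=lambda p: (p.contig, p.start))
    return out


def frip(fragments: Iterable, peaks: Sequence) -> float:
    """Fraction of sequenced fragments whose midpoint lies inside any peak.

    A signal-to-noise QC: high FRiP means methylation is concentrated in
    called regions rather than spread over accessibility background.
    """
    peak_by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for p in peaks:
        peak_by_contig.setdefault(p.contig, []).append((p.start, p.end))
    starts_by_contig = {}
    for contig, ivals in peak_by_contig.items():
        ivals.sort()
        starts_by_contig[contig] = (
            np.asarray([s for s, _ in ivals]),
            np.asarray([e for _, e in ivals]),
        )
    total = 0
    inside = 0
    for f in fragments:
        total += 1
        hit = starts_by_contig.get(f.contig)
        if hit is None:
            continue
        mid = (f.start + f.end) // 2
        starts, ends = hit
        i = int(np.searchsorted(starts, mid, side="right")) - 1
        if i >= 0 and mid < ends[i]:
            inside += 1
    if total == 0:
        raise PeakError("frip: zero fragments")
    return inside / total


# ---------------------------------------------------------------------------
# peak BED I/O


def write_peaks_bed(peaks: Sequence[Peak], path, seed: Optional[int] = None) -> None:
    """BED6+1: chrom, start, end, name, round(score*1000), strand '.', fdr_q."""
    with open(path, "w") as out:
        if seed is not None:
            out.write(f"# damtrack peaks; permutation_seed={seed}\n")
        for i, p in enumerate(peaks):
            out.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{p.sample_label or 'peak'}_{i}\t"
                f"{round(p.score * 1000)}\t.\t{p.fdr_q:.6g}\n"
            )


def read_peaks_bed(path, sample_label: str = "") -> List[Peak]:
    peaks: List[Peak] = []
    with open(path) as handle:
        for i, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PeakError(f"malformed peak BED line {i} in {path}")
            score = float(parts[4]) / 1000 if len(parts) > 4 else 0.0
            fdr_q = float(parts[6]) if len(parts) > 6 else 0.0
            peaks.append(
                Peak(
                    contig=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    score=score,
                    n_fragments=1,
                    fdr_q=fdr_q,
                    sample_label=sample_label or (parts[3] if len(parts) > 3 else ""),
                )
            )
    return peaks


def write_consensus_bed(consensus: Sequence[ConsensusPeak], path) -> None:
    """BED with support count and contributing samples in extra columns."""
    with open(path, "w") as out:
        for i, c in enumerate(consensus):
            out.write(
                f"{c.contig}\t{c.start}\t{c.end}\tconsensus_{i}\t{c.support}\t.\t"
                f"{c.core_start}\t{c.core_end}\t{','.join(c.contributing_samples)}\n"
            )


def read_narrowpeak(path, sample_label: str = "") -> List[Peak]:
    """Import externally called peaks (e.g. MACS narrowPeak) for consensus calling."""
    peaks: List[Peak] = []
    with open(path) as handle:
        for i, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise PeakError(f"malformed narrowPeak line {i} in {path}")
            peaks.append(
                Peak(
                    contig=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    score=float(parts[6]),
                    n_fragments=1,
                    fdr_q=10 ** (-float(parts[8])) if float(parts[8]) >= 0 else 1.0,
                    sample_label=sample_label or parts[3],
                )
            )
    return peaks
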