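"""Per-fragment quantification and Dam-only normalisation.

The central signal type is the :class:`RatioTrack`: per-GATC-fragment
log2(Dam-fusion / Dam-only) values.  Construction follows the DamID-specific
recipe:

1. read/fragment counts over GATC fragments, with proportional overlap
   splitting so total signal is conserved;
2. all possible Dam-fusion x Dam-only pairings are enumerated, so designs
   with unequal replicate numbers use every sample;
3. per pair: counts-per-million scaling, exclusion of fragments with zero
   raw counts in both samples (GATC-dense read-free regions otherwise
   dominate the noise), pseudocounted log2 ratio, and subtraction of a
   global scale offset (the mode of a kernel-density estimate of the
   per-fragment ratios, i.e. the typical background fold-change);
4. optional quantile normalisation across tracks (rank-mean transform over
   the shared non-excluded fragments) to remove batch-like distributional
   differences.

Track utilities (mean track, the visualisation de-log transform, bedGraph
I/O) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GatcFragmentMap
from .ingest import ExtendedFragment


class NormalizeError(ValueError):
    pass


@dataclass
class FragmentCounts:
    """Per-sample counts over GATC fragments (fractional under proportional
    overlap assignment)."""

    sample_id: str
    role: str  # 'fusion' or 'dam_only'
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise NormalizeError("negative fragment counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class RatioTrack:
    """Per-fragment log2(fusion/dam) values with an excluded-fragment mask.

    ``values`` is NaN wherever ``excluded_mask`` is True.  ``scale_offset``
    is the global log2 correction that was subtracted.
    """

    pair_label: str
    values: np.ndarray
    excluded_mask: np.ndarray
    scale_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool)
        if self.values.shape != self.excluded_mask.shape:
            raise NormalizeError("values and excluded_mask differ in length")

    @property
    def n_fragments(self) -> int:
        return len(self.values)

    def defined_values(self) -> np.ndarray:
        return self.values[~self.excluded_mask]


def count_reads_per_fragment(
    fragments: Iterable[ExtendedFragment],
    fmap: GatcFragmentMap,
    sample_id: str = "",
    role: str = "fusion",
) -> FragmentCounts:
    """Count sequenced fragments over GATC fragments.

    Each sequenced fragment contributes total weight 1, split across the
    GATC fragments it overlaps proportionally to overlap length, so the
    count vector sums to the number of fragments counted.
    """
    counts = np.zeros(fmap.n_fragments, dtype=float)
    per_contig: Dict[str, List[Tuple[int, int]]] = {}
    for f in fragments:
        if f.contig not in fmap.boundaries:
            raise NormalizeError(f"fragment on unknown contig {f.contig!r}")
        per_contig.setdefault(f.contig, []).append((f.start, f.end))
    for contig, ivals in per_contig.items():
        b = fmap.boundaries[contig]
        off = fmap.id_offset(contig)
        arr = np.asarray(ivals, dtype=np.int64)
        starts, ends = arr[:, 0], arr[:, 1]
        i0 = np.searchsorted(b, starts, side="right") - 1
        i1 = np.searchsorted(b, ends, side="left") - 1
        single = i0 == i1
        np.add.at(counts, off + i0[single], 1.0)
        for s, e, a0, a1 in zip(
            starts[~single], ends[~single], i0[~single], i1[~single]
        ):
            total = e - s
            for j in range(a0, a1 + 1):
                ov = min(e, b[j + 1]) - max(s, b[j])
                counts[off + j] += ov / total
    return FragmentCounts(sample_id=sample_id, role=role, counts=counts)


def enumerate_pairings(
    fusion_ids: Sequence[str], dam_ids: Sequence[str]
) -> List[Tuple[str, str, str]]:
    """All fusion x Dam-only pairings, fusion-major order.

    Returns (fusion_id, dam_id, label) triples with labels
    ``"<fusion>_vs_<dam>"``.  Every available sample is used even when
    replicate numbers are unequal.
    """
    if not fusion_ids or not dam_ids:
        raise NormalizeError(
            "both a Dam-fusion and a Dam-only sample list are required: "
            "DamID normalisation is relative to the Dam-only control"
        )
    return [(f, d, f"{f}_vs_{d}") for f in fusion_ids for d in dam_ids]


def _kde_mode(values: np.ndarray, max_points: int = 4000) -> float:
    """Mode of a Gaussian KDE evaluated at the data points.

    Bandwidth is Silverman's 1.06*sigma*n^(-1/5).  Evaluating at the data
    points (stride-subsampled above *max_points*) keeps the estimate exactly
    antisymmetric: mode(-x) == -mode(x).
    """
    n = len(values)
    if n > max_points:
        stride = int(np.ceil(n / max_points))
        values = values[::stride]
        n = len(values)
    sigma = float(np.std(values))
    if sigma == 0.0 or n < 10:
        return float(np.median(values))
    h = 1.06 * sigma * n ** (-0.2)
    z = (values[None, :] - values[:, None]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1)
    return float(values[int(np.argmax(density))])


def normalize_pair(
    fusion: FragmentCounts,
    dam: FragmentCounts,
    pseudocount: float = 0.5,
    offset_method: str = "kde-mode",
    pair_label: Optional[str] = None,
    exclude_mode: str = "both",
) -> RatioTrack:
    """Build the log2(fusion/dam) ratio track for one sample pair.

    Both count vectors are scaled to counts-per-million; fragments with zero
    raw counts in both samples (``exclude_mode='both'``, default) or in
    either (``'either'``, stricter) are excluded; the remaining fragments
    get ``log2((f+psi)/(d+psi))``; finally a global scale offset — the KDE
    mode of the ratios over fragments observed in both samples — is
    subtracted so that the unbound background sits at 0.
    ``offset_method`` is one of ``kde-mode``, ``median``, ``none``.
    """
    if pseudocount <= 0:
        raise NormalizeError("pseudocount must be > 0")
    f_raw = fusion.counts
    d_raw = dam.counts
    if f_raw.shape != d_raw.shape:
        raise NormalizeError("count vectors differ in length")
    if exclude_mode == "both":
        excluded = (f_raw == 0) & (d_raw == 0)
    elif exclude_mode == "either":
        excluded = (f_raw == 0) | (d_raw == 0)
    else:
        raise NormalizeError(f"unknown exclude_mode {exclude_mode!r}")
    if excluded.all():
        raise NormalizeError("all fragments excluded: no fragment has reads")
    f_total, d_total = f_raw.sum(), d_raw.sum()
    if f_total == 0 or d_total == 0:
        raise NormalizeError("a sample has zero total counts")
    f_cpm = f_raw / f_total * 1e6
    d_cpm = d_raw / d_total * 1e6
    values = np.full(len(f_raw), np.nan)
    keep = ~excluded
    values[keep] = np.log2((f_cpm[keep] + pseudocount) / (d_cpm[keep] + pseudocount))
    offset_sample = values[(f_raw >= 1) & (d_raw >= 1)]
    if offset_method == "none" or len(offset_sample) == 0:
        offset = 0.0
    elif offset_method == "median":
        offset = float(np.median(offset_sample))
    elif offset_method == "kde-mode":
        offset = _kde_mode(offset_sample)
    else:
        raise NormalizeError(f"unknown offset_method {offset_method!r}")
    values[keep] -= offset
    label = pair_label or f"{fusion.sample_id}_vs_{dam.sample_id}"
    return RatioTrack(
        pair_label=label, values=values, excluded_mask=excluded, scale_offset=offset
    )


def quantile_normalize(tracks: Sequence[RatioTrack]) -> List[RatioTrack]:
    """Rank-mean quantile normalisation over the shared non-excluded fragments.

    The reference distribution is the per-rank mean of the sorted value
    vectors; each value is replaced by the reference value at its
    within-sample rank, ties receiving the mean of the reference values over
    their tied rank range.  Fragments excluded in any track are left
    untouched (the operation is defined on shared genomic coordinates only).
    """
    if len(tracks) < 2:
        raise NormalizeError("quantile normalisation needs >= 2 tracks")
    shared = ~np.logical_or.reduce([t.excluded_mask for t in tracks])
    n_shared = int(shared.sum())
    if n_shared < 2:
        raise NormalizeError("fewer than 2 fragments shared across all tracks")
    matrix = np.stack([t.values[shared] for t in tracks], axis=1)
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out: List[RatioTrack] = []
    for col_idx, track in enumerate(tracks):
        col = matrix[:, col_idx]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        # group ties: consecutive equal sorted values share the mean reference
        new_group = np.empty(n_shared, dtype=bool)
        new_group[0] = True
        new_group[1:] = sorted_vals[1:] != sorted_vals[:-1]
        gid = np.cumsum(new_group) - 1
        gsum = np.bincount(gid, weights=reference)
        gcount = np.bincount(gid)
        normalized_sorted = (gsum / gcount)[gid]
        new_col = np.empty(n_shared)
        new_col[order] = normalized_sorted
        new_values = track.values.copy()
        new_values[shared] = new_col
        out.append(
            RatioTrack(
                pair_label=track.pair_label,
                values=new_values,
                excluded_mask=track.excluded_mask.copy(),
                scale_offset=track.scale_offset,
            )
        )
    return out


def mean_track(tracks: Sequence[RatioTrack], label: str = "mean") -> RatioTrack:
    """Per-fragment arithmetic mean over tracks where the fragment is
    non-excluded; excluded only where excluded in every input."""
    if not tracks:
        raise NormalizeError("mean_track needs >= 1 track")
    stack = np.stack([t.values for t in tracks], axis=1)
    masks = np.stack([t.excluded_mask for t in tracks], axis=1)
    all_excluded = masks.all(axis=1)
    contrib = np.where(masks, 0.0, np.nan_to_num(stack))
    n_defined = (~masks).sum(axis=1)
    means = contrib.sum(axis=1) / np.maximum(n_defined, 1)
    means[all_excluded] = np.nan
    return RatioTrack(pair_label=label, values=means, excluded_mask=all_excluded)


def delog_track(track: RatioTrack) -> np.ndarray:
    """Visualisation transform: 2**value, so the midline moves from 0 to 1.

    Excluded fragments are NaN in the returned array.
    """
    return np.where(track.excluded_mask, np.nan, np.exp2(track.values))


def write_bedgraph(track: RatioTrack, fmap: GatcFragmentMap, path) -> None:
    """One line per non-excluded fragment, ``contig<TAB>start<TAB>end<TAB>value``
    (6 significant digits).  Adjacent equal-valued fragments are NOT merged,
    preserving GATC-fragment resolution."""
    with open(path, "w") as out:
        out.write(f'track type=bedGraph name="{track.pair_label}"\n')
        for contig, start, end, fid in fmap.iter_fragments():
            if not track.excluded_mask[fid]:
                out.write(f"{contig}\t{start}\t{end}\t{track.values[fid]:.6g}\n")


def read_bedgraph(path, fmap: GatcFragmentMap, pair_label: Optional[str] = None) -> RatioTrack:
    """Read a bedGraph written over *fmap*; intervals absent from the file
    are marked excluded.  Intervals that do not match a fragment exactly, or
    malformed lines, are hard errors naming the line."""
    values = np.full(fmap.n_fragments, np.nan)
    excluded = np.ones(fmap.n_fragments, dtype=bool)
    label = pair_label
    frag_lookup: Dict[Tuple[str, int], Tuple[int, int]] = {}
    for contig, start, end, fid in fmap.iter_fragments():
        frag_lookup[(contig, start)] = (end, fid)
    with open(path) as handle:
        for i, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("track"):
                if label is None and 'name="' in line:
                    label = line.split('name="', 1)[1].split('"', 1)[0]
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise NormalizeError(f"malformed bedGraph line {i} in {path}: {line!r}")
            try:
                contig, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise NormalizeError(f"malformed bedGraph line {i} in {path}: {line!r}") from exc
            hit = frag_lookup.get((contig, start))
            if hit is None or hit[0] != end:
                raise NormalizeError(
                    f"bedGraph line {i} interval {contig}:{start}-{end} does not match a GATC fragment"
                )
            values[hit[1]] = value
            excluded[hit[1]] = False
    return RatioTrack(pair_label=label or "", values=values, excluded_mask=excluded)


def write_counts_tsv(counts_list: Sequence[FragmentCounts], fmap: GatcFragmentMap, path) -> None:
    """Fragments x samples count matrix as TSV."""
    import pandas as pd

    data = {c.sample_id: c.counts for c in counts_list}
    idx = [f"frag_{fid}" for _, _, _, fid in fmap.iter_fragments()]
    pd.DataFrame(data, index=idx).to_csv(path, sep="\t", index_label="fragment")
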