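# Methods

## Coordinate system: the GATC fragment map

All quantification is over the partition of each contig into GATC
fragments. Fragment boundaries sit at motif midpoints (position p+2 for a
motif starting at p): DpnI cuts within the palindromic GATC, and the
midpoint convention assigns half the motif to each flank and is identical
on both strands. A contig with k motifs yields k+1 abutting fragments
covering it exactly; the convention is recorded in the map's metadata.
Coordinates are 0-based half-open everywhere, matching BED/bedGraph; GTF
input is converted at the parser boundary.

## Read ingest

Unmapped, secondary, supplementary and low-MAPQ (default < 30) records are
dropped and counted per reason. Paired-end proper pairs yield one fragment
spanning the template; discordant pairs are dropped and counted. Single-end
reads are extended in the 3' direction to whichever comes first of 300 bp
total length, the nearest fragment-map boundary, or the contig edge; reads
already ≥ 300 bp are untouched. Duplicates are *not* removed: DamID
libraries are amplicon-based, so identical fragments are expected.

Decoy filtering (against the transfected Dam-fusion construct) drops any
read sharing an exact k-mer (default k = 21, minimum 11) with a decoy
sequence or its reverse complement. This is deterministic and conservative
relative to alignment-based filtering; users wanting the latter should
pre-filter upstream.

## Counting and normalisation

Each sequenced fragment contributes total weight 1, split across overlapped
GATC fragments proportionally to overlap length, so counts are conserved.
All fusion × Dam-only pairings are enumerated (fusion-major order, labels
`<fusion>_vs_<dam>`); pairs sharing a Dam-only sample are not independent,
and pair provenance is carried through so downstream users can decide how
to weight them.

Per pair: counts-per-million scaling; exclusion of fragments with zero raw
counts in both samples (config `exclude_mode: either` is a stricter
option); v = log2((f+ψ)/(d+ψ)) with ψ = 0.5 (configurable); subtraction of
a global scale offset. The offset is the mode of a Gaussian KDE (bandwidth
1.06·σ·n^(−1/5), evaluated at the data points, stride-subsampled above
4000 points) of the ratios over fragments with at least one raw read in
*both* samples; this set is symmetric in the two samples, which makes the
offset exactly antisymmetric under swapping fusion and Dam-only. Fallback
is the median when the sample is tiny or constant (`offset-method:
kde-mode|median|none`).

Quantile normalisation (optional, default on when ≥ 2 tracks) is the
rank-mean transform over fragments non-excluded in *all* tracks: the
reference is the per-rank mean of sorted vectors; ties receive the mean of
the reference values over their tied rank range. With ties present the
output multisets differ slightly between samples and the transform is not
exactly idempotent — both are inherent to tie-averaging, not defects.
Fragments outside the shared set keep their values.

Track utilities: per-fragment mean across tracks (excluded only where all
inputs are excluded); the visualisation de-log transform v → 2^v (midline
1); bedGraph I/O at one line per non-excluded fragment, 6 significant
digits, adjacent equal values never merged so GATC resolution survives a
round trip.

## Peak calling

Candidates are maximal runs of ≥ `min_fragments` (default 2) consecutive
non-excluded fragments with value > `min_score_threshold` (default 0);
excluded fragments break runs unless they span ≤ `merge_gap` bp (default
0). Candidate boundaries depend only on the data.

Significance uses a permutation null: the non-excluded values are permuted
uniformly (default 100 times, seeded). Each run is summarised two ways and
the reported q is the larger (capped at 1, cummax-monotonised so q never
decreases with decreasing extremeness):

1. **Empirical-FDR ratio.** Runs are ranked by joint extremeness
   m = 1 + the number of pooled null runs at least as long *and* as
   high-scoring. The FDR at a candidate's level is (expected null runs at
   least that extreme) / (observed runs at least that extreme), with the
   null count taken at its Garwood 95% Poisson upper confidence bound —
   with only a handful of null events the point estimate is too uncertain
   to act on.
2. **k-FWER permutation p.** On the scalar run sum T = length × mean score,
   the fraction of permutations containing at least as many runs with
   T' ≥ T as the observed track does, reported as the Clopper–Pearson 95%
   upper bound. The discovery credit k is the observed count, collapsed to
   the max-test for counts ≤ 2 (FDR 0.05 with ≤ 2 discoveries tolerates no
   false run).

The design stance is that every resampling-based error estimate acts
through a 95% upper confidence bound, which is appropriate at the default
100 permutations. Consequences, verified by simulation in the test suite:
on signal-free tracks (5000 fragments, N(0, 0.5) noise) some call is made
in only a few of 100 tracks; a single planted 10-fragment run at 3.0 is
called; 10 planted runs at ~2.5 are recovered with recall and precision
≥ 0.9. The caller is deliberately conservative for isolated marginal peaks:
a peak whose statistic lies within the range of per-permutation extremes is
not reported unless several comparable discoveries share its level.
Externally called peaks (e.g. MACS narrowPeak) can be imported and used for
consensus instead.

## Consensus peaks

The genome is partitioned by all peak boundaries; cells covered by
≥ `min_support` distinct samples merge into core intervals; each core is
extended to the envelope (min start, max end) of every peak overlapping it;
strictly overlapping envelopes merge (support = max of merged supports,
contributing samples = union); an optional symmetric extra extension is
applied, clipped to contig bounds, and re-merged. Support counts distinct
samples with ≥ 1 peak overlapping the core. Total core coverage is monotone
non-increasing in `min_support`; the *number* of consensus peaks is not
necessarily monotone (a bridging peak present in one sample can connect two
cores at low support that separate at high support) — this is a property of
the definition, not an implementation artifact.

## Annotation and QC

Peaks are annotated at their midpoint: nearest TSS (ties to the
lexicographically smaller gene_id), strand-aware signed distance (negative
= upstream), and feature class with precedence promoter (|d| ≤ 5 kb both
sides, configurable) > exon > intron > downstream (≤ 3 kb past the 3' end)
> distal intergenic. The class set is deliberately simpler than
ChIPseeker's (no UTR classes). QC comprises pairwise Spearman correlation
with average-linkage clustering on 1 − ρ (constant columns get ρ = 0 with a
warning), PCA of log2(CPM+1) counts (fragment-centred, SVD, deterministic
sign convention), per-sample alignment-rate tables, and FRiP (fraction of
fragment midpoints inside peaks).

## Synthetic data

The generator emulates the assay's data model. Genome: i.i.d. uniform
A/C/G/T with spontaneous GATC motifs mutated away and motifs planted at
Poisson-spaced positions to reach the target density (default 4/kb, the
genome-wide 4-mer expectation); the returned index is an exact re-scan, so
planted ⊆ scanned always holds. Binding: non-overlapping planted intervals
(default 16 sites of 1 kb — a realistic multi-fragment footprint at this
GATC density). Accessibility background: per-fragment log-normal weights
(σ = 0.5), shared across samples, giving the heavy-tailed coverage DamID
exhibits. Reads: fragments drawn with replacement proportionally to
background × (enrichment_fold on site-overlapping fragments for fusion
samples, default 8); each draw emits a 50 bp read at the fragment's 5'
boundary on a random strand (or a proper pair spanning the fragment),
mirroring amplicons that begin at DpnI cut sites — which also makes
single-end extension exactly recover fragments, a sharp test of that logic.
All streams derive deterministically from one seed; identical configs give
byte-identical SAM output.

What the simulation does *not* model: sequencing errors, PCR duplicates,
mappability structure, chromatin-state-dependent GATC accessibility, or
methylation kinetics. Passing recovery tests therefore demonstrates the
correctness of the quantification and inference machinery under the stated
generative model, not performance on real libraries.

Problem sizes in the test suite and acceptance script are desk-scale by
design: the calibration studies use 5000-fragment tracks and the end-to-end
study 2 × 100 kb contigs with 200k reads/sample — large enough that count
noise, GATC-density variation and permutation nulls behave realistically,
while a full run completes in well under a minute.

## Pipeline and provenance

`run_pipeline` chains index → ingest/count → pair/normalise → call peaks →
consensus → annotate → QC. Stage caching is content-addressed: a stage
re-runs only when the SHA-256 of its parameters and input files changes or
an output is missing, so re-runs are free and deleting an intermediate
recomputes only from that point. `report.json` records versions, resolved
parameters, seeds and per-stage counts; together with the resolved config
copy it suffices to reproduce a run. CLI exit codes: 0 success, 2 config
error, 3 data error, 4 internal error.

## Known limitations

- The normalisation is a documented variant of the field's Dam-only
  correction, not a bit-for-bit reimplementation of any external tool.
- The caller's conservatism trades sensitivity for specificity on isolated
  marginal peaks; lowering `min_score_threshold` or raising
  `n_permutations` sharpens resolution but does not change the stance.
- Combinatorial pairs share underlying samples; consensus support counts
  pairs, and users should set `min_support` with that dependence in mind.
- The decoy filter is k-mer exact matching, not alignment.
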