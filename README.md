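# damtrack

DamID-seq analysis from aligned reads to annotated consensus peaks:
GATC-fragment quantification, Dam-only normalisation, quantile
normalisation, permutation-FDR peak calling, consensus peaks with replicate
support, annotation and QC — plus a synthetic-data generator so the whole
workflow is testable without any external download.

## Who this is for

DamID-seq maps protein–chromatin interactions by fusing the *E. coli* Dam
methyltransferase to a protein of interest: adenines in accessible GATC
motifs near binding sites are methylated, and the fragments between
methylated sites are amplified and sequenced. Because untethered Dam also
methylates accessible chromatin, every experiment carries a Dam-only
control, and signal lives at the resolution of *GATC fragments* — the
genomic intervals between consecutive GATC motifs. damtrack is for groups
analysing such data who want a scriptable Python library (or a small CLI)
rather than a full workflow-manager deployment.

## The model

For each Dam-fusion sample *f* and Dam-only control *d*, counts over GATC
fragments are scaled to counts-per-million and the per-fragment signal is

> v_i = log2((f_i + ψ) / (d_i + ψ)) − offset,  ψ = 0.5

with fragments lacking reads in both samples excluded, and the offset taken
as the mode of a kernel-density estimate of the ratios over fragments
observed in both samples, so the unbound background sits at 0. With *F*
fusion and *D* Dam-only replicates, all *F × D* pairings are formed so
unequal replicate numbers use every sample. Single-end reads are first
extended in their 3' direction to 300 bp or the nearest GATC-fragment
boundary, reconstructing the sequenced DamID fragment.

Peaks on each ratio track are maximal runs of consecutive fragments above a
score threshold; their significance is an empirical permutation FDR (the
null permutes fragment values), reported as a 95% upper confidence bound
and floored by a k-FWER permutation test so that signal-free tracks yield
essentially no calls. Consensus peaks are regions covered by peaks from at
least `min_support` samples, extended to the outermost boundaries of the
contributing peaks and annotated with their support count.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_end_to_end.py` simulates a tiny experiment (1 × 20 kb
contig, 4 planted sites, 2 fusion + 1 Dam-only samples) and runs the whole
pipeline:

```
pairs normalised: 2
peaks per pair: {'fusion0_vs_dam_only0': 2, 'fusion1_vs_dam_only0': 2}
consensus peaks: 2
FRiP per sample: {'fusion0': 0.522, 'fusion1': 0.528, 'dam_only0': 0.162}
truth sites:
chr1    845     1645    site_0
chr1    8462    9262    site_1
...
consensus calls:
chr1    541     1908    consensus_0     2       ...
chr1    7749    10907   consensus_1     2       ...
```

Fusion samples concentrate ~52% of their reads in called peaks versus ~16%
for the Dam-only control (FRiP), and the consensus intervals overlap the
planted truth; sites 1–3 lie within one GATC-sparse neighbourhood and merge
into a single broad call, which is the expected behaviour at GATC
resolution.

The same workflow is available as a CLI:

```bash
damtrack simulate --preset small --seed 1 --out-dir work/
damtrack run --config work/config.yaml
damtrack report --out-dir work/results
```

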