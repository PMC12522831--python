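"""Build a GATC fragment map from a small genome and print its structure.

The fragment map — the genome partitioned at GATC motif midpoints — is the
coordinate system for all DamID quantification in damtrack.
"""

from damtrack import GenomeSequence, build_fragment_map, scan_gatc_sites

genome = GenomeSequence(
    {"chr_demo": "AATTGATCCCGGAATTACGATCTTGGCCAAGATCTTAACCGGTT"}
)
index = scan_gatc_sites(genome)
fmap = build_fragment_map(index, genome.lengths)

print(f"contig length: {genome.lengths['chr_demo']} bp")
print(f"GATC motifs at: {list(index.sites['chr_demo'])}")
for contig, start, end, fid in fmap.iter_fragments():
    print(f"  fragment {fid}: {contig}:{start}-{end} ({end - start} bp)")
# Each motif contributes a boundary at its midpoint (position + 2), so a
# contig with k motifs yields k + 1 abutting fragments covering it exactly.
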