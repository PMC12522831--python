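"""Build a log2(Dam-fusion / Dam-only) ratio track from fragment counts.

Shows the full normalisation recipe: CPM scaling, exclusion of read-free
fragments, pseudocounted log2 ratio, KDE-mode scale correction, and optional
quantile normalisation across pairs.
"""

import numpy as np

from damtrack import FragmentCounts, normalize_pair, quantile_normalize

rng = np.random.default_rng(0)
n = 200
background = rng.lognormal(0, 0.5, n)

dam = FragmentCounts("dam0", "dam_only", rng.poisson(50 * background))
enriched = background.copy()
enriched[80:90] *= 8  # a bound region: 8-fold methylation enrichment
fusion = FragmentCounts("fusion0", "fusion", rng.poisson(50 * enriched))

track = normalize_pair(fusion, dam)
print(f"pair {track.pair_label}: {int((~track.excluded_mask).sum())} fragments quantified")
print(f"scale offset subtracted: {track.scale_offset:+.3f} log2 units")
print(f"background mean log2 ratio: {np.nanmean(track.values[:80]):+.3f} (should be ~0)")
print(f"enriched-region mean log2 ratio: {np.nanmean(track.values[80:90]):+.3f} (~log2(8)=3)")

# a second pair, then quantile normalisation makes the distributions identical
fusion2 = FragmentCounts("fusion1", "fusion", rng.poisson(40 * enriched))
track2 = normalize_pair(fusion2, dam)
q1, q2 = quantile_normalize([track, track2])
shared = ~(q1.excluded_mask | q2.excluded_mask)  # the operation acts on shared fragments
print(
    "after quantile normalisation, max sorted-value difference on shared fragments:",
    f"{np.max(np.abs(np.sort(q1.values[shared]) - np.sort(q2.values[shared]))):.2e}",
)
# The distributions are now essentially identical; the residual difference
# comes from tied ratio values (integer counts), which receive the mean of
# their tied rank range rather than distinct reference values.
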