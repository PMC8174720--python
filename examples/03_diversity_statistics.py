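"""Per-locus PIC and panel-level discrimination power.

Uses exact-count genotype draws so the two extreme loci reproduce the
count-derived frequencies 41/73 and 72/73 of a 73-accession panel, and
shows both PIC variants at those endpoints.
"""

import numpy as np

from indelbarcode import (
    generate_matrix,
    panel_summary,
    pattern_frequencies,
    pic_botstein,
    pic_simple,
)

rng = np.random.default_rng(0)
freqs = list(rng.uniform(0.56, 0.99, size=50))
freqs[0], freqs[1] = 0.5616, 0.9863  # most / least polymorphic locus
matrix, _ = generate_matrix(freqs, n_accessions=73, seed=1, mode="exact")

for marker in ("TB1", "TB2"):
    f = pattern_frequencies(matrix, marker)
    print(
        f"{marker}: major pattern frequency {f.iloc[0]:.4f}  "
        f"PIC(Botstein) {pic_botstein(f.to_numpy()):.4f}  "
        f"PIC(1-sum p^2) {pic_simple(f.to_numpy()):.4f}"
    )

summary = panel_summary(matrix, pic_variant="botstein")
print(
    f"\npanel: mean PIC {summary.mean_pic:.4f}, "
    f"range {summary.pic_range[0]:.4f}-{summary.pic_range[1]:.4f}"
)
print(
    f"discrimination: {summary.unique_profile_count}/73 unique profiles, "
    f"{summary.resolved_pair_fraction:.3f} of accession pairs resolved, "
    f"mean pairwise difference {summary.mean_pairwise_difference:.1f} markers"
)
# A locus typed a in 41/73 accessions has Botstein PIC 0.3712; one typed a
# in 72/73 has 0.0267 — the informativeness range of a biallelic panel.
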