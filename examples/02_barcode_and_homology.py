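"""Encode accession genotypes as black-and-white barcodes and compare them.

Builds a small a/b genotype matrix (each call compares an accession's PCR
product to the reference variety), renders 1D and 2D barcodes, and computes
pairwise homology — the fraction of markers with identical banding patterns.
"""

from indelbarcode import encode_barcode, decode_barcode, generate_matrix, homology

matrix, _ = generate_matrix(
    [0.6, 0.9, 0.75, 0.8, 0.65, 0.95, 0.7, 0.85, 0.6, 0.9] * 5,
    n_accessions=4,
    seed=11,
)

for profile in matrix.profiles:
    strip = encode_barcode(profile, matrix.marker_ids, layout="1D")
    block = encode_barcode(profile, matrix.marker_ids, layout="2D")  # 5 x 10 grid
    assert decode_barcode(block) == profile  # lossless
    print(f"{profile.accession_id}: {strip.to_text()}")

print()
p1, p2 = matrix.profiles[0], matrix.profiles[1]
h = homology(p1, p2)
d = p1.differences(p2)
print(
    f"homology({p1.accession_id}, {p2.accession_id}) = {h:.2f} "
    f"({d} of {len(matrix.marker_ids)} markers differ)"
)
# A homology of 0.86 means the two accessions share banding patterns at 43
# of 50 markers; 1 - homology is the simple-matching distance used for trees.
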