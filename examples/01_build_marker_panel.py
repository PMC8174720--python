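"""Select a PCR-typeable co-dominant InDel panel from variant calls.

Generates a synthetic resequencing bundle (reference fragments, a
multi-accession VCF, a primer table) with 12 panel-grade loci hidden among
80 decoys, then runs the selection funnel: InDel length window (10-20 bp),
panel homozygosity, polymorphism, and a 150-231 bp amplicon-size window.
"""

from indelbarcode import (
    FilterLog,
    SelectionConfig,
    SyntheticPanelConfig,
    amplicon_size_filter,
    build_marker_loci,
    filter_candidates,
    generate_panel,
)

cfg = SyntheticPanelConfig(n_accessions=26, n_markers=12, n_decoy_variants=80)
panel = generate_panel(cfg, seed=42)

log = FilterLog()
selection = SelectionConfig()
survivors = filter_candidates(panel.variants, panel.accessions, selection, log)
loci = build_marker_loci(survivors, panel.primer_table, panel.reference, selection, log)
kept = amplicon_size_filter(loci, selection, log)

print("selection funnel (stage -> surviving variants):")
for stage, n in log.stage_counts:
    print(f"  {stage:>14s}: {n}")
print()
print("selected markers (ref/alt amplicon sizes differ by the InDel length):")
for l in kept[:5]:
    print(
        f"  {l.marker_id:>5s}  {l.indel_length:+3d} bp InDel  "
        f"ref {l.ref_amplicon_bp} bp / alt {l.alt_amplicon_bp} bp"
    )
print(f"  ... {len(kept)} markers total; "
      f"recovered planted panel: {sorted(l.marker_id for l in kept) == sorted(panel.truth.planted_ids())}")

# Each surviving marker can be typed on a gel: the two homozygous classes
# give products whose sizes differ by the planted InDel length, so every
# accession scores as reference-like (a) or variant (b) at each marker.
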