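# Methods

This note documents the models, conventions and numerical choices behind
`indelbarcode`, and what the synthetic data generator does and does not
emulate.

## Variant model and coordinates

Variants are biallelic InDels in the anchored VCF representation: `pos` is
the 1-based coordinate of the shared anchor base, the reference and
alternative alleles differ in length, and the signed InDel length is
`len(alt) − len(ref)` (positive = insertion relative to the reference).
Internal sequence arithmetic is 0-based half-open. Multi-allelic records are
decomposed into one biallelic record per alternative allele; a sample whose
genotype carries an allele from a *different* alternative is treated as
missing in the decomposed record. Only diploid calls are supported (the
germplasm this workflow targets is selfed toward homozygosity); other
ploidies raise an error rather than being silently reinterpreted. Phased and
unphased genotype separators are both accepted.

Per-accession heterozygous rate is reported as `HET / (HET + HOM_ALT)`: the
denominator counts only calls that differ from the reference variety, which
is how resequencing panels scored against a single reference conventionally
report it. An accession with no non-reference calls gets rate 0 and an
explicit `no_alt_calls` flag rather than a NaN.

## Marker selection

The funnel applies, in a fixed logged order, predicates whose conjunction is
order-independent:

1. **length** — `min_abs_len ≤ |InDel length| ≤ max_abs_len`, default
   10–20 bp. Shorter events do not separate reliably on low-percentage
   agarose; much longer events start failing PCR consistency.
2. **zygosity** — no panel accession heterozygous at the site (default on).
   A panel-wide homozygous site gives every accession exactly one band, so a
   single gel lane scores it unambiguously.
3. **polymorphism** — at least one panel accession homozygous-alternative
   *and* at least one homozygous-reference (default on). The reference
   variety is deliberately not counted as an implicit reference-carrying
   panel member: a site where every accession carries the alternative allele
   cannot discriminate among the accessions themselves, which is what the
   panel is for.
4. **amplicon size** — both predicted allele products inside
   `[amplicon_min, amplicon_max]`, default 150–231 bp.

Both window defaults are configurable; the defaults jointly satisfy the
published descriptions of such panels (candidate lengths quoted variously as
"more than 10 bp" and "5–20 bp" — the 10–20 bp default sits in the
intersection). Every dropped variant is recorded with its first failing rule
and per-stage survivor counts are logged.

### In-silico PCR

The e-PCR model is intentionally minimal: a primer binds where it aligns to
the plus strand (forward primer) or where its reverse complement aligns
downstream (reverse primer) with at most `max_mismatch` Hamming mismatches;
no indels in the binding site; when mismatches are allowed, the 3′-terminal
base of each primer must still match exactly, since 3′ mismatches kill
extension. Product length runs from the forward primer's 5′ end to the
reverse primer's 5′ end inclusive. Primer thermodynamics (Tm, GC content,
secondary structure) are not modeled — primer design is upstream of this
package and primer sequences are consumed from a table.

The alternative-allele product size is computed by substituting the
alternative allele into the reference sequence and re-running e-PCR, so the
two sizes differ by exactly the InDel length by construction; a marker whose
InDel lies outside its amplicon, or that yields zero or more than
`max_products` (default 1) products on either haplotype, is rejected by name.

## Genotype codes and barcodes

Calls are `a` (same amplicon as the reference variety), `b` (different),
`h` (heterozygous, both bands) and `-` (missing/failed). The 1D barcode is
one module per marker; the 2D layout is row-major in panel order with a
default of 5 rows (a 50-marker panel renders as a 5×10 block), padding cells
after the last marker, and a one-cell quiet border added only at render
time. The grid dimensions, marker order and accession id are stored in a
JSON sidecar, making decoding lossless; encode→decode is a bijection on
`{a,b}`ⁿ for any grid that fits.

The strict (default) rendering policy refuses `h` and `-` — a binary
barcode has no cell state for them — and names the offending markers.
Lenient mode renders `h` as a half-tone and `-` as a light cell; both decode
back to their symbols. The barcode is a plain cell grid, not a checksummed
retail symbology: the figure-style output conveys marker states only. SVG
output is deterministic (identical profile and layout give byte-identical
files).

Homology between two profiles is the simple matching coefficient
(matches / compared markers); markers where either call is `-` drop out of
both numerator and denominator under the default policy, and the denominator
actually used is available via `homology_counts`. `h` matches only `h`.

## Diversity statistics

Frequencies are **pattern frequencies over accessions** — each accession
contributes one banding pattern per marker — not chromosome-count allele
frequencies. This is the convention under which a 73-accession panel shows
count-derived frequencies like 41/73 = 0.5616. Missing calls leave the
denominator.

Two PIC variants are computed and always reported side by side:

* `pic_simple` = 1 − Σ pⱼ² (the expected-heterozygosity form);
* `pic_botstein` = 1 − Σ pⱼ² − Σⱼ Σₖ>ⱼ 2 pⱼ² pₖ² (Botstein et al. 1980),
  the default, because published crop-fingerprinting panel tables are
  conventionally computed with it (at p = 0.5616 it gives 0.3712 where the
  simple form gives 0.4924).

For a biallelic locus the Botstein PIC is strictly decreasing in the major
frequency on (0.5, 1], so a panel's PIC range endpoints always coincide with
its frequency extremes. Panel summaries report the unweighted mean PIC, the
range, the number of unique profiles, the fraction of resolved accession
pairs (pairs differing at ≥1 comparable marker) with unresolved pairs listed
by id, and — because "average difference" is ambiguous — both the mean
pairwise Hamming difference over unordered pairs and each accession's
difference from the all-`a` reference profile. Tables round to 4 decimals;
machine output keeps full precision.

## Distances, trees, PCA

The distance matrix is 1 − homology under the same missing policy; a pair
with zero comparable markers is an error naming the pair. Simple-matching
distances need not satisfy the triangle inequality, and nothing downstream
assumes it.

Neighbor joining is the canonical Saitou–Nei algorithm with the
Studier–Keppler criterion Q(i,j) = (r−2)·d(i,j) − Rᵢ − Rⱼ. "Weighted NJ" as
implemented in some desktop packages is an undocumented variant; canonical
NJ is the reproducible baseline and the choice is recorded in run metadata.
Determinism: among exactly tied Q minima the pair whose clade labels
(lexicographically smallest leaf under each node) sort lowest is joined;
negative limb lengths are clamped to zero with the deficit logged. The
result is the standard unrooted topology returned with a trifurcating root;
NJ is exact on additive matrices (verified against tip-to-tip distances) and
its topology is cross-checked in the tests against an independent NJ
implementation (Robinson–Foulds 0), which serves only as an oracle. Newick
output carries branch lengths at 6 significant digits and round-trips
through the parser.

PCA encodes `a`→0, `b`→1, `h`→0.5 (intermediate dosage), mean-imputes `-`
per locus, centers columns, and takes the full SVD; each component's sign is
fixed so its largest-magnitude loading is positive, making coordinates
reproducible. In distances, by contrast, `h` is its own state and mismatches
both homozygous calls. STRUCTURE export writes two integer rows per
accession (alleles 1/2, −9 missing).

## Synthetic data generator

`generate_panel` emulates the statistical structure of a resequenced
germplasm panel at study scale, and these defaults *are* the test
conditions: 73 accessions, 50 planted panel-grade loci, 500 decoys,
heterozygous rate 0.10 among non-reference calls at background loci,
per-locus major-pattern frequencies drawn uniformly from 0.55–0.99
(spanning the 0.56–0.99 range such panels report), InDel lengths 10–20 bp,
amplicons 150–231 bp. Planted loci satisfy every selection rule (in
particular they are panel-homozygous — that is the design criterion, so
`het_probability` does not apply to them). Decoys split 80/8/5/7% into four
classes, each violating exactly one rule: 1–4 bp events (matching the
real-data dominance of ≤4 bp InDels), heterozygous-in-panel,
monomorphic-alternative, and out-of-window amplicons (the only decoy class
that carries primers, so it reaches and fails the amplicon stage).

Reference "genomes" are independent fragments, one contig per variant
region, with synthesized coordinates; linkage, chromosome structure,
sequencing error and read-level simulation are not modeled. Passing tests
therefore demonstrate correctness of the selection, coding and statistics
machinery under the stated frequency structure — not robustness to
alignment or variant-calling artifacts, which are upstream of this package.

`generate_matrix` draws a/b matrices directly from per-locus major
frequencies in two modes. Sampling mode draws i.i.d. calls (for
recovery/power checks). Exact-count mode assigns `round(p·n)` major calls at
rng-chosen accessions; nearest-integer rounding (rather than floor) is used
so that count-derived frequencies such as 72/73 = 0.98630 are hit exactly
from their rounded 4-decimal representations. All generator output is
byte-reproducible from the seed.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely at desk scale: the largest
jobs are the 550-variant study-scale funnel (73 accessions), a 5,000-variant
heterozygosity recovery, 500-profile barcode bijection checks, and 100 NJ
reconstructions at 5–12 leaves — seconds in total. Frequency-sum validation
uses a 1e-9 tolerance; distance symmetry 1e-12; PIC oracle agreement 1e-12.
Degenerate inputs are defined rather than left to chance: empty variant
lists filter to empty, an all-reference accession reports zero heterozygosity
with a flag, a monomorphic locus has PIC 0, and an all-missing marker column
is an error.

## Known limitations

* The in-silico funnel cannot reproduce wet-lab attrition (primer sets
  discarded for gel behavior); it models only sequence-level selection.
* "Weighted" NJ variants and admixture/STRUCTURE modeling are out of scope;
  the genotype matrix is exported in STRUCTURE's input format instead.
* Primer binding ignores thermodynamics and indel-containing binding sites.
* Barcodes are read back from their own metadata, not from photographs.
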