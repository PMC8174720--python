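# indelbarcode

Co-dominant InDel marker panels and black-and-white genotype barcodes for
identifying crop germplasm accessions.

Curating a germplasm collection needs a cheap, reproducible way to tell
accessions apart. A practical solution is a small panel of insertion/deletion
(InDel) markers typed by ordinary PCR and gel electrophoresis: each marker is a
10–20 bp length polymorphism placed inside a 150–231 bp amplicon, so the
reference-like and variant alleles separate cleanly on an agarose gel and the
heterozygote shows both bands (co-dominance). Scoring every accession against a
reference variety turns its genotype into a string over `a` (same product as
the reference), `b` (different product), `h` (heterozygous) and `-` (failed),
which renders directly as a black-and-white barcode — white for `a`, black for
`b` — that a curator can compare by eye.

`indelbarcode` implements the full desk side of that workflow:

* **variant ingestion** — read multi-accession VCF against a reference,
  classify calls by zygosity, summarize heterozygous rates and the InDel
  length spectrum;
* **marker selection** — a filter funnel (length window → panel homozygosity →
  polymorphism → amplicon-size window) plus a minimal in-silico PCR model
  (Hamming mismatches, exact 3′-terminal base) that predicts reference and
  alternative amplicon sizes from a primer table and reference FASTA;
* **genotype barcodes** — lossless 1D strip and 2D block (default 5×10)
  encodings with PNG/SVG/text output, and inter-accession homology;
* **diversity statistics** — pattern frequencies, two PIC variants, panel
  discrimination power;
* **phylogeny & structure** — simple-matching distances, canonical
  neighbor-joining with newick output, PCA coordinates, STRUCTURE-format
  export;
* **synthetic data** — a generator that emulates a study-scale panel
  (73 accessions, 50 planted marker loci among decoy variants) so the whole
  pipeline is testable without any download.

## The statistics at the core

For marker *i* with pattern frequencies *p*<sub>ij</sub> (each accession
contributes one banding pattern, so a locus typed `a` in 41 of 73 accessions
has *p* = 41/73 = 0.5616), two polymorphism-information-content variants are
computed:

* simple form: PIC<sub>i</sub> = 1 − Σ<sub>j</sub> *p*<sub>ij</sub>²
* Botstein form (default): PIC<sub>i</sub> = 1 − Σ<sub>j</sub> *p*<sub>ij</sub>²
  − Σ<sub>j</sub> Σ<sub>k&gt;j</sub> 2 *p*<sub>ij</sub>² *p*<sub>ik</sub>²

The Botstein form is the default because it is what marker-panel reports in
crop fingerprinting conventionally tabulate; both are always reported. Between
two accessions, homology is the simple matching coefficient (fraction of
markers with identical calls), and 1 − homology is the distance used for
neighbor joining.

## Worked example

```bash
python examples/03_diversity_statistics.py
```

prints

```
TB1: major pattern frequency 0.5616  PIC(Botstein) 0.3712  PIC(1-sum p^2) 0.4924
TB2: major pattern frequency 0.9863  PIC(Botstein) 0.0267  PIC(1-sum p^2) 0.0270

panel: mean PIC 0.2450, range 0.0267-0.3712
discrimination: 73/73 unique profiles, 1.000 of accession pairs resolved, mean pairwise difference 15.3 markers
```

TB1 is a maximally informative biallelic locus for this panel — 41 of 73
accessions share the reference pattern, giving a Botstein PIC of 0.3712 —
while TB2 (72 of 73 reference-like) is barely informative at 0.0267. The
panel resolves every pair of accessions, with an average of ~15 markers
differing between two accessions. The other examples build a marker panel
from a synthetic VCF (`01`), render and decode barcodes (`02`), and compute
the NJ tree and PCA (`04`).

The same operations are available from the shell:

```bash
indelbarcode simulate --seed 42 --out-dir sim
indelbarcode select --vcf sim/variants.vcf --primers sim/primers.tsv \
    --fasta sim/reference.fasta --out-dir sel
indelbarcode report --matrix sel/genotype_matrix.csv --out-dir report
```

Every command writes a `run_config.json` provenance sidecar (parameters,
input hashes, version); re-running with identical inputs reproduces outputs
byte for byte.

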