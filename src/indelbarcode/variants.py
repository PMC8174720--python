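"""Reading and classifying biallelic InDel variants from multi-sample VCF.

Variants are held in the anchored VCF representation (1-based ``pos`` at the
shared anchor base); all internal sequence arithmetic is 0-based half-open.
Multi-allelic records are decomposed into biallelic records; alleles that
belong to neither the reference nor the decomposed alternative are treated as
missing for that sample.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "Zygosity",
    "InDelVariant",
    "AccessionRecord",
    "read_variants",
    "write_variants",
    "indel_length",
    "classify_zygosity",
    "zygosity_counts",
    "length_spectrum",
    "read_accession_metadata",
]


class Zygosity(enum.Enum):
    """Diploid genotype class of one accession at one biallelic site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


#: VCF GT strings for each zygosity class (unphased form; writer output).
_GT_STRING = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}


@dataclass
class InDelVariant:
    """One biallelic insertion/deletion site with per-accession genotypes.

    ``pos`` is the 1-based coordinate of the anchor base, as in VCF.
    ``genotypes`` maps accession id to :class:`Zygosity`.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: dict[str, Zygosity] = field(default_factory=dict)
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass
class AccessionRecord:
    """Panel metadata for one germplasm accession (landrace or variety)."""

    accession_id: str
    registry_id: str = ""
    country: str = ""
    rutin_mg_per_100g: float | None = None


def indel_length(v: InDelVariant) -> int:
    """Signed InDel length in bp: ``len(alt) - len(ref)``.

    Positive values are insertions relative to the reference, negative are
    deletions. Raises ``ValueError`` for a length-preserving (non-InDel)
    record.
    """
    delta = len(v.alt_allele) - len(v.ref_allele)
    if delta == 0:
        raise ValueError(
            f"{v.chrom}:{v.pos} ref and alt have equal length; not an InDel"
        )
    return delta


def classify_zygosity(v: InDelVariant, accession: str) -> Zygosity:
    """Zygosity class of ``accession`` at site ``v``.

    ref/ref -> HOM_REF, ref/alt -> HET, alt/alt -> HOM_ALT (both alleles
    identical to the alternative genotype), absent call -> MISSING.
    """
    try:
        return v.genotypes[accession]
    except KeyError:
        raise KeyError(
            f"accession {accession!r} has no genotype at {v.chrom}:{v.pos}"
        ) from None


def _zygosity_from_gt(alleles: tuple, alt_index: int, sample: str, where: str) -> Zygosity:
    """Map a pysam GT tuple onto a biallelic zygosity for one split alt."""
    if alleles is None or len(alleles) == 0 or all(a is None for a in alleles):
        return Zygosity.MISSING
    if len(alleles) != 2:
        raise ValueError(
            f"sample {sample!r} at {where} has ploidy {len(alleles)}; only diploid calls are supported"
        )
    if any(a is None for a in alleles):
        warnings.warn(f"half-missing GT for {sample!r} at {where}; treated as missing")
        return Zygosity.MISSING
    coded = []
    for a in alleles:
        if a == 0:
            coded.append(0)
        elif a == alt_index:
            coded.append(1)
        else:  # allele from another alt of a multi-allelic record
            return Zygosity.MISSING
    s = sum(coded)
    return (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)[s]


def read_variants(
    vcf_source: str | Path,
    accessions: Sequence[str] | None = None,
) -> list[InDelVariant]:
    """Read InDel records for the requested accessions from a VCF 4.x file.

    SNPs and other length-preserving records are excluded; multi-allelic
    records are decomposed into biallelic records. The result is ordered by
    (chrom, pos). Unknown sample names raise ``KeyError``.
    """
    out: list[InDelVariant] = []
    with pysam.VariantFile(str(vcf_source)) as vf:
        available = list(vf.header.samples)
        if accessions is None:
            accessions = available
        else:
            unknown = [a for a in accessions if a not in set(available)]
            if unknown:
                raise KeyError(
                    f"sample(s) {', '.join(unknown)} not present in {vcf_source}"
                )
        for rec in vf:
            if rec.alts is None:
                continue
            for k, alt in enumerate(rec.alts, start=1):
                if alt is None or len(alt) == len(rec.ref):
                    continue  # SNP / MNP / symbolic: not an InDel
                if not set(alt.upper()) <= set("ACGT"):
                    continue  # symbolic or ambiguous alt
                where = f"{rec.chrom}:{rec.pos}"
                gts = {
                    s: _zygosity_from_gt(
                        rec.samples[s].get("GT"), k, s, where
                    )
                    for s in accessions
                }
                out.append(
                    InDelVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        genotypes=gts,
                        variant_id=rec.id,
                    )
                )
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def write_variants(
    variants: Iterable[InDelVariant],
    path: str | Path,
    accessions: Sequence[str] | None = None,
) -> Path:
    """Write variants to an uncompressed VCF 4.2 file with GT fields only."""
    variants = list(variants)
    if accessions is None:
        seen: list[str] = []
        for v in variants:
            for a in v.genotypes:
                if a not in seen:
                    seen.append(a)
        accessions = seen
    contigs: list[str] = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=indelbarcode\n")
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(accessions)) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            gts = [
                _GT_STRING[v.genotypes.get(a, Zygosity.MISSING)] for a in accessions
            ]
            row = [
                v.chrom,
                str(v.pos),
                v.variant_id or ".",
                v.ref_allele,
                v.alt_allele,
                ".",
                ".",
                ".",
                "GT",
            ] + gts
            fh.write("\t".join(row) + "\n")
    return path


def zygosity_counts(
    variants: Sequence[InDelVariant],
    accessions: Sequence[str],
) -> pd.DataFrame:
    """Per-accession counts of homozygous-alternative and heterozygous calls.

    ``het_rate = HET / (HET + HOM_ALT)``: the denominator counts only calls
    that differ from the reference, matching how resequencing panels report
    heterozygous rates against a reference variety. Accessions with no
    non-reference calls get het_rate 0 and ``no_alt_calls=True``.
    """
    if not variants or not accessions:
        raise ValueError("variants and accessions must be nonempty")
    rows = []
    for a in accessions:
        hom_alt = sum(
            1 for v in variants if v.genotypes.get(a) is Zygosity.HOM_ALT
        )
        het = sum(1 for v in variants if v.genotypes.get(a) is Zygosity.HET)
        denom = hom_alt + het
        rows.append(
            {
                "accession": a,
                "hom_alt": hom_alt,
                "het": het,
                "het_rate": het / denom if denom else 0.0,
                "no_alt_calls": denom == 0,
            }
        )
    return pd.DataFrame(rows).set_index("accession")


def length_spectrum(
    variants: Sequence[InDelVariant],
    bins: Sequence[int],
) -> pd.Series:
    """Histogram of absolute InDel lengths.

    ``bins`` are strictly increasing left edges; the last bin is open-ended.
    E.g. ``bins=[1, 5, 10]`` gives bins [1,4], [5,9] and >=10 bp. Counts sum
    to the number of variants.
    """
    edges = list(bins)
    if any(b >= c for b, c in zip(edges, edges[1:])):
        raise ValueError("bins must be strictly increasing")
    lengths = np.array([abs(indel_length(v)) for v in variants], dtype=float)
    counts, _ = np.histogram(lengths, bins=edges + [np.inf])
    labels = [
        f"{lo}-{hi - 1}" for lo, hi in zip(edges, edges[1:])
    ] + [f">={edges[-1]}"]
    return pd.Series(counts.astype(int), index=labels, name="count")


def read_accession_metadata(path: str | Path) -> list[AccessionRecord]:
    """Read accession metadata CSV (accession_id, registry_id, country[, rutin])."""
    df = pd.read_csv(path)
    if "accession_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'accession_id'")
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise ValueError(f"{path}: duplicate accession_id {dup!r}")
    recs = []
    for _, row in df.iterrows():
        recs.append(
            AccessionRecord(
                accession_id=str(row["accession_id"]),
                registry_id=str(row.get("registry_id", "") or ""),
                country=str(row.get("country", "") or ""),
                rutin_mg_per_100g=(
                    float(row["rutin"]) if "rutin" in df.columns and pd.notna(row["rutin"]) else None
                ),
            )
        )
    return recs
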