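"""Synthetic reference fragments, variant calls, primers and genotype matrices.

The generator emulates the statistical structure of a resequenced crop
germplasm panel typed against a reference variety: ~73 accessions, 50
planted panel-grade InDel loci (10-20 bp, homozygous across the panel,
polymorphic, 150-231 bp amplicons) among decoy variants that each violate
at least one selection rule, per-accession heterozygous rates around 10%
of non-reference calls, and per-locus major-pattern frequencies spanning
~0.55-0.99. Reference fragments are independent sequences (one contig per
variant region); chromosome-scale linkage is not modeled.

Everything is reproducible from the seed, and every emitted file is in the
same format the rest of the package consumes (FASTA, VCF 4.2, primer TSV,
genotype CSV, truth-table JSON).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codec import GenotypeMatrix, GenotypeProfile
from .markers import revcomp
from .variants import InDelVariant, Zygosity, write_variants

__all__ = [
    "SyntheticPanelConfig",
    "TruthTable",
    "SyntheticPanel",
    "generate_panel",
    "generate_matrix",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Study-scale defaults for the synthetic germplasm panel."""

    n_accessions: int = 73
    n_markers: int = 50
    n_decoy_variants: int = 500
    het_probability: float = 0.10
    major_freq_range: tuple[float, float] = (0.55, 0.99)
    indel_length_range: tuple[int, int] = (10, 20)
    amplicon_range: tuple[int, int] = (150, 231)
    fragment_length: int = 600
    primer_length: int = 20
    # decoy class mix: short (1-4 bp), heterozygous-in-panel, monomorphic,
    # out-of-window amplicon
    decoy_mix: tuple[float, float, float, float] = (0.80, 0.08, 0.05, 0.07)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.het_probability <= 1:
            raise ValueError("het_probability outside [0,1]")
        for lo, hi in (
            self.major_freq_range,
            self.indel_length_range,
            self.amplicon_range,
        ):
            if lo > hi:
                raise ValueError("invalid range in config")
        if abs(sum(self.decoy_mix) - 1.0) > 1e-9:
            raise ValueError("decoy_mix must sum to 1")
        min_inner = self.amplicon_range[0] - 2 * self.primer_length
        if min_inner < self.indel_length_range[1] + 3:
            raise ValueError(
                "amplicon window too small to hold primers plus the largest InDel"
            )


@dataclass
class TruthTable:
    """Ground truth behind a synthetic bundle, consistent with every file."""

    seed: int
    accessions: list[str]
    planted: list[dict]
    decoys: list[dict]
    matrix_freqs: dict = field(default_factory=dict)

    def planted_ids(self) -> list[str]:
        return [p["marker_id"] for p in self.planted]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticPanel:
    """In-memory synthetic bundle: reference, variants, primers, truth."""

    reference: dict[str, str]
    variants: list[InDelVariant]
    primer_table: pd.DataFrame
    truth: TruthTable
    accessions: list[str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit FASTA + VCF + primer TSV + truth JSON into a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "reference.fasta",
            "vcf": out / "variants.vcf",
            "primers": out / "primers.tsv",
            "truth": out / "truth.json",
        }
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self.reference.items())
        ]
        SeqIO.write(records, paths["fasta"], "fasta")
        write_variants(self.variants, paths["vcf"], self.accessions)
        self.primer_table.to_csv(paths["primers"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _background_genotypes(
    rng: np.random.Generator,
    accessions: Sequence[str],
    het_probability: float,
    nonref_prob: float,
) -> dict[str, Zygosity]:
    """Draw genotypes: non-reference with prob q, HET within the non-reference
    calls with the configured heterozygous rate."""
    gts = {}
    for a in accessions:
        if rng.random() < nonref_prob:
            gts[a] = (
                Zygosity.HET if rng.random() < het_probability else Zygosity.HOM_ALT
            )
        else:
            gts[a] = Zygosity.HOM_REF
    return gts


def _panel_genotypes(
    rng: np.random.Generator, accessions: Sequence[str], major_freq: float
) -> dict[str, Zygosity]:
    """Homozygous, polymorphic genotypes with HOM_REF as the major pattern."""
    gts = {
        a: Zygosity.HOM_REF if rng.random() < major_freq else Zygosity.HOM_ALT
        for a in accessions
    }
    calls = list(gts.values())
    if Zygosity.HOM_ALT not in calls:
        gts[rng.choice(np.array(accessions))] = Zygosity.HOM_ALT
    if Zygosity.HOM_REF not in calls:
        gts[rng.choice(np.array(accessions))] = Zygosity.HOM_REF
    return gts


def _build_region(
    rng: np.random.Generator,
    cfg: SyntheticPanelConfig,
    signed_len: int,
    amplicon_ref_bp: int,
) -> tuple[str, int, str, str, str, str]:
    """Construct one reference fragment with a primer-flanked InDel site.

    Returns (fragment, pos_1based, ref_allele, alt_allele, forward, reverse).
    """
    plen = cfg.primer_length
    ref_allele_len = 1 + (-signed_len if signed_len < 0 else 0)
    inner = amplicon_ref_bp - 2 * plen
    if inner < ref_allele_len + 2:
        raise ValueError("amplicon shorter than primers plus the InDel site")
    for _ in range(20):
        fwd = _random_seq(rng, plen)
        rev_site = _random_seq(rng, plen)  # plus-strand sequence at the site
        left_pad = int(rng.integers(1, inner - ref_allele_len))
        right_pad = inner - ref_allele_len - left_pad
        ref_allele = _random_seq(rng, ref_allele_len)
        if signed_len > 0:
            alt_allele = ref_allele + _random_seq(rng, signed_len)
        else:
            alt_allele = ref_allele[0]
        amplicon = fwd + _random_seq(rng, left_pad) + ref_allele + _random_seq(rng, right_pad) + rev_site
        flank = max(20, (cfg.fragment_length - amplicon_ref_bp) // 2)
        frag = _random_seq(rng, flank) + amplicon + _random_seq(rng, flank)
        # the e-PCR model binds the forward primer and revcomp(reverse) on
        # the plus strand; both must occur exactly once
        if frag.count(fwd) == 1 and frag.count(rev_site) == 1:
            pos = flank + plen + left_pad + 1  # 1-based anchor
            return frag, pos, ref_allele, alt_allele, fwd, revcomp(rev_site)
    raise RuntimeError("could not place unique primer sites (pathological RNG state)")


def generate_panel(
    cfg: SyntheticPanelConfig = SyntheticPanelConfig(),
    seed: int | None = None,
) -> SyntheticPanel:
    """Generate a full synthetic bundle: reference, variants, primers, truth.

    Planted loci satisfy every selection rule; each decoy violates at least
    one (recorded as its ``failing_rule``). Panel marker ids TB1..TBn are
    assigned in genomic (contig, pos) order.
    """
    if seed is None:
        seed = cfg.rng_seed
    rng = np.random.default_rng(seed)
    accessions = [f"HLB{1001 + i}" for i in range(cfg.n_accessions)]

    n_total = cfg.n_markers + cfg.n_decoy_variants
    n_short = int(round(cfg.decoy_mix[0] * cfg.n_decoy_variants))
    n_het = int(round(cfg.decoy_mix[1] * cfg.n_decoy_variants))
    n_mono = int(round(cfg.decoy_mix[2] * cfg.n_decoy_variants))
    n_bad_amp = cfg.n_decoy_variants - n_short - n_het - n_mono

    kinds = (
        ["planted"] * cfg.n_markers
        + ["short"] * n_short
        + ["het"] * n_het
        + ["monomorphic"] * n_mono
        + ["bad_amplicon"] * n_bad_amp
    )
    rng.shuffle(kinds)

    width = len(str(n_total))
    reference: dict[str, str] = {}
    variants: list[InDelVariant] = []
    primer_rows: list[dict] = []
    planted_raw: list[dict] = []
    decoys: list[dict] = []
    amp_lo, amp_hi = cfg.amplicon_range
    len_lo, len_hi = cfg.indel_length_range
    f_lo, f_hi = cfg.major_freq_range
    n_dec = 0

    for idx, kind in enumerate(kinds):
        chrom = f"scf{idx + 1:0{width}d}"
        if kind == "short":
            slen = int(rng.integers(1, 5)) * int(rng.choice([-1, 1]))
            ref_len = 1 + (-slen if slen < 0 else 0)
            frag = _random_seq(rng, 200)
            pos = int(rng.integers(20, 200 - ref_len - 20))
            ref_allele = frag[pos - 1 : pos - 1 + ref_len]
            alt_allele = (
                ref_allele + _random_seq(rng, slen) if slen > 0 else ref_allele[0]
            )
            if alt_allele == ref_allele:  # 1-bp substitution corner
                alt_allele = ref_allele + "A"
                slen = 1
            gts = _background_genotypes(
                rng, accessions, cfg.het_probability, float(rng.uniform(0.2, 0.8))
            )
            reference[chrom] = frag
            variants.append(InDelVariant(chrom, pos, ref_allele, alt_allele, gts))
            decoys.append(
                {"chrom": chrom, "pos": pos, "indel_length": slen, "failing_rule": "length"}
            )
            continue

        slen = int(rng.integers(len_lo, len_hi + 1)) * int(rng.choice([-1, 1]))
        if kind == "bad_amplicon":
            amp_ref = int(rng.integers(amp_hi + 10, amp_hi + 60))
        else:
            lo = amp_lo + (-slen if slen < 0 else 0)
            hi = amp_hi - (slen if slen > 0 else 0)
            amp_ref = int(rng.integers(lo, hi + 1))
        frag, pos, ref_allele, alt_allele, fwd, rev = _build_region(
            rng, cfg, slen, amp_ref
        )
        reference[chrom] = frag

        if kind == "het":
            gts = _background_genotypes(
                rng, accessions, cfg.het_probability, float(rng.uniform(0.2, 0.8))
            )
            if not any(z is Zygosity.HET for z in gts.values()):
                gts[accessions[int(rng.integers(0, len(accessions)))]] = Zygosity.HET
        elif kind == "monomorphic":
            # fixed for the alternative allele in every accession: passes the
            # length and zygosity stages, fails the polymorphism stage
            gts = {a: Zygosity.HOM_ALT for a in accessions}
        else:  # planted or bad_amplicon: homozygous and polymorphic
            major = float(rng.uniform(f_lo, f_hi))
            gts = _panel_genotypes(rng, accessions, major)

        variants.append(InDelVariant(chrom, pos, ref_allele, alt_allele, gts))
        if kind == "planted":
            planted_raw.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "indel_length": slen,
                    "target_major_freq": major,
                    "ref_amplicon_bp": amp_ref,
                    "alt_amplicon_bp": amp_ref + slen,
                    "forward": fwd,
                    "reverse": rev,
                    "genotypes": {
                        a: "a" if z is Zygosity.HOM_REF else "b" for a, z in gts.items()
                    },
                }
            )
        else:
            n_dec += 1
            decoys.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "indel_length": slen,
                    "failing_rule": {
                        "het": "heterozygous_in_panel",
                        "monomorphic": "monomorphic",
                        "bad_amplicon": "amplicon_size",
                    }[kind],
                }
            )
            if kind == "bad_amplicon":
                primer_rows.append(
                    {
                        "marker_id": f"DEC{n_dec:04d}",
                        "forward": fwd,
                        "reverse": rev,
                        "chrom": chrom,
                        "pos": pos,
                    }
                )

    # TB labels in genomic order over the planted loci
    planted_raw.sort(key=lambda p: (p["chrom"], p["pos"]))
    for i, p in enumerate(planted_raw, start=1):
        p["marker_id"] = f"TB{i}"
        primer_rows.append(
            {
                "marker_id": p["marker_id"],
                "forward": p["forward"],
                "reverse": p["reverse"],
                "chrom": p["chrom"],
                "pos": p["pos"],
            }
        )

    primer_table = pd.DataFrame(
        primer_rows, columns=["marker_id", "forward", "reverse", "chrom", "pos"]
    ).sort_values("marker_id", ignore_index=True)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    truth = TruthTable(
        seed=seed, accessions=accessions, planted=planted_raw, decoys=decoys
    )
    return SyntheticPanel(reference, variants, primer_table, truth, accessions)


def generate_matrix(
    freqs: Sequence[float],
    n_accessions: int = 73,
    seed: int = 0,
    mode: str = "sampling",
    marker_ids: Sequence[str] | None = None,
    accession_ids: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw an accession x marker a/b matrix with given major-pattern frequencies.

    ``mode='sampling'`` draws each call independently ('a' with the locus
    frequency). ``mode='exact'`` assigns exactly ``round(p * n)`` 'a' calls
    per locus (placed at rng-chosen accessions), which reproduces printed
    count-derived frequencies such as 41/73 exactly.
    """
    freqs = list(map(float, freqs))
    if any(not 0.0 <= f <= 1.0 for f in freqs):
        raise ValueError("frequencies must lie in [0, 1]")
    if mode not in ("sampling", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if marker_ids is None:
        marker_ids = [f"TB{i + 1}" for i in range(len(freqs))]
    if accession_ids is None:
        accession_ids = [f"HLB{1001 + i}" for i in range(n_accessions)]
    n = n_accessions
    cols = []
    for p in freqs:
        if mode == "sampling":
            col = np.where(rng.random(n) < p, "a", "b")
        else:
            n_major = int(round(p * n))
            col = np.array(["b"] * n, dtype=object)
            col[rng.permutation(n)[:n_major]] = "a"
        cols.append(col)
    grid = np.column_stack(cols)
    profiles = [
        GenotypeProfile(acc, tuple(grid[i])) for i, acc in enumerate(accession_ids)
    ]
    matrix = GenotypeMatrix(list(marker_ids), profiles)
    truth = TruthTable(
        seed=seed,
        accessions=list(accession_ids),
        planted=[],
        decoys=[],
        matrix_freqs={
            "mode": mode,
            "target": dict(zip(marker_ids, freqs)),
        },
    )
    return matrix, truth
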