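"""Candidate InDel filtering and in-silico PCR amplicon prediction.

The selection chain mirrors a PCR-typeable co-dominant panel design: keep
biallelic InDels in a length window, require the panel to be homozygous at
the site (heterozygotes are ambiguous on a gel), require polymorphism among
the panel accessions, then keep loci whose predicted reference and
alternative amplicons both fall in an electrophoresis-friendly size window.

The e-PCR model is deliberately minimal: Hamming mismatches on the aligned
primer with an exactly-matching 3'-terminal base, no indels in the binding
site, no thermodynamics. Primer design itself is out of scope — primer
sequences are consumed from a table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import InDelVariant, Zygosity, indel_length

logger = logging.getLogger(__name__)

__all__ = [
    "PrimerPair",
    "AmpliconPrediction",
    "MarkerLocus",
    "SelectionConfig",
    "FilterLog",
    "MarkerSelectionError",
    "filter_candidates",
    "epcr",
    "predict_allele_amplicons",
    "amplicon_size_filter",
    "build_marker_loci",
    "read_primer_table",
    "write_panel_table",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class MarkerSelectionError(ValueError):
    """Raised when a marker violates the single-product amplicon contract."""


@dataclass(frozen=True)
class PrimerPair:
    """A synthesized primer pair, both sequences written 5'->3'.

    ``reverse_seq`` is the reverse primer as synthesized, i.e. the reverse
    complement of the plus strand at its binding site.
    """

    marker_id: str
    forward_seq: str
    reverse_seq: str
    min_length: int = 15

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            up = seq.upper()
            object.__setattr__(self, f"{name}_seq", up)
            if not set(up) <= set("ACGT"):
                raise ValueError(f"{self.marker_id}: {name} primer has non-ACGT characters")
            if len(up) < self.min_length:
                raise ValueError(
                    f"{self.marker_id}: {name} primer shorter than {self.min_length} nt"
                )


@dataclass(frozen=True)
class AmpliconPrediction:
    """One predicted PCR product on a template (0-based half-open span)."""

    template_id: str
    start: int
    end: int
    forward_mismatches: int
    reverse_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MarkerLocus:
    """A selected panel marker with predicted allele amplicon sizes."""

    marker_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    indel_length: int
    primer_pair: PrimerPair
    ref_amplicon_bp: int | None = None
    alt_amplicon_bp: int | None = None
    annotation_class: str = "intergenic"

    ANNOTATION_CLASSES = ("coding", "5'UTR", "3'UTR", "splice", "intergenic")

    def __post_init__(self) -> None:
        if self.annotation_class not in self.ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.annotation_class!r}")
        if self.ref_amplicon_bp is not None and self.alt_amplicon_bp is not None:
            if abs(self.ref_amplicon_bp - self.alt_amplicon_bp) != abs(self.indel_length):
                raise ValueError(
                    f"{self.marker_id}: amplicon size difference does not equal |indel length|"
                )


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable thresholds of the marker selection funnel.

    Defaults target gel-resolvable co-dominant InDels: 10-20 bp length
    difference typed as 150-231 bp products, homozygous across the panel,
    polymorphic among panel accessions, exact primer binding.
    """

    min_abs_len: int = 10
    max_abs_len: int = 20
    amplicon_min: int = 150
    amplicon_max: int = 231
    require_homozygous_panel: bool = True
    require_polymorphic: bool = True
    max_primer_mismatch: int = 0
    max_products: int = 1

    def __post_init__(self) -> None:
        if self.min_abs_len > self.max_abs_len:
            raise ValueError("min_abs_len > max_abs_len")
        if self.amplicon_min > self.amplicon_max:
            raise ValueError("amplicon_min > amplicon_max")


@dataclass
class FilterLog:
    """Per-stage survivor counts and per-variant failure reasons."""

    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    failures: dict[tuple[str, int, str, str], str] = field(default_factory=dict)

    def record_stage(self, stage: str, survivors: int) -> None:
        self.stage_counts.append((stage, survivors))
        logger.info("selection stage %s: %d survivors", stage, survivors)

    def record_failure(self, key: tuple, reason: str) -> None:
        self.failures.setdefault(key, reason)


def filter_candidates(
    variants: Sequence[InDelVariant],
    panel: Sequence[str],
    cfg: SelectionConfig = SelectionConfig(),
    log: FilterLog | None = None,
) -> list[InDelVariant]:
    """Apply the VCF-level selection chain: length -> zygosity -> polymorphism.

    The stages are logged in this fixed order but the outcome is a pure
    conjunction of predicates. A variant survives iff:

    * it is a biallelic InDel with ``min_abs_len <= |length| <= max_abs_len``;
    * no panel accession is heterozygous at the site (if
      ``require_homozygous_panel``);
    * at least one panel accession is HOM_ALT and at least one is HOM_REF
      (if ``require_polymorphic``).
    """
    if not panel:
        raise ValueError("panel of accessions must be nonempty")
    if log is None:
        log = FilterLog()
    log.record_stage("input", len(variants))

    stage1 = []
    for v in variants:
        if not v.is_indel():
            log.record_failure(v.key, "not_an_indel")
            continue
        alen = abs(indel_length(v))
        if not (cfg.min_abs_len <= alen <= cfg.max_abs_len):
            log.record_failure(v.key, f"length_{alen}bp_outside_window")
            continue
        stage1.append(v)
    log.record_stage("length", len(stage1))

    stage2 = []
    for v in stage1:
        if cfg.require_homozygous_panel and any(
            v.genotypes.get(a) is Zygosity.HET for a in panel
        ):
            log.record_failure(v.key, "heterozygous_in_panel")
            continue
        stage2.append(v)
    log.record_stage("zygosity", len(stage2))

    stage3 = []
    for v in stage2:
        if cfg.require_polymorphic:
            calls = [v.genotypes.get(a, Zygosity.MISSING) for a in panel]
            if not (
                any(c is Zygosity.HOM_ALT for c in calls)
                and any(c is Zygosity.HOM_REF for c in calls)
            ):
                log.record_failure(v.key, "monomorphic_in_panel")
                continue
        stage3.append(v)
    log.record_stage("polymorphism", len(stage3))
    return stage3


def _match_positions(template: bytes, probe: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, mismatch_count) where probe aligns to the plus strand.

    With mismatches allowed, the probe's final base (index -1 of the byte
    string handed in) must match exactly.
    """
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    t = np.frombuffer(template, dtype=np.uint8)
    n, m = len(t), len(p)
    if m > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mm = (windows != p).sum(axis=1)
    hits = np.nonzero(mm <= max_mismatch)[0]
    return [(int(i), int(mm[i])) for i in hits]


def epcr(
    primers: PrimerPair,
    template: str,
    max_mismatch: int = 0,
    template_id: str = "",
) -> list[AmpliconPrediction]:
    """Predict PCR products of a primer pair on a plus-strand template.

    The forward primer must match the plus strand and the reverse
    complement of the reverse primer must match downstream, each with at
    most ``max_mismatch`` Hamming mismatches; when mismatches are allowed
    the 3'-terminal base of each primer must still match exactly. The
    product spans from the forward primer's 5' end to the reverse primer's
    5' end inclusive. Predictions are sorted by (start, end).
    """
    if not template:
        raise ValueError("template is empty")
    template = template.upper()
    tb = template.encode()
    fwd = primers.forward_seq
    rc_rev = revcomp(primers.reverse_seq)
    f_hits = _match_positions(tb, fwd, max_mismatch)
    r_hits = _match_positions(tb, rc_rev, max_mismatch)
    if max_mismatch > 0:
        # 3' anchor: forward primer's last base; reverse primer's 3' base is
        # the FIRST base of its reverse complement on the plus strand.
        f_hits = [(i, m) for i, m in f_hits if template[i + len(fwd) - 1] == fwd[-1]]
        r_hits = [(j, m) for j, m in r_hits if template[j] == rc_rev[0]]
    preds = []
    for i, fm in f_hits:
        for j, rm in r_hits:
            if j >= i + len(fwd):
                preds.append(
                    AmpliconPrediction(
                        template_id=template_id,
                        start=i,
                        end=j + len(rc_rev),
                        forward_mismatches=fm,
                        reverse_mismatches=rm,
                    )
                )
    preds.sort(key=lambda a: (a.start, a.end))
    return preds


def predict_allele_amplicons(
    locus: MarkerLocus,
    ref_genome: Mapping[str, str],
    max_mismatch: int = 0,
    max_products: int = 1,
) -> tuple[int, int]:
    """Predicted (reference, alternative) amplicon sizes for one marker.

    The reference size comes from e-PCR on the reference sequence; the
    alternative size from e-PCR on the reference sequence with the
    alternative allele substituted at the site. The two sizes always differ
    by exactly ``|indel_length|``. Raises :class:`MarkerSelectionError` if
    either haplotype yields zero or more than ``max_products`` amplicons, or
    if the InDel does not lie inside the reference amplicon (which would
    break the co-dominant design).
    """
    try:
        template = ref_genome[locus.chrom]
    except KeyError:
        raise MarkerSelectionError(
            f"{locus.marker_id}: template {locus.chrom!r} not in reference"
        ) from None
    preds = epcr(locus.primer_pair, template, max_mismatch, template_id=locus.chrom)
    if len(preds) == 0:
        raise MarkerSelectionError(f"{locus.marker_id}: no reference amplicon")
    if len(preds) > max_products:
        raise MarkerSelectionError(
            f"{locus.marker_id}: {len(preds)} reference amplicons (max {max_products})"
        )
    amp = preds[0]
    site_start = locus.pos - 1  # 0-based
    site_end = site_start + len(locus.ref_allele)
    if not (amp.start <= site_start and site_end <= amp.end):
        raise MarkerSelectionError(
            f"{locus.marker_id}: InDel at {locus.chrom}:{locus.pos} lies outside "
            f"the reference amplicon [{amp.start}, {amp.end})"
        )
    alt_template = (
        template[:site_start] + locus.alt_allele + template[site_end:]
    )
    alt_preds = epcr(locus.primer_pair, alt_template, max_mismatch, template_id=locus.chrom)
    if len(alt_preds) == 0:
        raise MarkerSelectionError(f"{locus.marker_id}: no alternative-allele amplicon")
    if len(alt_preds) > max_products:
        raise MarkerSelectionError(
            f"{locus.marker_id}: {len(alt_preds)} alternative amplicons (max {max_products})"
        )
    ref_bp, alt_bp = amp.length, alt_preds[0].length
    assert abs(ref_bp - alt_bp) == abs(locus.indel_length)
    return ref_bp, alt_bp


def amplicon_size_filter(
    loci: Iterable[MarkerLocus],
    cfg: SelectionConfig = SelectionConfig(),
    log: FilterLog | None = None,
) -> list[MarkerLocus]:
    """Keep loci whose reference AND alternative amplicons are in-window."""
    kept = []
    loci = list(loci)
    for l in loci:
        if l.ref_amplicon_bp is None or l.alt_amplicon_bp is None:
            raise ValueError(f"{l.marker_id}: amplicon sizes not populated")
        if (
            cfg.amplicon_min <= l.ref_amplicon_bp <= cfg.amplicon_max
            and cfg.amplicon_min <= l.alt_amplicon_bp <= cfg.amplicon_max
        ):
            kept.append(l)
        elif log is not None:
            log.record_failure(
                (l.chrom, l.pos, l.ref_allele, l.alt_allele),
                f"amplicon_{l.ref_amplicon_bp}/{l.alt_amplicon_bp}bp_outside_window",
            )
    if log is not None:
        log.record_stage("amplicon_size", len(kept))
    return kept


def build_marker_loci(
    variants: Sequence[InDelVariant],
    primer_table: pd.DataFrame,
    ref_genome: Mapping[str, str],
    cfg: SelectionConfig = SelectionConfig(),
    log: FilterLog | None = None,
) -> list[MarkerLocus]:
    """Attach primers to surviving variants and predict allele amplicons.

    Variants without a primer-table entry (matched on chrom+pos) are
    dropped with a logged reason; loci violating the single-product rule
    are dropped likewise rather than aborting the whole panel.
    """
    by_site = {
        (str(r["chrom"]), int(r["pos"])): r for _, r in primer_table.iterrows()
    }
    loci = []
    for v in variants:
        row = by_site.get((v.chrom, v.pos))
        if row is None:
            if log is not None:
                log.record_failure(v.key, "no_primer_pair")
            continue
        pair = PrimerPair(
            marker_id=str(row["marker_id"]),
            forward_seq=str(row["forward"]),
            reverse_seq=str(row["reverse"]),
        )
        locus = MarkerLocus(
            marker_id=pair.marker_id,
            chrom=v.chrom,
            pos=v.pos,
            ref_allele=v.ref_allele,
            alt_allele=v.alt_allele,
            indel_length=indel_length(v),
            primer_pair=pair,
        )
        try:
            ref_bp, alt_bp = predict_allele_amplicons(
                locus, ref_genome, cfg.max_primer_mismatch, cfg.max_products
            )
        except MarkerSelectionError as exc:
            if log is not None:
                log.record_failure(v.key, f"epcr_failed:{exc}")
            continue
        loci.append(replace(locus, ref_amplicon_bp=ref_bp, alt_amplicon_bp=alt_bp))
    if log is not None:
        log.record_stage("epcr", len(loci))
    return loci


def read_primer_table(path: str | Path) -> pd.DataFrame:
    """Read a primer TSV with columns marker_id, forward, reverse, chrom, pos."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    required = {"marker_id", "forward", "reverse", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: primer table missing column(s) {sorted(missing)}")
    return df


def write_panel_table(loci: Sequence[MarkerLocus], path: str | Path) -> Path:
    """Write the selected-panel TSV (one row per marker)."""
    rows = [
        {
            "marker_id": l.marker_id,
            "chrom": l.chrom,
            "pos": l.pos,
            "ref_allele": l.ref_allele,
            "alt_allele": l.alt_allele,
            "indel_length_bp": l.indel_length,
            "forward_primer": l.primer_pair.forward_seq,
            "reverse_primer": l.primer_pair.reverse_seq,
            "ref_amplicon_bp": l.ref_amplicon_bp,
            "alt_amplicon_bp": l.alt_amplicon_bp,
            "annotation_class": l.annotation_class,
        }
        for l in loci
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
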