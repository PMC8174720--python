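"""Per-locus informativeness statistics and panel-level discrimination power.

Frequencies here are *pattern* frequencies: each accession contributes one
banding pattern (its call symbol) per marker, so a biallelic locus typed in
73 accessions with 41 reference-like patterns has major frequency
41/73 = 0.5616. Two PIC variants are computed:

* ``pic_simple``:  PIC = 1 - sum_j p_j^2   (expected heterozygosity form)
* ``pic_botstein``: PIC = 1 - sum_j p_j^2 - sum_j sum_{k>j} 2 p_j^2 p_k^2
  (Botstein et al. 1980), the form that marker-panel reports in crop
  fingerprinting conventionally print.

For a biallelic locus with major frequency p in (0.5, 1], the Botstein PIC
is strictly decreasing in p, so a panel's PIC range endpoints are attained
at the loci with the extreme major-pattern frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codec import GenotypeMatrix, GenotypeProfile, homology_counts

__all__ = [
    "LocusStats",
    "PanelStats",
    "pattern_frequencies",
    "pic_simple",
    "pic_botstein",
    "locus_stats",
    "panel_summary",
    "discrimination_power",
    "locus_stats_table",
]


@dataclass
class LocusStats:
    """Pattern counts, frequencies and PIC for one marker."""

    marker_id: str
    pattern_counts: dict[str, int]
    pattern_freqs: np.ndarray
    major_allele_freq: float
    pic_simple: float
    pic_botstein: float
    missing_count: int


@dataclass
class PanelStats:
    """Panel-level summary over all loci and accession pairs."""

    loci: list[LocusStats]
    pic_variant: str
    mean_pic: float
    pic_range: tuple[float, float]
    unique_profile_count: int
    resolved_pair_fraction: float
    unresolved_pairs: list[tuple[str, str]]
    mean_pairwise_difference: float
    reference_differences: pd.Series | None = None

    def to_dict(self) -> dict:
        d = {
            "pic_variant": self.pic_variant,
            "mean_pic": self.mean_pic,
            "pic_range": list(self.pic_range),
            "unique_profile_count": self.unique_profile_count,
            "resolved_pair_fraction": self.resolved_pair_fraction,
            "unresolved_pairs": [list(p) for p in self.unresolved_pairs],
            "mean_pairwise_difference": self.mean_pairwise_difference,
        }
        if self.reference_differences is not None:
            d["reference_differences"] = self.reference_differences.to_dict()
        return d


def _validate_freqs(freqs: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(freqs), dtype=float)
    if (p < 0).any():
        raise ValueError("negative pattern frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def pattern_frequencies(m: GenotypeMatrix, marker_id: str) -> pd.Series:
    """Pattern frequencies at one marker, sorted descending.

    Missing calls ('-') are excluded from the denominator. Raises if the
    marker is absent or every call is missing.
    """
    if marker_id not in m.marker_ids:
        raise KeyError(f"marker {marker_id!r} not in panel")
    col = m.marker_ids.index(marker_id)
    calls = [p.calls[col] for p in m.profiles]
    counts = pd.Series([c for c in calls if c != "-"], dtype=object).value_counts()
    if counts.empty:
        raise ValueError(f"marker {marker_id!r}: all calls missing")
    freqs = counts / counts.sum()
    # deterministic order: frequency descending, then symbol
    freqs = freqs.sort_index().sort_values(ascending=False, kind="stable")
    freqs.name = marker_id
    return freqs


def pic_simple(freqs: Sequence[float]) -> float:
    """PIC = 1 - sum p_j^2 (the expected-heterozygosity form)."""
    p = _validate_freqs(freqs)
    return float(1.0 - np.sum(p**2))


def pic_botstein(freqs: Sequence[float]) -> float:
    """PIC = 1 - sum p_j^2 - sum_{j<k} 2 p_j^2 p_k^2 (Botstein et al.)."""
    p = _validate_freqs(freqs)
    p2 = p**2
    cross = np.sum(np.outer(p2, p2)) - np.sum(p2**2)  # sum over j != k
    return float(1.0 - p2.sum() - cross)


def locus_stats(m: GenotypeMatrix, marker_id: str) -> LocusStats:
    """All per-locus statistics for one marker."""
    freqs = pattern_frequencies(m, marker_id)
    col = m.marker_ids.index(marker_id)
    missing = sum(1 for p in m.profiles if p.calls[col] == "-")
    counts_all = pd.Series(
        [p.calls[col] for p in m.profiles if p.calls[col] != "-"], dtype=object
    ).value_counts()
    vec = freqs.to_numpy()
    return LocusStats(
        marker_id=marker_id,
        pattern_counts={str(k): int(v) for k, v in counts_all.items()},
        pattern_freqs=vec,
        major_allele_freq=float(vec[0]),
        pic_simple=pic_simple(vec),
        pic_botstein=pic_botstein(vec),
        missing_count=missing,
    )


def discrimination_power(
    m: GenotypeMatrix,
) -> tuple[int, float, list[tuple[str, str]]]:
    """(unique profile count, resolved pair fraction, unresolved pairs).

    A pair of accessions is resolved if their profiles differ at >= 1
    marker where both calls are non-missing.
    """
    if not m.profiles:
        raise ValueError("empty genotype matrix")
    unique = len({p.calls for p in m.profiles})
    unresolved = []
    pairs = list(combinations(m.profiles, 2))
    for p1, p2 in pairs:
        if p1.differences(p2) == 0:
            unresolved.append((p1.accession_id, p2.accession_id))
    resolved = 1.0 if not pairs else 1.0 - len(unresolved) / len(pairs)
    return unique, resolved, unresolved


def panel_summary(
    m: GenotypeMatrix,
    pic_variant: str = "botstein",
    missing_policy: str = "exclude",
) -> PanelStats:
    """Panel summary: mean/range PIC, discrimination, pairwise differences.

    ``mean_pairwise_difference`` is the mean count of mismatching markers
    over all unordered accession pairs (markers with a missing call in
    either profile are not counted). The per-accession difference from the
    reference variety (an all-'a' profile) is reported alongside, since
    "average difference" is ambiguous between the two readings.
    """
    if pic_variant not in ("simple", "botstein"):
        raise ValueError(f"unknown PIC variant {pic_variant!r}")
    per_locus = [locus_stats(m, mid) for mid in m.marker_ids]
    pics = [
        l.pic_botstein if pic_variant == "botstein" else l.pic_simple
        for l in per_locus
    ]
    pairs = list(combinations(m.profiles, 2))
    if pairs:
        diffs = [p1.differences(p2) for p1, p2 in pairs]
        mean_diff = float(np.mean(diffs))
    else:
        mean_diff = 0.0
    ref_profile = GenotypeProfile("__reference__", tuple("a" * len(m.marker_ids)))
    ref_diffs = pd.Series(
        {p.accession_id: p.differences(ref_profile) for p in m.profiles},
        name="differences_from_reference",
    )
    unique, resolved, unresolved = discrimination_power(m)
    return PanelStats(
        loci=per_locus,
        pic_variant=pic_variant,
        mean_pic=float(np.mean(pics)),
        pic_range=(float(np.min(pics)), float(np.max(pics))),
        unique_profile_count=unique,
        resolved_pair_fraction=resolved,
        unresolved_pairs=unresolved,
        mean_pairwise_difference=mean_diff,
        reference_differences=ref_diffs,
    )


def locus_stats_table(m: GenotypeMatrix, decimals: int = 4) -> pd.DataFrame:
    """Per-marker statistics table (marker, major pattern frequency, PIC).

    Values are rounded to ``decimals`` for the table; use
    :func:`locus_stats` for full precision.
    """
    rows = []
    for mid in m.marker_ids:
        ls = locus_stats(m, mid)
        rows.append(
            {
                "marker_id": ls.marker_id,
                "n_typed": int(sum(ls.pattern_counts.values())),
                "n_missing": ls.missing_count,
                "major_pattern_freq": round(ls.major_allele_freq, decimals),
                "pic_botstein": round(ls.pic_botstein, decimals),
                "pic_simple": round(ls.pic_simple, decimals),
            }
        )
    return pd.DataFrame(rows)
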