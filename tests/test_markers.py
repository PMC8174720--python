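"""Selection funnel, e-PCR binding-site model, amplicon prediction."""

import numpy as np
import pytest

from indelbarcode import (
    FilterLog,
    InDelVariant,
    MarkerLocus,
    MarkerSelectionError,
    PrimerPair,
    SelectionConfig,
    SyntheticPanelConfig,
    Zygosity,
    amplicon_size_filter,
    epcr,
    filter_candidates,
    generate_panel,
    predict_allele_amplicons,
    revcomp,
)

PANEL = ["s1", "s2", "s3"]


def variant(pos, delta, zygosities):
    ref = "A" * (1 + max(0, -delta))
    alt = "A" * (1 + max(0, delta)) if delta >= 0 else ref[0]
    if delta > 0:
        alt = "A" + "T" * delta
    gts = dict(zip(PANEL, zygosities))
    return InDelVariant("chr1", pos, ref, alt, gts)


HOM_REF, HET, HOM_ALT = Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT


class TestFilterCandidates:
    def toy_variants(self):
        return [
            variant(10, 3, [HOM_REF, HOM_ALT, HOM_ALT]),   # too short
            variant(20, 12, [HOM_ALT, HOM_ALT, HOM_ALT]),  # monomorphic
            variant(30, -11, [HOM_REF, HOM_ALT, HOM_REF]), # keeper
            variant(40, 15, [HOM_REF, HET, HOM_ALT]),      # heterozygous
            variant(50, 25, [HOM_REF, HOM_ALT, HOM_REF]),  # too long
            variant(60, -10, [HOM_ALT, HOM_REF, HOM_ALT]), # keeper
        ]

    def test_toy_chain(self):
        log = FilterLog()
        survivors = filter_candidates(self.toy_variants(), PANEL, log=log)
        assert [v.pos for v in survivors] == [30, 60]
        assert log.stage_counts == [
            ("input", 6),
            ("length", 4),
            ("zygosity", 3),
            ("polymorphism", 2),
        ]
        reasons = {k[1]: r for k, r in log.failures.items()}
        assert "length" in reasons[10] and "length" in reasons[50]
        assert reasons[40] == "heterozygous_in_panel"
        assert reasons[20] == "monomorphic_in_panel"

    def test_empty_input(self):
        assert filter_candidates([], PANEL) == []

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            filter_candidates([], [])

    def test_order_insensitive_conjunction(self, rng):
        """Survivors equal an unordered brute-force conjunction of the three
        predicates, regardless of input ordering."""
        variants = self.toy_variants()
        cfg = SelectionConfig()

        def oracle(v):
            from indelbarcode import indel_length

            calls = [v.genotypes[a] for a in PANEL]
            return (
                cfg.min_abs_len <= abs(indel_length(v)) <= cfg.max_abs_len
                and not any(c is HET for c in calls)
                and any(c is HOM_ALT for c in calls)
                and any(c is HOM_REF for c in calls)
            )

        expected = {v.key for v in variants if oracle(v)}
        for _ in range(5):
            shuffled = list(variants)
            rng.shuffle(shuffled)
            got = {v.key for v in filter_candidates(shuffled, PANEL, cfg)}
            assert got == expected


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_epcr(fwd, rev, template, max_mismatch):
    """Independent oracle: scan every (i, j) position pair directly."""
    rc = revcomp(rev)
    hits = []

    def sites(probe, anchor_last):
        out = []
        for i in range(len(template) - len(probe) + 1):
            window = template[i : i + len(probe)]
            mm = sum(a != b for a, b in zip(window, probe))
            if mm > max_mismatch:
                continue
            if max_mismatch > 0:
                if anchor_last and window[-1] != probe[-1]:
                    continue
                if not anchor_last and window[0] != probe[0]:
                    continue
            out.append((i, mm))
        return out

    for i, fm in sites(fwd, anchor_last=True):
        for j, rm in sites(rc, anchor_last=False):
            if j >= i + len(fwd):
                hits.append((i, j + len(rc), fm, rm))
    return sorted(hits)


class TestEpcr:
    def test_constructed_template(self, rng):
        fwd = random_seq(rng, 10)
        rev_site = random_seq(rng, 10)
        template = "GGGGG" + fwd + random_seq(rng, 25) + rev_site + "GGGGG"
        pair = PrimerPair("m", fwd, revcomp(rev_site), min_length=10)
        preds = epcr(pair, template, 0)
        assert len(preds) == 1
        assert preds[0].length == 45
        assert preds[0].start == 5

    def test_absent_primers_empty(self, rng):
        pair = PrimerPair("m", "A" * 18, "C" * 18)
        assert epcr(pair, random_seq(rng, 100) + "G", 0) == []

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_matches_brute_force_oracle(self, max_mismatch):
        """Predictions equal the all-position scan on random templates with
        half-planted primer sites."""
        rng = np.random.default_rng(100 + max_mismatch)
        for _ in range(60):
            fwd = random_seq(rng, 16)
            rev_site = random_seq(rng, 16)
            parts = [random_seq(rng, 40)]
            for _ in range(rng.integers(0, 3)):
                parts += [fwd, random_seq(rng, int(rng.integers(20, 60)))]
            for _ in range(rng.integers(0, 3)):
                parts += [rev_site, random_seq(rng, int(rng.integers(10, 40)))]
            template = "".join(parts)
            pair = PrimerPair("m", fwd, revcomp(rev_site))
            got = [
                (p.start, p.end, p.forward_mismatches, p.reverse_mismatches)
                for p in epcr(pair, template, max_mismatch)
            ]
            assert got == brute_force_epcr(
                fwd, revcomp(rev_site), template, max_mismatch
            )

    def test_mismatch_monotonicity(self, rng):
        """Raising the mismatch budget never loses predictions."""
        for _ in range(20):
            fwd = random_seq(rng, 15)
            rev_site = random_seq(rng, 15)
            template = (
                random_seq(rng, 30) + fwd + random_seq(rng, 50) + rev_site + random_seq(rng, 30)
            )
            pair = PrimerPair("m", fwd, revcomp(rev_site))
            counts = [len(epcr(pair, template, mm)) for mm in (0, 1, 2, 3)]
            assert counts == sorted(counts)

    def test_single_mismatch_tolerated_but_not_at_3prime_end(self, rng):
        fwd = random_seq(rng, 16)
        rev_site = random_seq(rng, 16)

        def mutate(s, i):
            return s[:i] + ("A" if s[i] != "A" else "C") + s[i + 1 :]

        spacer = random_seq(rng, 50)
        pair = PrimerPair("m", fwd, revcomp(rev_site))
        # internal mismatch in the forward site: found at budget 1, not 0
        t1 = random_seq(rng, 20) + mutate(fwd, 7) + spacer + rev_site
        assert epcr(pair, t1, 0) == []
        assert len(epcr(pair, t1, 1)) == 1
        # mismatch at the forward primer's 3'-terminal base: never tolerated
        t2 = random_seq(rng, 20) + mutate(fwd, 15) + spacer + rev_site
        assert epcr(pair, t2, 1) == []
        # mismatch at the reverse primer's 3' base (first base of the
        # plus-strand site): never tolerated
        t3 = random_seq(rng, 20) + fwd + spacer + mutate(rev_site, 0)
        assert epcr(pair, t3, 1) == []

    def test_zero_mismatch_equals_substring_search(self, rng):
        fwd = random_seq(rng, 15)
        rev_site = random_seq(rng, 15)
        template = random_seq(rng, 20) + fwd + random_seq(rng, 40) + rev_site
        pair = PrimerPair("m", fwd, revcomp(rev_site))
        preds = epcr(pair, template, 0)
        assert [p.start for p in preds] == [template.find(fwd)]


def build_locus(rng, delta, amp_ref_bp, marker_id="TBX"):
    """Plant one primer-flanked InDel site; return (locus, genome)."""
    plen = 20
    fwd = random_seq(rng, plen)
    rev_site = random_seq(rng, plen)
    ref_len = 1 + (-delta if delta < 0 else 0)
    inner = amp_ref_bp - 2 * plen
    left = (inner - ref_len) // 2
    right = inner - ref_len - left
    ref_allele = random_seq(rng, ref_len)
    alt_allele = ref_allele + random_seq(rng, delta) if delta > 0 else ref_allele[0]
    frag = (
        random_seq(rng, 30)
        + fwd
        + random_seq(rng, left)
        + ref_allele
        + random_seq(rng, right)
        + rev_site
        + random_seq(rng, 30)
    )
    pos = 30 + plen + left + 1
    locus = MarkerLocus(
        marker_id=marker_id,
        chrom="t",
        pos=pos,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        indel_length=delta,
        primer_pair=PrimerPair(marker_id, fwd, revcomp(rev_site)),
    )
    return locus, {"t": frag}


class TestPredictAlleleAmplicons:
    def test_deletion_sizes(self, rng):
        locus, genome = build_locus(rng, -11, 180)
        assert predict_allele_amplicons(locus, genome) == (180, 169)

    def test_insertion_sizes(self, rng):
        locus, genome = build_locus(rng, 10, 170)
        assert predict_allele_amplicons(locus, genome) == (170, 180)

    def test_size_difference_conservation(self, rng):
        for delta in (-20, -15, -10, 10, 15, 20):
            locus, genome = build_locus(rng, delta, 200)
            ref_bp, alt_bp = predict_allele_amplicons(locus, genome)
            assert abs(ref_bp - alt_bp) == abs(delta)

    def test_indel_outside_amplicon_errors(self, rng):
        locus, genome = build_locus(rng, -11, 180)
        # move the recorded site outside the amplified span
        locus.pos = 5
        locus.ref_allele = genome["t"][4:16]
        locus.alt_allele = genome["t"][4]
        with pytest.raises(MarkerSelectionError, match="outside"):
            predict_allele_amplicons(locus, genome)

    def test_no_amplicon_errors(self, rng):
        locus, genome = build_locus(rng, -11, 180)
        with pytest.raises(MarkerSelectionError, match=locus.marker_id):
            predict_allele_amplicons(locus, {"t": random_seq(rng, 300)})


class TestAmpliconSizeFilter:
    @staticmethod
    def locus_with_sizes(rng, ref_bp, alt_bp, marker_id):
        locus, _ = build_locus(rng, alt_bp - ref_bp, ref_bp, marker_id)
        locus.ref_amplicon_bp = ref_bp
        locus.alt_amplicon_bp = alt_bp
        return locus

    def test_window_boundaries(self, rng):
        keep = self.locus_with_sizes(rng, 150, 161, "in")
        low = self.locus_with_sizes(rng, 145, 156, "low")
        high = self.locus_with_sizes(rng, 225, 236, "high")
        kept = amplicon_size_filter([keep, low, high])
        assert [l.marker_id for l in kept] == ["in"]

    def test_empty_input(self):
        assert amplicon_size_filter([]) == []

    def test_matches_exhaustive_check(self, small_panel, default_cfg):
        """Survivors on a generated panel equal the exhaustively enumerated
        in-window set."""
        from indelbarcode import build_marker_loci, filter_candidates

        surv = filter_candidates(small_panel.variants, small_panel.accessions)
        loci = build_marker_loci(
            surv, small_panel.primer_table, small_panel.reference
        )
        kept = amplicon_size_filter(loci, default_cfg)
        expected = {
            l.marker_id
            for l in loci
            if default_cfg.amplicon_min <= l.ref_amplicon_bp <= default_cfg.amplicon_max
            and default_cfg.amplicon_min <= l.alt_amplicon_bp <= default_cfg.amplicon_max
        }
        assert {l.marker_id for l in kept} == expected
        assert expected == set(small_panel.truth.planted_ids())


class TestPrimerPair:
    def test_rejects_non_dna(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            PrimerPair("m", "ACGTACGTACGTACGN", "ACGTACGTACGTACGT")

    def test_rejects_short_primer(self):
        with pytest.raises(ValueError, match="shorter"):
            PrimerPair("m", "ACGTACGT", "ACGTACGTACGTACGT")
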