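"""Motif scanning, variant tables, co-occurrence and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_scan
from hoxtale.intervals import GenomicInterval, Peak, PeakSet
from hoxtale.motifs import (FORKHEAD_KMERS, GATA, HOX_PBX, KmerSet, MEIS,
                            MotifPattern, class_motif_enrichment,
                            count_variants, enumerate_variants, pair_distances,
                            presence_fraction, revcomp, scan,
                            select_candidate_sites, select_knockout_pairs)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _ranked_peakset(n, label="t"):
    peaks = [Peak(GenomicInterval("chr1", i * 1000, i * 1000 + 600),
                  i * 1000 + 300, float(n - i), f"{label}{i}")
             for i in range(n)]
    return PeakSet(peaks, label=label, genome_id="g")


class TestEnumerateVariants:
    def test_hox_pbx_expands_to_16(self):
        v = enumerate_variants(HOX_PBX)
        assert len(v) == 16
        assert "TGATTCAT" in v and "TGATGGAT" in v

    def test_w_code_expands_to_two(self):
        assert set(enumerate_variants(MotifPattern("g", "WGATAA"))) == {
            "AGATAA", "TGATAA"}

    def test_nn_expands_to_16_dinucleotides(self):
        assert len(enumerate_variants(MotifPattern("d", "NN"))) == 16

    def test_cardinality_is_product_of_degeneracies(self):
        assert len(enumerate_variants(MotifPattern("x", "RYN"))) == 2 * 2 * 4


class TestScan:
    def test_forward_hit(self):
        hits = scan("AATGATGGATCC", HOX_PBX)
        assert [(h.offset, h.strand, h.matched_variant) for h in hits] == [
            (2, "+", "TGATGGAT")]

    def test_reverse_hit_reports_motif_orientation(self):
        hits = scan("ATCCATCA", MotifPattern("h", "TGATGGAT"))
        assert [(h.offset, h.strand, h.matched_variant) for h in hits] == [
            (0, "-", "TGATGGAT")]

    def test_genomic_n_never_matches_fixed_positions(self):
        assert scan("NGATGGAT", HOX_PBX, "forward") == []
        # but genomic N at the free (pattern-N) positions is fine
        hits = scan("TGATNNAT", HOX_PBX, "forward")
        assert len(hits) == 1

    def test_mismatch_budget_on_fixed_positions_only(self):
        pat = MotifPattern("h", "TGATNNAT", 1)
        hits = scan("CGATGGAT", pat, "forward")  # one fixed-base mismatch
        assert hits and hits[0].mismatches == 1
        assert scan("CCATGGAT", pat, "forward") == []  # two mismatches

    def test_overlapping_hits_all_reported(self):
        hits = scan("TGACATGACA", MEIS, "forward")
        assert [h.offset for h in hits] == [0, 5]

    @pytest.mark.parametrize("mm", [0, 1])
    def test_equals_bruteforce_oracle(self, rng, mm):
        pat = MotifPattern("h", "TGATNNAT", mm)
        for _ in range(30):
            seq = _random_seq(rng, 500)
            got = [(h.offset, h.strand, h.matched_variant, h.mismatches)
                   for h in scan(seq, pat)]
            assert got == brute_scan(seq, "TGATNNAT", mm)

    def test_kmerset_scan_with_internal_wildcard(self):
        ks = KmerSet("k", ["ATNAATCAACA"])
        hits = scan("GGATGAATCAACAGG", ks, "forward")
        assert [(h.offset, h.matched_variant) for h in hits] == [
            (2, "ATGAATCAACA")]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=80))
    def test_revcomp_invariance(self, seq):
        # both-strand scanning of seq and of its reverse complement find the
        # same variants with mirrored offsets
        fwd = scan(seq, HOX_PBX)
        rev = scan(revcomp(seq), HOX_PBX)
        L = len(seq)
        mapped = sorted((L - h.end, {"+": "-", "-": "+"}[h.strand],
                         h.matched_variant) for h in rev)
        assert mapped == sorted((h.offset, h.strand, h.matched_variant)
                                for h in fwd)


class TestCountVariants:
    def test_single_planted_variant(self):
        ps = _ranked_peakset(1)
        tab = count_variants(ps, ["G" * 20 + "TGATTCAT" + "G" * 20])
        assert tab.totals["TGATTCAT"] == 1
        assert tab.totals.sum() == 1

    def test_counts_conserve_scan_totals(self, rng):
        ps = _ranked_peakset(120)
        seqs = [_random_seq(rng, 200) for _ in range(120)]
        tab = count_variants(ps, seqs, bin_size=50)
        total = sum(
            sum(1 for h in scan(s, MotifPattern("h", "TGATNNAT", 0)))
            for s in seqs)
        assert tab.totals.sum() == total
        assert list(tab.counts.columns) == ["1-50", "51-100", "101-120"]

    def test_selective_variant_absent_from_other_tissue(self, small_bundle):
        b = small_bundle
        sw = dict(zip(b.region_ids, b.summit_sequences()))
        tabs = {}
        for name in ("HOXA3_PBA_r1", "HOXA2_BA2_r1"):
            ps = b.peaksets[name].ranked()
            tabs[name] = count_variants(ps, [sw[p.name] for p in ps])
        pba, ba2 = tabs["HOXA3_PBA_r1"], tabs["HOXA2_BA2_r1"]
        n_pba, n_ba2 = len(b.peaksets["HOXA3_PBA_r1"]), len(b.peaksets["HOXA2_BA2_r1"])
        # the PBA-selective variant is present in ~20% of PBA peaks and at
        # chance level in BA2 peaks
        assert 0.10 <= pba.presence["TGATTCAT"] / n_pba <= 0.32
        assert ba2.presence["TGATTCAT"] / n_ba2 <= 0.05

    def test_sequence_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_variants(_ranked_peakset(2), ["ACGT" * 50])


class TestPresenceFraction:
    def test_all_windows_contain_site(self):
        ps = _ranked_peakset(10)
        seqs = ["A" * 50 + "TGATTCAT" + "A" * 50] * 10
        df = presence_fraction(ps, seqs, HOX_PBX, [5, 10])
        assert (df["fraction"] == 1.0).all()

    def test_fraction_equals_bruteforce_count(self, rng):
        ps = _ranked_peakset(60)
        seqs = [_random_seq(rng, 300) for _ in range(60)]
        df = presence_fraction(ps, seqs, MEIS, [20, 60])
        for _, row in df.iterrows():
            n = int(row["N"])
            expect = sum(bool(brute_scan(s, "TGACA", 0)) for s in seqs[:n]) / n
            assert row["fraction"] == pytest.approx(expect)

    def test_opposite_trends_for_perfect_and_low_affinity_sites(self, rng):
        # perfect-site probability decays with FE rank; low-affinity (exactly
        # one mismatch) sites are planted with the complementary trend. An
        # A/C-only background cannot produce chance hits within 1 mismatch.
        n = 300
        ps = _ranked_peakset(n)
        seqs = []
        for i in range(n):
            s = list(rng.choice(["A", "C"], size=200))
            p_perfect = 0.9 - 0.8 * i / n
            if rng.random() < p_perfect:
                s[50:58] = "TGATTCAT"
            elif rng.random() < 0.9:
                s[120:128] = "CGATTCAT"  # one fixed-base mismatch
            seqs.append("".join(s))
        perfect = presence_fraction(ps, seqs, HOX_PBX, [50, 300], "forward")
        lowaff = presence_fraction(
            ps, seqs, MotifPattern("h1", "TGATNNAT", 1), [50, 300], "forward",
            exact_mismatch=True)
        assert perfect["fraction"].iloc[0] > perfect["fraction"].iloc[1]
        assert lowaff["fraction"].iloc[0] < lowaff["fraction"].iloc[1]


class TestPairDistances:
    def test_gap_arithmetic(self):
        a = scan("AA" + "TGATTCAT" + "AA" + "TGACA" + "A" * 10, HOX_PBX)
        b = scan("AA" + "TGATTCAT" + "AA" + "TGACA" + "A" * 10, MEIS)
        df, _ = pair_distances(a, b)
        assert df["gap"].iloc[0] == 2

    def test_overlapping_spans_gap_zero(self):
        from hoxtale.motifs import MotifHit
        a = [MotifHit("r", 10, "+", "TGATTCAT", 0, "h", 8)]
        b = [MotifHit("r", 14, "+", "TGACA", 0, "m", 5)]
        df, _ = pair_distances(a, b)
        assert df["gap"].iloc[0] == 0

    def test_regions_without_partner_counted(self):
        from hoxtale.motifs import MotifHit
        a = [MotifHit("r1", 10, "+", "TGATTCAT", 0, "h", 8),
             MotifHit("r2", 10, "+", "TGATTCAT", 0, "h", 8)]
        b = [MotifHit("r1", 30, "+", "TGACA", 0, "m", 5)]
        df, excluded = pair_distances(a, b)
        assert len(df) == 1 and excluded == 1

    def test_matches_bruteforce_minimum(self, rng):
        from hoxtale.motifs import MotifHit
        for _ in range(20):
            a = [MotifHit("r", int(o), "+", "X" * 8, 0, "a", 8)
                 for o in rng.integers(0, 500, size=5)]
            b = [MotifHit("r", int(o), "+", "Y" * 5, 0, "b", 5)
                 for o in rng.integers(0, 500, size=7)]
            df, _ = pair_distances(a, b)
            for h, g in zip(a, df["gap"]):
                expect = min(max(0, bo - h.end, h.offset - (bo + 5))
                             for bo in (x.offset for x in b))
                assert g == expect


class TestCandidateSites:
    def test_sites_outside_halfwindow_removed(self):
        seq = "TACAAA" + "G" * 588 + "TACAAA"  # at the region edges
        from hoxtale.motifs import FORKHEAD_CONSENSUS
        sites = select_candidate_sites(["r"], [seq], FORKHEAD_CONSENSUS,
                                       summit_halfwindow=250)
        assert sites == []

    def test_forkhead_kmer_near_summit_retained(self):
        seq = "T" * 290 + "AAAATAAACA" + "T" * 300
        sites = select_candidate_sites(["r"], [seq], FORKHEAD_KMERS)
        assert len(sites) == 1 and sites[0].offset == 290

    def test_candidate_spanning_hoxpbx_core_removed(self):
        # an 11-mer k-mer whose span contains a full TGATNNAT match
        ks = KmerSet("k", ["ATGATGGATCA"])
        seq = "G" * 295 + "ATGATGGATCA" + "G" * 294
        assert select_candidate_sites(["r"], [seq], ks) == []
        assert len(select_candidate_sites(["r"], [seq], ks,
                                          exclude_internal=None)) == 1

    def test_planted_sites_recovered_exactly(self, small_bundle):
        b = small_bundle
        sites = select_candidate_sites(b.region_ids, b.sequences,
                                       FORKHEAD_KMERS, exclude_internal=None,
                                       deduplicate_overlapping=False)
        planted = {(r["region_id"], p["offset"])
                   for r in b.truth for p in r["plantings"]
                   if p["class"] == "forkhead"}
        got = {(s.region_id, s.offset) for s in sites}
        assert planted <= got  # every planting recovered (chance hits allowed)


class TestKnockoutPairs:
    def _hit(self, rid, off, length=8, pattern="h"):
        from hoxtale.motifs import MotifHit
        return MotifHit(rid, off, "+", "X" * length, 0, pattern, length)

    def test_gap_window_boundaries(self):
        hox = [self._hit("r", 100)]
        assert len(select_knockout_pairs(hox, [self._hit("r", 150, 10)])) == 1
        # abutting (gap 0) excluded under dmin=1
        assert len(select_knockout_pairs(hox, [self._hit("r", 108, 10)])) == 0
        # too far (gap > 100) excluded
        assert len(select_knockout_pairs(hox, [self._hit("r", 300, 10)])) == 0

    def test_matches_bruteforce_pair_search(self, rng):
        for _ in range(10):
            hox = [self._hit("r", int(o)) for o in rng.integers(0, 600, 6)]
            other = [self._hit("r", int(o), 10, "f")
                     for o in rng.integers(0, 600, 6)]
            pairs = select_knockout_pairs(hox, other, 1, 100)
            expect = 0
            for o in other:
                g = min(max(0, h.offset - (o.offset + 10), o.offset - (h.offset + 8))
                        for h in hox)
                expect += 1 <= g <= 100
            assert len(pairs) == expect


class TestClassEnrichment:
    def test_exclusive_pattern_strongly_enriched(self, rng):
        present = ["G" * 40 + "TACAAA" + "G" * 40 for _ in range(30)]
        absent = [_random_seq(rng, 86).replace("TACAAA", "ACGTAC")
                  for _ in range(30)]
        from hoxtale.motifs import FORKHEAD_CONSENSUS
        df = class_motif_enrichment({"up": present, "down": absent},
                                    [FORKHEAD_CONSENSUS])
        qup = df[(df["class"] == "up")]["q"].iloc[0]
        assert qup < 1e-6

    def test_planted_class_enrichment_top_ranked(self, rng):
        # 40% Forkhead in the "PBA_up" class vs ~5% background
        from hoxtale.motifs import BHLH, FORKHEAD_CONSENSUS
        up, bg = [], []
        for i in range(100):
            s = list(_random_seq(rng, 200))
            if rng.random() < 0.40:
                s[50:56] = "TACAAA"
            up.append("".join(s))
        for i in range(100):
            s = list(_random_seq(rng, 200))
            if rng.random() < 0.05:
                s[50:56] = "TACAAA"
            bg.append("".join(s))
        df = class_motif_enrichment({"PBA_up": up, "other": bg},
                                    [FORKHEAD_CONSENSUS, BHLH, MEIS])
        best = df[df["class"] == "PBA_up"].sort_values("p").iloc[0]
        assert best["pattern"] == "Forkhead" and best["q"] < 0.01

    def test_permuted_labels_give_uniform_p(self, rng):
        from scipy import stats
        seqs = [_random_seq(rng, 150) for _ in range(200)]
        ps = []
        for _ in range(200):
            rng.shuffle(seqs)
            df = class_motif_enrichment(
                {"a": seqs[:100], "b": seqs[100:]}, [MEIS])
            ps.append(df["p"].iloc[0])
        # discrete hypergeometric p-values are stochastically >= uniform;
        # check no anti-conservatism at conventional thresholds
        assert (np.array(ps) < 0.05).mean() <= 0.07

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            class_motif_enrichment({"a": [], "b": ["ACGT"]}, [MEIS])
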