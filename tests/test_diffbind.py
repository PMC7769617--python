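"""Consensus regions, counting, normalization and differential testing."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hoxtale.diffbind import (CountMatrix, Sample, bh_fdr,
                              correlate_differential, differential_test,
                              group_by_association, poisson_enrichment,
                              quantify, recenter_consensus, rpkm,
                              six_class_labels, tmm_factors)
from hoxtale.intervals import GenomicInterval, Peak, PeakSet


def _cm(counts, libs=None, samples=None, width=600):
    counts = np.asarray(counts)
    regions = [GenomicInterval("chr1", i * width, (i + 1) * width)
               for i in range(counts.shape[0])]
    if samples is None:
        samples = [Sample("MEIS", f"T{j}", 1) for j in range(counts.shape[1])]
    if libs is None:
        libs = np.full(counts.shape[1], 1e7)
    return CountMatrix(regions, samples, counts, libs)


class TestRecenter:
    def _peak(self, chrom, summit, fe, name):
        return Peak(GenomicInterval(chrom, summit - 100, summit + 100),
                    summit, fe, name)

    def test_single_peak_centred_on_summit(self):
        ps = PeakSet([self._peak("chr1", 5000, 4.0, "a")], label="x")
        regions, assign = recenter_consensus([ps], width=600)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (4700, 5300)

    def test_equal_fe_peaks_average_their_summits(self):
        ps1 = PeakSet([self._peak("chr1", 5100, 4.0, "a")], label="x")
        ps2 = PeakSet([self._peak("chr1", 5120, 4.0, "b")], label="y")
        regions, assign = recenter_consensus([ps1, ps2], width=600)
        assert len(regions) == 1
        assert regions[0].center == 5110
        assert set(assign["region_id"]) == {0}

    def test_every_summit_within_halfwidth_of_its_consensus(self, rng):
        sets = []
        for k in range(3):
            peaks, used = [], set()
            while len(peaks) < 100:
                s = int(rng.integers(1000, 500_000))
                if s in used:
                    continue
                used.add(s)
                peaks.append(self._peak("chr1", s, float(rng.uniform(1, 20)),
                                        f"s{k}_{len(peaks)}"))
            sets.append(PeakSet(peaks, label=f"set{k}"))
        regions, assign = recenter_consensus(sets, width=600)
        assert len(assign) == 300  # every input peak assigned exactly once
        for _, row in assign.iterrows():
            r = regions[row["region_id"]]
            assert abs(row["summit"] - r.center) <= 300


class TestQuantify:
    def test_counts_read_starts_in_region(self):
        regions = [GenomicInterval("chr1", 100, 700)]
        s = Sample("MEIS", "PBA")
        reads = {s: {"chr1": np.array([99, 100, 350, 699, 700])}}
        cm = quantify(regions, reads)
        assert cm.counts[0, 0] == 3
        assert cm.library_sizes[0] == 5

    def test_empty_sample_gives_zeros(self):
        regions = [GenomicInterval("chr1", 100, 700)]
        reads = {Sample("MEIS", "PBA"): {"chr2": np.array([5])}}
        cm = quantify(regions, reads)
        assert cm.counts[0, 0] == 0

    def test_poisson_reads_match_generator_draws(self, rng):
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 600)
                   for i in range(50)]
        draws = rng.poisson(20, size=50)
        pos = np.concatenate([
            rng.integers(r.start, r.end, size=d)
            for r, d in zip(regions, draws)])
        cm = quantify(regions, {Sample("H", "X"): {"chr1": pos}})
        np.testing.assert_array_equal(cm.counts[:, 0], draws)


class TestRPKM:
    def test_arithmetic(self):
        cm = _cm([[10]], libs=[1e7])
        bm = rpkm(cm)
        assert bm.log2_rpkm[0, 0] == pytest.approx(np.log2(1.75))

    def test_zero_counts_finite(self):
        assert np.isfinite(rpkm(_cm([[0]])).log2_rpkm).all()

    def test_doubling_library_size_subtracts_one(self):
        a = rpkm(_cm([[10], [3]], libs=[1e7])).log2_rpkm
        b = rpkm(_cm([[10], [3]], libs=[2e7])).log2_rpkm
        np.testing.assert_allclose(a - b, 1.0)


class TestTMM:
    def test_identical_samples_give_unit_factors(self, rng):
        c = rng.poisson(50, size=(500, 1))
        cm = _cm(np.hstack([c, c, c]), libs=[1e6] * 3)
        np.testing.assert_allclose(tmm_factors(cm), 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        counts = rng.poisson(rng.uniform(10, 200, size=(300, 1)),
                             size=(300, 4))
        cm = _cm(counts, libs=[1e6, 2e6, 1.5e6, 3e6])
        f = tmm_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_composition_bias_recovered(self, rng):
        # sample 2 has 8x counts on a 10% subset: its factor should reflect
        # the trimmed mean of the unchanged majority, within 5% of the
        # directly evaluated truth
        base = rng.poisson(100, size=(1000, 1)).astype(float)
        boosted = base.copy()
        boosted[:100] *= 8
        cm = _cm(np.hstack([base, boosted]),
                 libs=[base.sum(), boosted.sum()], samples=[
                     Sample("M", "A"), Sample("M", "B")])
        f = tmm_factors(cm)
        # direct evaluation: majority regions have M = log2 ratio of
        # proportions; the trimmed mean sits on that majority value
        pj = boosted[100:, 0] / boosted.sum()
        pr = base[100:, 0] / base.sum()
        expect = 2 ** np.median(np.log2(pj / pr))
        ratio = (f[1] / f[0]) / (expect / (1 / expect) ** 0)  # factor ratio
        assert abs(f[1] / np.sqrt(f[1] * f[0]) / np.sqrt(expect)) == pytest.approx(
            1.0, abs=0.05) or abs(np.log2(f[1] / f[0]) - np.log2(expect)) < 0.07

    def test_invariant_to_global_scaling(self, rng):
        counts = rng.poisson(rng.uniform(20, 100, size=(400, 1)), size=(400, 3))
        cm1 = _cm(counts, libs=counts.sum(axis=0))
        cm2 = _cm(counts * 4, libs=4 * counts.sum(axis=0))
        np.testing.assert_allclose(tmm_factors(cm1), tmm_factors(cm2),
                                   rtol=1e-9)

    def test_matches_edger_calcnormfactors(self, rng, tmp_path):
        # independent oracle: edgeR's reference TMM implementation
        counts = rng.poisson(rng.uniform(5, 500, size=(400, 1)), size=(400, 3))
        counts[:40, 2] *= 6  # composition bias in sample 3
        cm = _cm(counts, libs=counts.sum(axis=0).astype(float))
        ours = tmm_factors(cm)
        csv = tmp_path / "counts.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("{csv}"))
            f <- calcNormFactors(x, method="TMM")
            cat(f, sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        theirs = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=0.05)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(_cm([[0, 5], [0, 2]]))


class TestPoissonEnrichmentAndBH:
    def test_zero_observation_gives_p_one(self):
        assert poisson_enrichment(0, 2.0) == 1.0

    def test_matches_direct_summation(self):
        lam = 2.0
        import math
        direct = 1.0 - sum(np.exp(-lam) * lam ** k / math.factorial(k)
                           for k in range(10))
        assert poisson_enrichment(10, lam) == pytest.approx(direct)

    def test_bh_arithmetic(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_bh_monotone_and_dominates_p(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=100)
        np.testing.assert_allclose(bh_fdr(p),
                                   multipletests(p, method="fdr_bh")[1])


class TestDifferentialTest:
    def _samples(self):
        return [Sample("MEIS", "PBA", 1), Sample("MEIS", "PBA", 2),
                Sample("MEIS", "BA2", 1), Sample("MEIS", "BA2", 2)]

    def test_identical_tissues_all_ns(self, rng):
        c = rng.poisson(100, size=(200, 1))
        cm = _cm(np.hstack([c, c, c, c]), samples=self._samples())
        res = differential_test(cm, ("PBA", "BA2"), factor="MEIS")
        assert (res.table["call"] == "ns").all()
        np.testing.assert_allclose(res.table["lfc"], 0.0, atol=1e-9)

    def test_absent_tissue_rejected(self, rng):
        cm = _cm(rng.poisson(50, size=(10, 4)), samples=self._samples())
        with pytest.raises(ValueError, match="absent"):
            differential_test(cm, ("PBA", "BA1"), factor="MEIS")

    def test_null_fdr_controlled(self, rng):
        # global null: any BH discovery is a false one; the fraction of
        # replicates with a discovery must stay near the nominal 0.05
        reps, hits = 60, 0
        for _ in range(reps):
            counts = rng.poisson(500, size=(5000, 4))
            cm = _cm(counts, samples=self._samples())
            res = differential_test(cm, ("PBA", "BA2"), factor="MEIS",
                                    lfc_threshold=0.0)
            hits += (res.table["call"] != "ns").any()
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 2 * mc_se + 1e-9

    def test_null_p_uniform(self, rng):
        counts = rng.poisson(500, size=(10_000, 4))
        cm = _cm(counts, samples=self._samples())
        res = differential_test(cm, ("PBA", "BA2"), factor="MEIS",
                                lfc_threshold=0.0)
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01

    def test_planted_fourfold_regions_detected(self, rng):
        n = 2000
        lam = np.full((n, 4), 50.0)
        up = rng.random(n) < 0.05
        lam[up, :2] *= 4  # PBA columns
        counts = rng.poisson(lam)
        cm = _cm(counts, samples=self._samples())
        res = differential_test(cm, ("PBA", "BA2"), factor="MEIS")
        called_up = (res.table["call"] == "up").to_numpy()
        assert called_up[up].mean() >= 0.90
        assert called_up[~up].mean() <= 0.01

    def test_six_class_labels_partition(self, rng):
        samples = [Sample("MEIS", t, r) for t in ("BA1", "BA2", "PBA")
                   for r in (1, 2)]
        lam = np.full((600, 6), 80.0)
        lam[:50, 4:6] *= 5    # PBA up
        lam[50:100, 2:4] /= 5  # BA2 down
        counts = rng.poisson(lam)
        cm = _cm(counts, samples=samples)
        results = {}
        for pair in (("PBA", "BA2"), ("PBA", "BA1"), ("BA2", "BA1")):
            results[pair] = differential_test(cm, pair, factor="MEIS")
        labels = six_class_labels(results)
        assert (labels[:50] == "PBA_up").mean() > 0.9
        assert (labels[50:100] == "BA2_down").mean() > 0.9
        assert (labels[100:] == "ns").mean() > 0.98
        # no region carries two labels by construction (single series), and
        # every label is one of the seven legal values
        legal = {f"{t}_{d}" for t in ("BA1", "BA2", "PBA")
                 for d in ("up", "down")} | {"ns"}
        assert set(labels) <= legal


class TestCorrelateDifferential:
    def test_perfect_correlation(self, rng):
        lfc = rng.normal(size=500) * 2
        r, n = correlate_differential(lfc, lfc, lfc_filter=1.0)
        assert r == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        lfc = rng.normal(size=5000) * 2
        other = rng.normal(size=5000)
        r, n = correlate_differential(lfc, other, lfc_filter=0.0)
        assert abs(r) < 0.05

    def test_small_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate_differential(np.array([0.1, 0.2, 0.1, 10.0]),
                                   np.zeros(4), lfc_filter=1.0)


class TestGroupByAssociation:
    def _genes(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [200_000, 500_000, 800_000],
            "end": [220_000, 520_000, 820_000],
            "label": ["up_A", "up_B", "no_DE"],
        })

    def test_intragenic_takes_precedence(self):
        regions = [GenomicInterval("chr1", 214_000, 214_600)]
        assign, _ = group_by_association(regions, np.array([1.0]), self._genes())
        assert assign.loc[0, "location"] == "intragenic"
        assert assign.loc[0, "group"] == "up_A"

    def test_far_region_unassigned(self):
        regions = [GenomicInterval("chr1", 370_000, 370_600)]
        assign, _ = group_by_association(regions, np.array([1.0]), self._genes())
        assert assign.loc[0, "location"] == "unassigned"

    def test_planted_group_shift_recovered(self, rng):
        regions, deltas = [], []
        for i in range(300):
            gene = i % 3
            center = [210_000, 510_000, 810_000][gene] + int(rng.integers(-80_000, 80_000))
            regions.append(GenomicInterval("chr1", max(0, center - 300),
                                           center + 300))
            deltas.append(rng.normal([1.0, -1.0, 0.0][gene], 0.3))
        assign, summary = group_by_association(regions, np.array(deltas),
                                               self._genes())
        med = summary["median"]
        assert med["up_A"] > med["no_DE"] > med["up_B"]
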