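"""Interval mapping: flanking probabilities, Haley-Knott scan, QTL calling."""

import numpy as np
import pandas as pd
import pytest

import binqtl as bq
from binqtl.binmap import Bin, bins_from_sim
from binqtl.mapping import build_genetic_map, cm_to_rf
from binqtl.qtl import (classify_gene_action, flanking_genotype_probs,
                        summarize_qtls)
from tests.conftest import f2_phenotype


def enumerate_flanking_probs(g_l, g_r, r_l, r_r):
    """Brute-force oracle: enumerate the two-gamete haplotype combinations."""
    probs = np.zeros(3)
    norm = 0.0
    for l1 in (0, 1):
        for q1 in (0, 1):
            for r1 in (0, 1):
                p1 = 0.5 * (r_l if l1 != q1 else 1 - r_l) \
                    * (r_r if q1 != r1 else 1 - r_r)
                for l2 in (0, 1):
                    for q2 in (0, 1):
                        for r2 in (0, 1):
                            p2 = 0.5 * (r_l if l2 != q2 else 1 - r_l) \
                                * (r_r if q2 != r2 else 1 - r_r)
                            if l1 + l2 == g_l and r1 + r2 == g_r:
                                probs[q1 + q2] += p1 * p2
                                norm += p1 * p2
    return probs / norm


class TestFlankingProbs:
    def test_locus_at_marker_copies_marker_genotype(self):
        assert flanking_genotype_probs(0, 0, 0.0, 0.1) == pytest.approx([1, 0, 0])

    def test_close_identical_flanks_pin_the_genotype(self):
        p = flanking_genotype_probs(0, 0, 0.01, 0.01)
        assert p[0] > 0.99

    def test_midpoint_between_opposite_homozygotes_is_symmetric(self):
        # AA and BB flanks 20 cM apart, locus at the midpoint
        r = cm_to_rf(10.0, "haldane")
        p = flanking_genotype_probs(0, 2, r, r)
        assert p[0] == pytest.approx(p[2])
        assert p == pytest.approx(enumerate_flanking_probs(0, 2, r, r), abs=1e-12)

    @pytest.mark.parametrize("gl,gr", [(0, 0), (0, 1), (1, 1), (2, 0), (1, 2)])
    def test_matches_enumeration_oracle(self, gl, gr):
        r_l, r_r = 0.07, 0.12
        p = flanking_genotype_probs(gl, gr, r_l, r_r)
        assert p.sum() == pytest.approx(1.0)
        assert p == pytest.approx(enumerate_flanking_probs(gl, gr, r_l, r_r),
                                  abs=1e-12)

    def test_missing_flanks_reduce_to_mendelian_prior(self):
        assert flanking_genotype_probs(-1, -1, 0.1, 0.1) == pytest.approx(
            [0.25, 0.5, 0.25])


class TestGeneAction:
    @pytest.mark.parametrize("a,d,expected", [
        (2.34, -0.74, "partial dominance"),   # |d/a| = 0.316
        (1.0, 0.0, "additive"),
        (1.0, 0.2, "additive"),               # boundary ratio 0.20 inclusive
        (1.0, 0.21, "partial dominance"),
        (1.0, 0.8, "partial dominance"),
        (1.0, 0.81, "dominant"),
        (1.0, 1.2, "dominant"),
        (1.0, 1.21, "overdominant"),
        (0.0, 1.0, "overdominant"),           # infinite ratio
    ])
    def test_rubric_boundaries(self, a, d, expected):
        assert classify_gene_action(a, d) == expected

    def test_degenerate_zero_effects_warn_additive(self):
        with pytest.warns(UserWarning):
            assert classify_gene_action(0.0, 0.0) == "additive"


class TestScan:
    def test_perfect_additive_signal_gives_full_pve(self, study_map, study_bins):
        bins = study_bins["A01"]
        target = bins[len(bins) // 2]
        y = np.where(target.genotypes == 0, 1.0,
                     np.where(target.genotypes == 2, -1.0, 0.0))
        res = bq.IntervalMapper(y, study_map, study_bins, trait="synth").fit()
        cm = study_map.chromosomes["A01"]["cm"]
        peak = res.profile.loc[res.profile["lod"].idxmax()]
        assert peak["pve"] > 99.5
        assert abs(peak["d_hat"]) < 0.05

    def test_haley_knott_equals_group_mean_contrasts_at_marker(self, study_map,
                                                               study_bins):
        bins = study_bins["A01"]
        target = bins[10]
        rng = np.random.default_rng(5)
        y = rng.normal(size=target.genotypes.shape) + 0.8 * (1 - target.genotypes)
        model = bq.IntervalMapper(y, study_map, study_bins, trait="t")
        res = model.fit(step_cm=0.5)
        pos = float(study_map.chromosomes["A01"]["cm"].iloc[10])
        row = res.profile.iloc[(res.profile["pos_cm"] - pos).abs().idxmin()]
        g = target.genotypes
        a_oracle = 0.5 * (y[g == 0].mean() - y[g == 2].mean())
        d_oracle = y[g == 1].mean() - 0.5 * (y[g == 0].mean() + y[g == 2].mean())
        assert row["a_hat"] == pytest.approx(a_oracle, abs=0.02)
        assert row["d_hat"] == pytest.approx(d_oracle, abs=0.04)

    def test_lod_invariant_to_affine_phenotype_transform(self, study_sim, study_map,
                                                         study_bins):
        y = f2_phenotype(study_sim, "PH1")
        r1 = bq.IntervalMapper(y, study_map, study_bins, trait="t").fit()
        r2 = bq.IntervalMapper(3.0 * y - 7.0, study_map, study_bins, trait="t").fit()
        assert np.allclose(r1.profile["lod"], r2.profile["lod"], atol=1e-8)

    def test_planted_qtl_recovered(self, study_sim, study_map, study_bins):
        y = f2_phenotype(study_sim, "PH1")
        res = bq.IntervalMapper(y, study_map, study_bins, trait="PH1").fit()
        top = max(res.qtls, key=lambda q: q.lod)
        # QTL planted at 5.05 Mb on a uniform 10 cM/Mb chromosome -> 50.5 cM true
        assert abs(top.peak_cm - 50.5) < 10.0
        assert top.a == pytest.approx(1.0, abs=0.3)
        assert top.d == pytest.approx(0.5, abs=0.5)
        assert top.name.startswith("qPH1-A01")

    def test_constant_phenotype_warns_flat_profile(self, study_map, study_bins):
        n = len(study_bins["A01"][0].genotypes)
        with pytest.warns(UserWarning, match="constant"):
            res = bq.IntervalMapper(np.ones(n), study_map, study_bins, trait="c").fit()
        assert res.max_lod == pytest.approx(0.0, abs=1e-6)

    def test_too_few_phenotyped_rejected(self, study_map, study_bins):
        n = len(study_bins["A01"][0].genotypes)
        y = np.full(n, np.nan)
        y[:10] = 1.0
        with pytest.raises(ValueError, match="phenotyped"):
            bq.IntervalMapper(y, study_map, study_bins)


class TestCallQtls:
    def _profile(self, lods, chrom="A01"):
        return pd.DataFrame({"chromosome": chrom,
                             "pos_cm": np.arange(len(lods), dtype=float),
                             "lod": lods, "a_hat": 1.0, "d_hat": 0.0,
                             "pve": 5.0})

    def _map_and_bins(self, n):
        g = np.zeros(40, dtype=np.int8)
        bins = [Bin(f"bin{i+1}", "A01", i * 100_000, (i + 1) * 100_000, g)
                for i in range(n)]
        df = pd.DataFrame({"bin_id": [b.id for b in bins],
                           "start": [b.start for b in bins],
                           "end": [b.end for b in bins],
                           "mid_bp": [(b.start + b.end) / 2 for b in bins],
                           "rf_prev": np.nan,
                           "cm": np.arange(n, dtype=float)})
        gmap = bq.GeneticMap(map_function="kosambi")
        gmap.chromosomes["A01"] = df
        return gmap, {"A01": bins}

    def test_subthreshold_profile_calls_nothing(self):
        gmap, bins = self._map_and_bins(50)
        lods = 2.4 * np.exp(-0.5 * ((np.arange(50) - 25.0) / 5) ** 2)
        assert bq.call_qtls(self._profile(lods), "t", gmap, bins) == []

    def test_single_peak_naming(self):
        gmap, bins = self._map_and_bins(50)
        lods = 4.0 * np.exp(-0.5 * ((np.arange(50) - 25.0) / 3) ** 2)
        out = bq.call_qtls(self._profile(lods), "CNH", gmap, bins)
        assert [q.name for q in out] == ["qCNH-A01"]

    def test_two_separated_peaks_get_suffixes(self):
        gmap, bins = self._map_and_bins(80)
        x = np.arange(80)
        lods = 4.0 * np.exp(-0.5 * ((x - 15.0) / 3) ** 2) \
            + 5.0 * np.exp(-0.5 * ((x - 60.0) / 3) ** 2)
        out = bq.call_qtls(self._profile(lods), "STLH", gmap, bins)
        assert [q.name for q in out] == ["qSTLH-A01-1", "qSTLH-A01-2"]

    def test_nearby_shoulder_without_valley_suppressed(self):
        gmap, bins = self._map_and_bins(40)
        x = np.arange(40)
        main = 8.0 * np.exp(-0.5 * ((x - 20.0) / 4) ** 2)
        shoulder = np.where(x == 26, main[26] + 0.1, 0.0)
        out = bq.call_qtls(self._profile(np.maximum(main, shoulder)), "t", gmap, bins)
        assert len(out) == 1

    def test_support_interval_brackets_peak(self):
        gmap, bins = self._map_and_bins(60)
        lods = 6.0 * np.exp(-0.5 * ((np.arange(60) - 30.0) / 4) ** 2)
        q = bq.call_qtls(self._profile(lods), "t", gmap, bins)[0]
        assert q.ci_left_cm < q.peak_cm < q.ci_right_cm
        assert q.start_bp < q.end_bp
        assert q.left_bin == f"bin{int(q.ci_left_cm) + 1}"


class TestSummaries:
    def test_published_qtl_table_reproduces_printed_counts(self):
        s = summarize_qtls(bq.reference.qtl_table())
        assert s["n_qtls"] == 112
        assert s["n_a_subgenome"] == 41
        assert s["n_d_subgenome"] == 71
        assert s["interval_mb"]["max"] == pytest.approx(8.45, abs=0.005)
        assert s["pve_pct"]["max"] == pytest.approx(24.89, abs=1e-9)
        assert max(s["per_trait"].values()) == 10

    def test_empty_table_is_all_zero(self):
        s = summarize_qtls(pd.DataFrame())
        assert s["n_qtls"] == 0 and s["per_trait"] == {}

    def test_single_interval_size(self):
        df = pd.DataFrame({"trait": ["TCi"], "chromosome": ["A11"],
                           "start_bp": [807_428], "end_bp": [9_258_460],
                           "pve_pct": [12.52]})
        s = summarize_qtls(df)
        assert s["interval_mb"]["max"] == pytest.approx(8.451, abs=1e-3)


class TestPermutationNull:
    def test_permuted_phenotypes_rarely_exceed_threshold(self, study_sim, study_map,
                                                         study_bins):
        y = f2_phenotype(study_sim, "PH1")
        rng = np.random.default_rng(17)
        model = bq.IntervalMapper(rng.permutation(y), study_map, study_bins,
                                  trait="perm")
        # a single permuted scan on one chromosome: genome-wide nulls are
        # exercised at scale in the acceptance suite
        res = model.fit(step_cm=2.0)
        assert res.max_lod < 5.0
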