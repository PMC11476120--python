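"""SNP/individual QC, PCA covariates, association scans and annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirfa.genparams import build_G
from mirfa.gwas import (QCConfig, annotate_snps, bonferroni_threshold,
                        farmcpu_scan, glm_scan, hwe_chi2_p, mlm_scan,
                        pca_covariates, snp_qc)
from mirfa.simdata import (GenotypeMatrix, SimConfig, simulate_genotypes,
                           simulate_pedigree)


def geno_from_dosage(dosage, chrom=None, pos=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    return GenotypeMatrix(np.arange(1, n + 1),
                          np.array([f"s{j}" for j in range(m)]),
                          np.array(["1"] * m) if chrom is None else chrom,
                          np.arange(1, m + 1) * 1000 if pos is None else pos,
                          dosage)


def founder_genotypes(n, m, seed):
    cfg = SimConfig(n_founders=n, n_generations=0, matings_per_generation=0,
                    n_snps=m, seed=seed)
    return simulate_genotypes(simulate_pedigree(cfg), cfg)


class TestSnpQc:
    def test_low_call_rate_snp_removed(self, rng):
        d = rng.binomial(2, 0.4, (100, 5)).astype(float)
        d[:3, 0] = np.nan  # 97% call rate
        g, report = snp_qc(geno_from_dosage(d))
        assert "s0" not in g.snp_ids

    def test_low_call_rate_individual_removed(self, rng):
        d = rng.binomial(2, 0.4, (50, 100)).astype(float)
        d[0, :3] = np.nan
        g, report = snp_qc(geno_from_dosage(d))
        assert g.n_animals == 49

    def test_hwe_proportions_kept(self):
        d = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])[:, None]
        p = hwe_chi2_p([25], [50], [25])
        assert p[0] == pytest.approx(1.0)
        g, _ = snp_qc(geno_from_dosage(np.hstack([d, d])))
        assert g.n_snps == 2

    def test_hwe_violation_removed(self):
        # counts (30, 0, 30): chi-square 60, p << 1e-4
        bad = np.repeat([0.0, 2.0], [30, 30])
        good = np.tile([0.0, 1.0, 1.0, 2.0], 15)
        p = hwe_chi2_p([30], [0], [30])
        assert p[0] == pytest.approx(stats.chi2.sf(60.0, 1))
        g, _ = snp_qc(geno_from_dosage(np.column_stack([bad, good])))
        assert g.n_snps == 1 and g.snp_ids[0] == "s1"

    def test_report_counts_are_conserved(self, rng):
        d = rng.binomial(2, 0.4, (60, 40)).astype(float)
        d[:5, 0] = np.nan
        g, report = snp_qc(geno_from_dosage(d))
        assert report["snps_in"] == 40
        assert report["snps_callrate"] <= report["snps_chrom"]
        assert report["snps_hwe"] == g.n_snps

    def test_empty_output_error(self):
        bad = np.repeat([0.0, 2.0], [30, 30])[:, None]
        with pytest.raises(ValueError, match="survive"):
            snp_qc(geno_from_dosage(bad))


class TestPca:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        m = 300
        p1, p2 = rng.uniform(0.1, 0.3, m), rng.uniform(0.6, 0.9, m)
        d = np.vstack([rng.binomial(2, p1, (100, m)),
                       rng.binomial(2, p2, (100, m))]).astype(float)
        scores = pca_covariates(geno_from_dosage(d), k=2)
        label = np.repeat([0.0, 1.0], 100)
        r = np.corrcoef(scores[:, 0], label)[0, 1]
        assert abs(r) > 0.9

    def test_zero_mean_scores(self):
        g = founder_genotypes(50, 100, seed=1)
        scores = pca_covariates(g, k=3)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_k_zero_and_k_too_large(self):
        g = founder_genotypes(20, 50, seed=2)
        assert pca_covariates(g, k=0).shape == (20, 0)
        with pytest.raises(ValueError):
            pca_covariates(g, k=20)


class TestGlm:
    def test_exact_signal(self):
        g = founder_genotypes(200, 10, seed=3)
        y = 2.0 * g.dosage[:, 4]
        res = glm_scan(y, g, None)
        row = res.table.iloc[4]
        assert row["effect"] == pytest.approx(2.0, abs=1e-10)
        assert row["p"] < 1e-200

    def test_constant_phenotype_zero_effects(self):
        g = founder_genotypes(50, 20, seed=4)
        res = glm_scan(np.ones(50), g, None)
        assert np.allclose(res.table["effect"], 0.0, atol=1e-10)

    def test_null_p_distribution_uniform(self):
        """Kolmogorov-Smirnov uniformity of null p-values (alpha = 0.01)
        for GLM and MLM; because the SNP p-values of one scan share a
        phenotype, three independent phenotype replicates are scanned and
        at least two of three must pass for each model."""
        g = founder_genotypes(500, 2000, seed=5)
        pcs = pca_covariates(g, 3)
        K = build_G(g).matrix
        glm_pass = mlm_pass = 0
        for rep in range(3):
            y = np.random.default_rng(6 + rep).standard_normal(500)
            p_glm = glm_scan(y, g, pcs).table["p"]
            p_mlm = mlm_scan(y, g, pcs, K).table["p"]
            glm_pass += stats.kstest(p_glm, "uniform").pvalue > 0.01
            mlm_pass += stats.kstest(p_mlm, "uniform").pvalue > 0.01
        assert glm_pass >= 2 and mlm_pass >= 2

    def test_monomorphic_snp_flagged(self):
        d = np.column_stack([np.ones(30), np.random.default_rng(1).integers(0, 3, 30)])
        g = geno_from_dosage(d.astype(float))
        res = glm_scan(np.random.default_rng(2).standard_normal(30), g, None)
        assert res.table["p"].iloc[0] == 1.0
        assert res.table["effect"].iloc[0] == 0.0


class TestMlm:
    def test_identity_kinship_equals_glm(self):
        g = founder_genotypes(150, 300, seed=7)
        y = np.random.default_rng(8).standard_normal(150)
        pcs = pca_covariates(g, 2)
        glm = glm_scan(y, g, pcs)
        mlm = mlm_scan(y, g, pcs, np.eye(150))
        d = np.abs(np.log10(glm.table["p"]) - np.log10(mlm.table["p"]))
        assert d.max() < 0.01

    def test_mlm_deflates_family_structure_inflation(self):
        """Polygenic signal plus family structure inflates GLM;
        the kinship term brings lambda closer to 1 in >= 9/10 seeds."""
        better = 0
        for seed in range(10):
            cfg = SimConfig(n_founders=40, n_generations=2,
                            matings_per_generation=150, n_snps=600, seed=seed)
            ped = simulate_pedigree(cfg)
            geno = simulate_genotypes(ped, cfg)
            cows = ped.generation == 2
            g = geno.subset_animals(cows)
            rng = np.random.default_rng(seed + 100)
            beta = rng.standard_normal(g.n_snps) * 0.05
            y = g.dosage @ beta + rng.standard_normal(g.n_animals)
            glm = glm_scan(y, g, None)
            K = build_G(g).matrix
            mlm = mlm_scan(y, g, None, K)
            if abs(mlm.lambda_gc() - 1) < abs(glm.lambda_gc() - 1):
                better += 1
        assert better >= 9

    def test_causal_snp_top_ranked(self):
        hits = 0
        for seed in range(10):
            g = founder_genotypes(400, 800, seed=seed + 30)
            rng = np.random.default_rng(seed + 60)
            j = int(rng.integers(0, 800))
            x = g.dosage[:, j]
            var = x.var()
            y = x * np.sqrt(0.08 / var) + rng.standard_normal(400) * np.sqrt(0.92)
            res = mlm_scan(y, g, None, build_G(g).matrix)
            hits += int(res.table["p"].idxmin() == j)
        assert hits >= 9

    def test_non_psd_kinship_error(self):
        g = founder_genotypes(20, 30, seed=9)
        K = -np.eye(20)
        with pytest.raises(ValueError, match="positive semi-definite"):
            mlm_scan(np.zeros(20) + np.random.default_rng(0).standard_normal(20),
                     g, None, K)


class TestFarmcpu:
    def test_reduces_to_glm_when_nothing_significant(self):
        g = founder_genotypes(120, 300, seed=10)
        y = np.random.default_rng(11).standard_normal(120)
        fc = farmcpu_scan(y, g, None)
        if fc.flagged:
            glm = glm_scan(y, g, None)
            assert np.allclose(fc.table["p"], glm.table["p"])
            assert np.allclose(fc.table["effect"], glm.table["effect"])

    def test_detects_planted_qtn(self):
        g = founder_genotypes(500, 1000, seed=12)
        rng = np.random.default_rng(13)
        qtn = [50, 400, 800]
        X = g.dosage[:, qtn]
        p = X.mean(axis=0) / 2
        beta = np.sqrt(0.05 / (2 * p * (1 - p)))
        y = X @ beta + rng.standard_normal(500)
        res = farmcpu_scan(y, g, None)
        sig = set(np.where(res.table["significant"])[0])
        assert len(sig & set(qtn)) == 3


class TestBonferroni:
    def test_published_snp_count_rounds_to_1e_minus_6(self):
        thr = bonferroni_threshold(0.05, 42_500)
        assert thr == pytest.approx(1.18e-6, abs=0.005e-6)
        exponent = np.floor(np.log10(thr))
        assert round(thr / 10**exponent) * 10**exponent == pytest.approx(1e-6)

    @pytest.mark.parametrize("m,expected", [(1, 0.05), (100, 5e-4)])
    def test_simple_values(self, m, expected):
        assert bonferroni_threshold(0.05, m) == pytest.approx(expected)

    def test_monotone_decreasing_in_m(self):
        ms = [1, 10, 100, 1000, 42500]
        ts = [bonferroni_threshold(0.05, m) for m in ms]
        assert np.all(np.diff(ts) < 0)

    def test_zero_m_error(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestAnnotate:
    @staticmethod
    def genes():
        return pd.DataFrame({
            "gene": ["CASK", "NYX", "TTC29"],
            "chrom": ["X", "X", "17"],
            "start": [100_000, 200_000, 50_000],
            "end": [150_000, 230_000, 90_000],
            "strand": ["+", "+", "-"],
            "exons": ["100000-101000;149000-150000", "", "50000-52000"]})

    def test_intronic_and_exonic(self):
        snps = pd.DataFrame({"snp": ["a", "b"], "chrom": ["X", "X"],
                             "pos": [120_000, 100_500]})
        recs = annotate_snps(snps, self.genes())
        assert recs[0].region == "intronic" and recs[0].genes == ["CASK"]
        assert recs[1].region == "exonic"

    def test_intergenic_with_flanking_distances(self):
        # SNP 28,036 bp past CASK and 6,763 bp before NYX
        snps = pd.DataFrame({"snp": ["v"], "chrom": ["X"],
                             "pos": [150_000 + 28_036]})
        rec = annotate_snps(snps, self.genes())[0]
        assert rec.region == "intergenic"
        assert rec.genes == ["CASK", "NYX"]
        assert rec.distances == [28_036, 200_000 - 178_036]
        assert "CASK (dist = 28036)" in rec.label()

    def test_upstream_window(self):
        snps = pd.DataFrame({"snp": ["u"], "chrom": ["X"], "pos": [99_500]})
        rec = annotate_snps(snps, self.genes(), upstream_window=2000)[0]
        assert rec.region == "upstream" and rec.genes == ["CASK"]

    def test_upstream_respects_strand(self):
        # TTC29 is on the minus strand: upstream is past its end coordinate
        snps = pd.DataFrame({"snp": ["m"], "chrom": ["17"], "pos": [90_500]})
        rec = annotate_snps(snps, self.genes(), upstream_window=2000)[0]
        assert rec.region == "upstream" and rec.genes == ["TTC29"]

    def test_unknown_chromosome(self):
        snps = pd.DataFrame({"snp": ["z"], "chrom": ["5"], "pos": [1]})
        assert annotate_snps(snps, self.genes())[0].region == "unknown"

    def test_every_snp_gets_exactly_one_region(self, rng):
        snps = pd.DataFrame({"snp": [f"s{i}" for i in range(50)],
                             "chrom": rng.choice(["X", "17", "9"], 50),
                             "pos": rng.integers(1, 300_000, 50)})
        recs = annotate_snps(snps, self.genes())
        assert len(recs) == 50
        valid = {"exonic", "intronic", "upstream", "downstream",
                 "intergenic", "unknown"}
        assert all(r.region in valid for r in recs)
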