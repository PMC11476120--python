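"""Relationship matrices, AI-REML variance components, derived genetic
parameters and breeding values."""

import numpy as np
import pandas as pd
import pytest

from mirfa.genparams import (RandomTerm, RelationshipMatrix,
                             VarianceComponents, aireml, bend_to_psd, build_A,
                             build_G, build_H_inverse, ebv_solve,
                             genetic_parameters, reml_fit, reml_fit_bivariate)
from mirfa.phenocorrect import add_level_columns
from mirfa.simdata import (GenotypeMatrix, Pedigree, SimConfig,
                           simulate_genotypes, simulate_pedigree,
                           simulate_phenotypes)

from conftest import anova_icc, kinship_oracle


def ped_from_rows(rows):
    rows = np.array(rows)
    return Pedigree(rows[:, 0], rows[:, 1], rows[:, 2],
                    np.zeros(len(rows), dtype=int))


class TestBuildA:
    def test_founders_identity(self):
        ped = ped_from_rows([(1, 0, 0), (2, 0, 0), (3, 0, 0)])
        assert np.allclose(build_A(ped).matrix, np.eye(3))

    def test_trio(self):
        ped = ped_from_rows([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        A = build_A(ped).matrix
        assert A[2, 0] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        ped = ped_from_rows([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2),
                             (5, 3, 4)])
        A = build_A(ped).matrix
        assert A[4, 4] == pytest.approx(1.25)  # F = 0.25

    def test_matches_path_counting_oracle_on_small_pedigrees(self):
        """Exhaustive comparison with the recursive-coancestry oracle over
        a family of small pedigrees including loops and half-sibs."""
        pedigrees = [
            [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4),
             (6, 3, 4), (7, 5, 6)],
            [(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 1, 2), (5, 1, 3),
             (6, 4, 5)],
            [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 3), (5, 1, 4)],
            [(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0), (5, 1, 2),
             (6, 3, 4), (7, 5, 6), (8, 5, 6)],
            [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 3, 0), (5, 4, 2)],
        ]
        for rows in pedigrees:
            ped = ped_from_rows(rows)
            A = build_A(ped).matrix
            oracle = kinship_oracle(ped.animal, ped.sire, ped.dam)
            assert np.allclose(A, oracle, atol=1e-12)

    def test_unordered_pedigree_error(self):
        ped = ped_from_rows([(1, 2, 0), (2, 0, 0)])
        with pytest.raises(ValueError, match="ordered"):
            build_A(ped)


def geno_from_dosage(dosage):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    return GenotypeMatrix(np.arange(1, n + 1),
                          np.array([f"s{j}" for j in range(m)]),
                          np.array(["1"] * m), np.arange(1, m + 1) * 100,
                          dosage)


class TestBuildG:
    def test_identical_genotypes_equal_rows(self, rng):
        d = rng.integers(0, 3, (5, 40)).astype(float)
        d[1] = d[0]
        G = build_G(geno_from_dosage(d)).matrix
        assert np.allclose(G[0], G[1])
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_mean_diagonal_close_to_one(self):
        cfg = SimConfig(n_founders=400, n_generations=0,
                        matings_per_generation=0, n_snps=1000, seed=13)
        geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
        G = build_G(geno).matrix
        assert abs(np.diag(G).mean() - 1.0) < 0.05

    def test_duplicating_snps_leaves_G_unchanged(self, rng):
        d = rng.integers(0, 3, (8, 30)).astype(float)
        G1 = build_G(geno_from_dosage(d)).matrix
        G2 = build_G(geno_from_dosage(np.hstack([d, d]))).matrix
        assert np.allclose(G1, G2, atol=1e-12)


class TestBuildHInverse:
    def test_no_genotyped_equals_A_inverse(self):
        ped = ped_from_rows([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        A = build_A(ped)
        G = RelationshipMatrix(np.array([], dtype=int), np.empty((0, 0)), "G")
        H = build_H_inverse(A, G, genotyped_ids=[])
        assert np.allclose(H.matrix, np.linalg.inv(A.matrix))

    def test_G_equals_A_recovers_A_inverse(self):
        ped = ped_from_rows([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2)])
        A = build_A(ped)
        G = RelationshipMatrix(A.ids, A.matrix.copy(), "G")
        H = build_H_inverse(A, G, genotyped_ids=A.ids, w=1.0)
        assert np.allclose(H.matrix, np.linalg.inv(A.matrix), atol=1e-10)

    def test_matches_explicit_H_assembly(self, rng):
        """H^-1 from the blockwise formula equals the inverse of the
        textbook H built explicitly (conditional-distribution form)."""
        cfg = SimConfig(n_founders=6, n_generations=1,
                        matings_per_generation=6, n_snps=200, seed=2)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        A = build_A(ped)
        gen_ids = ped.animal[6:]  # genotyped subset: the offspring
        gmask = np.isin(geno.animal_ids, gen_ids)
        G = build_G(geno.subset_animals(gmask))
        w = 0.9
        Hinv = build_H_inverse(A, G, genotyped_ids=gen_ids, w=w).matrix
        # explicit H
        n = len(ped)
        gi = np.arange(6, n)
        oi = np.arange(0, 6)
        A11 = A.matrix[np.ix_(oi, oi)]
        A12 = A.matrix[np.ix_(oi, gi)]
        A22 = A.matrix[np.ix_(gi, gi)]
        Gb = w * G.matrix + (1 - w) * A22
        A22i = np.linalg.inv(A22)
        H = np.empty_like(A.matrix)
        H[np.ix_(oi, oi)] = A11 + A12 @ A22i @ (Gb - A22) @ A22i @ A12.T
        H[np.ix_(oi, gi)] = A12 @ A22i @ Gb
        H[np.ix_(gi, oi)] = H[np.ix_(oi, gi)].T
        H[np.ix_(gi, gi)] = Gb
        assert np.allclose(Hinv, np.linalg.inv(H), atol=1e-8)

    def test_unknown_genotyped_id_error(self):
        ped = ped_from_rows([(1, 0, 0), (2, 0, 0)])
        A = build_A(ped)
        G = RelationshipMatrix(np.array([9]), np.eye(1), "G")
        with pytest.raises(ValueError, match="subset"):
            build_H_inverse(A, G, genotyped_ids=[9])


def balanced_records(n_cows, m_records, sb2, sw2, seed):
    rng = np.random.default_rng(seed)
    cow = np.repeat(np.arange(1, n_cows + 1), m_records)
    b = rng.normal(0, np.sqrt(sb2), n_cows)
    y = b[cow - 1] + rng.normal(0, np.sqrt(sw2), len(cow))
    return pd.DataFrame({"animal": cow, "y": y})


class TestAireml:
    def test_identity_kinship_matches_anova_icc(self):
        """With K = I the additive and permanent-environment terms jointly
        form the cow effect, so (su2+sc2)/sp2 must equal the balanced
        one-way ANOVA intraclass estimator."""
        rec = balanced_records(300, 4, 0.6, 0.9, seed=5)
        K = RelationshipMatrix(np.arange(1, 301), np.eye(300), "A")
        vc, _ = reml_fit(rec, K, fixed_effects=(), tol=1e-12)
        icc = anova_icc(rec)
        assert (vc.sigma_u2 + vc.sigma_c2) / vc.sigma_p2 == \
            pytest.approx(icc, abs=1e-6)

    def test_loglik_not_decreased_from_start(self):
        rec = balanced_records(100, 3, 0.5, 0.5, seed=7)
        K = RelationshipMatrix(np.arange(1, 101), np.eye(100), "A")
        y = rec["y"].to_numpy()
        X = np.ones((len(rec), 1))
        Z = pd.get_dummies(rec["animal"]).to_numpy(float)
        start = {"u": 0.1, "e": 1.5}
        fit0 = aireml(y, X, [RandomTerm("u", Z, None, 0.0)], start=start,
                      max_iter=0)
        fit = aireml(y, X, [RandomTerm("u", Z, None, 0.0)], start=start)
        assert fit.loglik >= fit0.loglik - 1e-8

    def test_parameter_recovery_single_seed(self):
        cfg = SimConfig(n_founders=150, n_generations=2,
                        matings_per_generation=400, n_snps=50, n_qtn=0,
                        sigma_u2=0.3, sigma_c2=0.2, sigma_e2=0.5,
                        records_per_cow=(3, 3), seed=17)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        rec, _ = simulate_phenotypes(ped, geno, cfg,
                                     record_cows=ped.animal[ped.generation >= 1])
        rec = add_level_columns(rec)
        vc, _ = reml_fit(rec, build_A(ped))
        assert vc.converged
        p = genetic_parameters(vc)
        assert p["h2"] == pytest.approx(0.3, abs=0.1)
        assert p["t"] == pytest.approx(0.5, abs=0.08)

    def test_non_pd_kinship_error(self):
        rec = balanced_records(10, 2, 0.5, 0.5, seed=1)
        K = RelationshipMatrix(np.arange(1, 11), np.zeros((10, 10)), "A")
        with pytest.raises(ValueError, match="positive definite"):
            reml_fit(rec, K, fixed_effects=())


class TestBivariate:
    def test_duplicated_trait_has_unit_genetic_correlation(self):
        rec = balanced_records(150, 3, 0.4, 0.6, seed=3)
        rec["y2"] = rec["y"]
        K = RelationshipMatrix(np.arange(1, 151), np.eye(150), "A")
        vc1, vc2, pair = reml_fit_bivariate(rec, K, ("y", "y2"),
                                            fixed_effects=())
        p = genetic_parameters(vc1, vc2, pair)
        assert p["r_G"] == pytest.approx(1.0, abs=1e-6)
        assert p["r_P"] == pytest.approx(1.0, abs=1e-6)


class TestGeneticParameters:
    @pytest.mark.parametrize("su,sc,se,h2,t", [
        (18.91, 18.77, 24.27, 0.31, 0.61),   # saturated fatty-acid group
        (4.01, 6.26, 4.80, 0.27, 0.68),      # C16:0
    ])
    def test_published_variance_component_ratios(self, su, sc, se, h2, t):
        vc = VarianceComponents(su, sc, se)
        p = genetic_parameters(vc)
        assert round(p["h2"], 2) == h2
        assert round(p["t"], 2) == t

    def test_degenerate_components(self):
        assert genetic_parameters(VarianceComponents(0.0, 0.2, 0.3))["h2"] == 0
        with pytest.raises(ValueError):
            genetic_parameters(VarianceComponents(0.0, 0.0, 0.0))

    def test_h2_never_exceeds_t(self, rng):
        for _ in range(20):
            su, sc, se = rng.uniform(0.01, 2.0, 3)
            p = genetic_parameters(VarianceComponents(su, sc, se))
            assert p["h2"] <= p["t"] + 1e-12

    def test_bend_to_psd(self):
        M = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        B = bend_to_psd(M)
        assert np.linalg.eigvalsh(B).min() >= 0
        assert np.allclose(np.diag(B), 1.0)


class TestEbv:
    def test_shrinkage_limit_zero_heritability(self):
        rec = balanced_records(50, 3, 0.5, 0.5, seed=2)
        K = RelationshipMatrix(np.arange(1, 51), np.eye(50), "A")
        vc = VarianceComponents(sigma_u2=1e-9, sigma_c2=0.5, sigma_e2=0.5)
        ebv = ebv_solve(rec, vc, K, fixed_effects=())
        assert np.max(np.abs(ebv.table["ebv"])) < 1e-5

    def test_mme_equals_ridge_regression_with_identity_K(self):
        """One record per animal, K=I: BLUP equals ridge with penalty
        se2/su2 on the centered phenotype."""
        rng = np.random.default_rng(4)
        n = 40
        y = rng.standard_normal(n) + 3.0
        rec = pd.DataFrame({"animal": np.arange(1, n + 1), "y": y})
        K = RelationshipMatrix(np.arange(1, n + 1), np.eye(n), "A")
        su2, se2 = 0.7, 1.3
        vc = VarianceComponents(su2, 0.0, se2)
        ebv = ebv_solve(rec, vc, K, fixed_effects=())
        lam = se2 / su2
        # GLS intercept under V = su2 I + se2 I is the plain mean
        u_ridge = (y - y.mean()) / (1.0 + lam)
        got = ebv.table["ebv"].to_numpy()
        assert np.allclose(got - got.mean(), u_ridge - u_ridge.mean(),
                           atol=1e-8)

    def test_full_sibs_with_same_records_have_equal_ebvs(self):
        ped = ped_from_rows([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2)])
        A = build_A(ped)
        rec = pd.DataFrame({"animal": [3, 3, 4, 4], "y": [1.0, 1.2, 1.0, 1.2]})
        vc = VarianceComponents(0.4, 0.1, 0.5)
        ebv = ebv_solve(rec, vc, A, fixed_effects=())
        tab = ebv.table.set_index("animal")
        assert tab.loc[3, "ebv"] == pytest.approx(tab.loc[4, "ebv"], abs=1e-10)

    def test_ebv_accuracy_against_truth(self):
        """corr(EBV, true u) at h2=0.3, t=0.5, 3 records per cow is close
        to the theoretical sqrt(n h2 / (1+(n-1)t)) ~ 0.67."""
        cfg = SimConfig(n_founders=150, n_generations=2,
                        matings_per_generation=750, n_snps=50, n_qtn=0,
                        sigma_u2=0.3, sigma_c2=0.2, sigma_e2=0.5,
                        records_per_cow=(3, 3), seed=11)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        rec, truth = simulate_phenotypes(
            ped, geno, cfg, record_cows=ped.animal[ped.generation >= 1])
        rec = add_level_columns(rec)
        A = build_A(ped)
        vc, _ = reml_fit(rec, A)
        ebv = ebv_solve(rec, vc, A)
        pos = {a: i for i, a in enumerate(A.ids)}
        cows = sorted(rec["animal"].unique())
        u_true = [truth.u[pos[c]] for c in cows]
        u_hat = ebv.table.set_index("animal").loc[cows, "ebv"]
        assert np.corrcoef(u_true, u_hat)[0, 1] >= 0.6
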