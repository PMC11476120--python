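"""Relationship matrices, AI-REML variance components, and breeding values.

The repeatability animal model for a trait with repeated test-day records is

    y = Xb + Zu + Wc + e,   u ~ N(0, K su2),  c ~ N(0, I sc2),  e ~ N(0, I se2)

with K a pedigree (A), genomic (G) or single-step (H) relationship matrix.
Variance components are estimated by average-information REML with guarded
ascent: an AI (Newton) step is taken when it stays in the parameter space
and does not decrease the restricted likelihood, otherwise the monotone
EM-REML update is used.  Convergence follows the squared-relative-change
criterion sum((b_t - b_{t-1})^2) / sum(b_t^2) < 1e-6 with at most 300
iterations.

Derived parameters: heritability h2 = su2/sp2, repeatability
t = (su2+sc2)/sp2 with sp2 = su2+sc2+se2, and for trait pairs the genetic
and phenotypic correlations r_G = cov_u/(su1 su2), r_P = cov_p/(sp1 sp2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .simdata import GenotypeMatrix, Pedigree

VARIANCE_FLOOR_FRAC = 1e-8  # times total variance


@dataclass
class RelationshipMatrix:
    """Symmetric animal x animal covariance-structure matrix."""

    ids: np.ndarray
    matrix: np.ndarray
    kind: str = "A"           # A (pedigree), G (genomic), H (single-step)
    is_inverse: bool = False  # True when `matrix` stores the inverse

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")


@dataclass
class VarianceComponents:
    """REML estimates for one trait (or a pair, when covariances are set)."""

    sigma_u2: float
    sigma_c2: float
    sigma_e2: float
    converged: bool = True
    n_iter: int = 0
    loglik: float = np.nan
    cov_u: float | None = None   # pair quantities, sum-trait decomposition
    cov_c: float | None = None
    cov_e: float | None = None

    @property
    def sigma_p2(self) -> float:
        return self.sigma_u2 + self.sigma_c2 + self.sigma_e2


# ----------------------------------------------------------------------------
# relationship matrices


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method."""
    n = len(ped)
    idx = ped.index_of()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        si = idx.get(s, -1)
        di = idx.get(d, -1)
        if si >= i or di >= i:
            raise ValueError("pedigree is not ordered parents-first (or cyclic)")
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += 0.5 * A[:i, si]
            if di >= 0:
                row += 0.5 * A[:i, di]
            A[:i, i] = row
            A[i, :i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(ped.animal.copy(), A, kind="A")


def build_G(geno: GenotypeMatrix, freqs="observed") -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = Z Z' / (2 sum p_j (1-p_j)) with Z the allele-B dosages centered at
    2p_j.  Missing dosages are mean-imputed; monomorphic (or all-missing)
    SNPs are dropped.
    """
    M = np.array(geno.dosage, float)
    col_mean = np.nanmean(M, axis=0)
    all_missing = ~np.isfinite(col_mean)
    if all_missing.any():
        warnings.warn(f"dropping {all_missing.sum()} all-missing SNPs")
    if isinstance(freqs, str) and freqs == "observed":
        p = col_mean / 2.0
    else:
        p = np.asarray(freqs, float)
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    M = M[:, keep]
    p = p[keep]
    inds = np.where(np.isnan(M))
    M[inds] = (2 * p)[inds[1]]
    Z = M - 2 * p
    denom = 2.0 * float(np.sum(p * (1 - p)))
    if denom <= 0:
        raise ValueError("no polymorphic SNPs to build G from")
    return RelationshipMatrix(geno.animal_ids.copy(), Z @ Z.T / denom, kind="G")


def build_H_inverse(A: RelationshipMatrix, G: RelationshipMatrix,
                    genotyped_ids=None, w: float = 0.95) -> RelationshipMatrix:
    """Single-step H-matrix inverse.

    H^-1 = A^-1 + [[0, 0], [0, (w G + (1-w) A22)^-1 - A22^-1]] on the
    genotyped block; blending G with A22 (weight ``w`` on G) guarantees
    invertibility.
    """
    if genotyped_ids is None:
        genotyped_ids = G.ids
    gset = set(map(str, genotyped_ids))
    if not gset <= set(map(str, A.ids)):
        raise ValueError("genotyped ids must be a subset of pedigree ids")
    Ainv = np.linalg.inv(A.matrix)
    Hinv = Ainv.copy()
    if len(genotyped_ids) > 0:
        apos = {str(a): i for i, a in enumerate(A.ids)}
        gpos = {str(a): i for i, a in enumerate(G.ids)}
        ai = np.array([apos[str(g)] for g in genotyped_ids])
        gi = np.array([gpos[str(g)] for g in genotyped_ids])
        A22 = A.matrix[np.ix_(ai, ai)]
        Gb = w * G.matrix[np.ix_(gi, gi)] + (1 - w) * A22
        try:
            Gb_inv = np.linalg.inv(Gb)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "blended G is singular; lower the blend weight w") from err
        Hinv[np.ix_(ai, ai)] += Gb_inv - np.linalg.inv(A22)
    return RelationshipMatrix(A.ids.copy(), Hinv, kind="H", is_inverse=True)


# ----------------------------------------------------------------------------
# generic univariate AI-REML engine


@dataclass
class RandomTerm:
    """One random effect: incidence matrix and covariance structure."""

    name: str
    Z: np.ndarray                    # n x q incidence
    Kinv: np.ndarray | None = None   # None means identity structure
    logdet_K: float = 0.0


@dataclass
class MixedModelFit:
    """AI-REML fit of y = Xb + sum_i Z_i a_i + e."""

    variances: dict[str, float]
    converged: bool
    n_iter: int
    loglik: float
    beta: np.ndarray
    effects: dict[str, np.ndarray]
    diag_cinv: dict[str, np.ndarray]  # effect-block diagonal of C^-1


def aireml(y: np.ndarray, X: np.ndarray, terms: list[RandomTerm],
           start: dict[str, float] | None = None, max_iter: int = 300,
           tol: float = 1e-6) -> MixedModelFit:
    """Guarded average-information REML for an arbitrary set of independent
    random terms with iid residual."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    r = len(terms)
    q = [t.Z.shape[1] for t in terms]
    qtot = sum(q)
    names = [t.name for t in terms]

    # constant design cross-products
    blocks = [X] + [t.Z for t in terms]
    rhs = np.concatenate([b.T @ y for b in blocks])
    C0 = np.block([[bi.T @ bj for bj in blocks] for bi in blocks])
    yty = float(y @ y)
    offs = np.cumsum([p] + q)  # block offsets after X

    vary = float(np.var(y)) or 1.0
    floor = VARIANCE_FLOOR_FRAC * vary
    if start is None:
        theta = {nm: 0.5 * vary / r for nm in names}
        theta["e"] = 0.5 * vary
    else:
        theta = {k: max(float(v), floor) for k, v in start.items()}

    def assemble(th):
        C = C0.copy()
        for i, t in enumerate(terms):
            lam = th["e"] / th[names[i]]
            sl = slice(offs[i], offs[i] + q[i])
            if t.Kinv is None:
                C[sl, sl] += lam * np.eye(q[i])
            else:
                C[sl, sl] += lam * t.Kinv
        return C

    def factor_and_solve(th):
        C = assemble(th)
        cf = cho_factor(C, lower=True)
        sol = cho_solve(cf, rhs)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ssr = yty - float(sol @ rhs)
        m2l = ((n - p - qtot) * np.log(th["e"])
               + sum(qk * np.log(th[nm]) for qk, nm in zip(q, names))
               + sum(t.logdet_K for t in terms)
               + logdetC + ssr / th["e"])
        return cf, sol, -0.5 * m2l

    cf, sol, ll = factor_and_solve(theta)
    # max_iter=0 solves the mixed-model equations at the start values
    converged = max_iter == 0
    it = 0
    for it in range(1, max_iter + 1):
        beta = sol[:p]
        u = [sol[offs[i]:offs[i] + q[i]] for i in range(r)]
        fitted = X @ beta
        for i, t in enumerate(terms):
            fitted = fitted + t.Z @ u[i]
        ehat = y - fitted
        Cinv = cho_solve(cf, np.eye(C0.shape[0]))

        # traces tr(K_i^-1 C^ii) and quadratic forms u' K^-1 u
        Ti, quad = [], []
        for i, t in enumerate(terms):
            sl = slice(offs[i], offs[i] + q[i])
            Cii = Cinv[sl, sl]
            if t.Kinv is None:
                Ti.append(float(np.trace(Cii)))
                quad.append(float(u[i] @ u[i]))
            else:
                Ti.append(float(np.sum(t.Kinv * Cii.T)))
                quad.append(float(u[i] @ t.Kinv @ u[i]))

        se2 = theta["e"]
        score = np.empty(r + 1)
        for i, nm in enumerate(names):
            si2 = theta[nm]
            trP = q[i] / si2 - se2 * Ti[i] / si2**2
            score[i] = -0.5 * (trP - quad[i] / si2**2)
        trP_e = (n - p - qtot + sum(se2 / theta[nm] * T
                                    for nm, T in zip(names, Ti))) / se2
        score[r] = -0.5 * (trP_e - float(ehat @ ehat) / se2**2)

        # average-information matrix from working vectors w_i = dV/dθ_i Py
        Wmat = np.empty((n, r + 1))
        for i, t in enumerate(terms):
            Wmat[:, i] = (t.Z @ u[i]) / theta[names[i]]
        Wmat[:, r] = ehat / se2
        rhs_w = np.concatenate([b.T @ Wmat for b in blocks])
        sol_w = cho_solve(cf, rhs_w)
        # P w = (w - M sol_w)/se2 with M = [X, Z...]
        Mw = X @ sol_w[:p]
        for i, t in enumerate(terms):
            Mw = Mw + t.Z @ sol_w[offs[i]:offs[i] + q[i]]
        PW = (Wmat - Mw) / se2
        AI = 0.5 * (Wmat.T @ PW)
        AI = 0.5 * (AI + AI.T)

        # EM candidate (monotone fallback)
        em = {nm: (quad[i] + se2 * Ti[i]) / q[i] for i, nm in enumerate(names)}
        em["e"] = (yty - float(sol @ rhs)) / (n - p)

        th_vec = np.array([theta[nm] for nm in names] + [theta["e"]])
        accepted = None
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(16):
                cand = th_vec + step * delta
                if np.all(cand > floor):
                    th_new = dict(zip(names + ["e"], cand))
                    try:
                        cf_new, sol_new, ll_new = factor_and_solve(th_new)
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if ll_new >= ll - 1e-10:
                        accepted = (th_new, cf_new, sol_new, ll_new)
                        break
                step *= 0.5
        if accepted is None:
            th_new = {k: max(v, floor) for k, v in em.items()}
            cf_new, sol_new, ll_new = factor_and_solve(th_new)
            accepted = (th_new, cf_new, sol_new, ll_new)

        th_new, cf, sol, ll = accepted
        new_vec = np.array([th_new[nm] for nm in names] + [th_new["e"]])
        crit = float(np.sum((new_vec - th_vec) ** 2) / np.sum(new_vec**2))
        theta = th_new
        if crit < tol:
            converged = True
            break
    if not converged:
        warnings.warn("AI-REML did not converge; returning last iterate")

    beta = sol[:p]
    Cinv = cho_solve(cf, np.eye(C0.shape[0]))
    effects = {}
    diag_cinv = {}
    for i, nm in enumerate(names):
        sl = slice(offs[i], offs[i] + q[i])
        effects[nm] = sol[sl]
        diag_cinv[nm] = np.diag(Cinv)[sl]
    return MixedModelFit(variances=dict(theta), converged=converged,
                         n_iter=it, loglik=ll, beta=beta, effects=effects,
                         diag_cinv=diag_cinv)


# ----------------------------------------------------------------------------
# repeatability animal model front end


def _design(records: pd.DataFrame, fixed_effects, K: RelationshipMatrix,
            animal_col: str):
    """Build X (corner-constrained dummies), Z (animal), W (permanent env)."""
    n = len(records)
    cols = [np.ones(n)]
    col_names = ["mu"]
    for f in fixed_effects:
        levels = sorted(pd.unique(records[f]))
        for lev in levels[1:]:  # first level absorbed in the mean
            cols.append((records[f] == lev).to_numpy(float))
            col_names.append(f"{f}:{lev}")
    X = np.column_stack(cols)
    kpos = {str(a): i for i, a in enumerate(K.ids)}
    missing = [a for a in records[animal_col].astype(str) if a not in kpos]
    if missing:
        raise ValueError(f"records reference animals absent from K: "
                         f"{sorted(set(missing))[:5]}")
    arow = records[animal_col].astype(str).map(kpos).to_numpy()
    Z = np.zeros((n, len(K.ids)))
    Z[np.arange(n), arow] = 1.0
    cows = np.array(sorted(pd.unique(records[animal_col].astype(str))))
    cpos = {a: i for i, a in enumerate(cows)}
    W = np.zeros((n, len(cows)))
    W[np.arange(n), records[animal_col].astype(str).map(cpos)] = 1.0
    return X, col_names, Z, W, cows


def _k_inverse(K: RelationshipMatrix) -> tuple[np.ndarray, float]:
    if K.is_inverse:
        sign, logdet = np.linalg.slogdet(K.matrix)
        return K.matrix, -logdet
    try:
        cf = cho_factor(K.matrix, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError("relationship matrix is not positive definite") from err
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return cho_solve(cf, np.eye(len(K.ids))), logdet


def reml_fit(records: pd.DataFrame, K: RelationshipMatrix,
             value_col: str = "y", animal_col: str = "animal",
             fixed_effects=("parity_level", "lact_level", "season"),
             permanent_env: bool = True, start=None, max_iter: int = 300,
             tol: float = 1e-6) -> tuple[VarianceComponents, MixedModelFit]:
    """Fit the repeatability animal model by AI-REML.

    ``K`` covers every animal to be evaluated (with or without records).
    Returns the variance components and the full mixed-model fit.
    """
    fixed_effects = [f for f in fixed_effects if f in records.columns
                     and records[f].nunique() > 1]
    counts = records[animal_col].value_counts()
    if permanent_env and (counts.max() < 2):
        warnings.warn("no animal has repeated records; permanent-environment "
                      "variance is unidentifiable")
    X, _, Z, W, cows = _design(records, fixed_effects, K, animal_col)
    Kinv, logdetK = _k_inverse(K)
    terms = [RandomTerm("u", Z, Kinv, logdetK)]
    if permanent_env:
        terms.append(RandomTerm("c", W, None, 0.0))
    y = records[value_col].to_numpy(float)
    fit = aireml(y, X, terms, start=start, max_iter=max_iter, tol=tol)
    vc = VarianceComponents(
        sigma_u2=fit.variances["u"],
        sigma_c2=fit.variances.get("c", 0.0),
        sigma_e2=fit.variances["e"],
        converged=fit.converged, n_iter=fit.n_iter, loglik=fit.loglik)
    return vc, fit


def reml_fit_bivariate(records: pd.DataFrame, K: RelationshipMatrix,
                       value_cols: tuple[str, str], **kw
                       ) -> tuple[VarianceComponents, VarianceComponents,
                                  VarianceComponents]:
    """Pairwise (co)variance components via the sum-of-traits decomposition.

    Both traits must be recorded on the same rows.  The covariance of each
    component x is (var_x(y1+y2) - var_x(y1) - var_x(y2)) / 2, which equals
    the bivariate REML solution in the balanced equal-design case.  Returns
    (vc1, vc2, vc_pair) with the covariances stored on ``vc_pair``.
    """
    c1, c2 = value_cols
    rec = records.copy()
    rec["_sum"] = rec[c1] + rec[c2]
    vc1, _ = reml_fit(rec, K, value_col=c1, **kw)
    vc2, _ = reml_fit(rec, K, value_col=c2, **kw)
    vcs, _ = reml_fit(rec, K, value_col="_sum", **kw)
    pair = VarianceComponents(
        sigma_u2=np.nan, sigma_c2=np.nan, sigma_e2=np.nan,
        converged=vc1.converged and vc2.converged and vcs.converged,
        n_iter=vc1.n_iter + vc2.n_iter + vcs.n_iter,
        cov_u=0.5 * (vcs.sigma_u2 - vc1.sigma_u2 - vc2.sigma_u2),
        cov_c=0.5 * (vcs.sigma_c2 - vc1.sigma_c2 - vc2.sigma_c2),
        cov_e=0.5 * (vcs.sigma_e2 - vc1.sigma_e2 - vc2.sigma_e2))
    return vc1, vc2, pair


# ----------------------------------------------------------------------------
# derived parameters


def genetic_parameters(vc: VarianceComponents,
                       vc2: VarianceComponents | None = None,
                       pair: VarianceComponents | None = None) -> dict:
    """Heritability and repeatability (and correlations for a pair).

    h2 = su2/sp2 and t = (su2+sc2)/sp2; for a pair with covariances,
    r_G = cov_u/(su1 su2) and r_P = cov_p/(sp1 sp2) with
    cov_p = cov_u + cov_c + cov_e.  Correlations are clipped ("bent") into
    [-1, 1].
    """
    sp2 = vc.sigma_p2
    if sp2 <= 0:
        raise ValueError("total variance must be positive")
    out = {"h2": vc.sigma_u2 / sp2,
           "t": (vc.sigma_u2 + vc.sigma_c2) / sp2,
           "sigma_p2": sp2}
    if vc2 is not None and pair is not None:
        su1 = np.sqrt(vc.sigma_u2)
        su2 = np.sqrt(vc2.sigma_u2)
        cov_p = pair.cov_u + pair.cov_c + pair.cov_e
        out["r_G"] = float(np.clip(pair.cov_u / (su1 * su2), -1.0, 1.0)) \
            if su1 > 0 and su2 > 0 else np.nan
        out["r_P"] = float(np.clip(
            cov_p / np.sqrt(vc.sigma_p2 * vc2.sigma_p2), -1.0, 1.0))
    return out


def bend_to_psd(M: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nearest-PSD bending of a (correlation/covariance) matrix by flooring
    its eigenvalues."""
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    if vals.min() >= eps:
        return M
    vals = np.clip(vals, eps, None)
    out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d) * np.sqrt(np.outer(np.diag(M), np.diag(M)))


# ----------------------------------------------------------------------------
# EBVs


@dataclass
class EBVTable:
    table: pd.DataFrame          # animal, ebv, reliability
    accuracy: float              # corr(per-cow corrected phenotype, EBV)

    def summary(self) -> dict:
        e = self.table["ebv"]
        return {"mean": float(e.mean()), "min": float(e.min()),
                "max": float(e.max()), "acc": self.accuracy}


def ebv_solve(records: pd.DataFrame, vc: VarianceComponents,
              K: RelationshipMatrix, value_col: str = "y",
              animal_col: str = "animal",
              fixed_effects=("parity_level", "lact_level", "season"),
              corrected: pd.Series | None = None) -> EBVTable:
    """BLUP breeding values at the REML estimates.

    EBVs are centered to mean 0 over the evaluated animals.  Accuracy is the
    Pearson correlation between the per-cow corrected phenotype (per-cow mean
    of the record residuals after removing estimated fixed effects, unless a
    precomputed series indexed by animal id is supplied) and the EBV;
    a PEV-based reliability is reported per animal as auxiliary output.
    """
    if not vc.converged:
        warnings.warn("variance components did not converge; EBVs are "
                      "computed at the last iterate")
    fixed_effects = [f for f in fixed_effects if f in records.columns
                     and records[f].nunique() > 1]
    X, _, Z, W, cows = _design(records, fixed_effects, K, animal_col)
    Kinv, logdetK = _k_inverse(K)
    terms = [RandomTerm("u", Z, Kinv, logdetK)]
    if vc.sigma_c2 > 0:
        terms.append(RandomTerm("c", W, None, 0.0))
    start = {"u": max(vc.sigma_u2, 1e-10), "e": vc.sigma_e2}
    if vc.sigma_c2 > 0:
        start["c"] = vc.sigma_c2
    # solve the MME once at the supplied variance components
    fit = aireml(records[value_col].to_numpy(float), X, terms, start=start,
                 max_iter=0)
    u = fit.effects["u"]
    u = u - u.mean()
    rel = 1.0 - fit.variances["e"] * fit.diag_cinv["u"] / \
        np.maximum(vc.sigma_u2 * np.diag(K.matrix) if not K.is_inverse
                   else vc.sigma_u2, 1e-12)
    rel = np.clip(rel, 0.0, 1.0)
    table = pd.DataFrame({"animal": K.ids, "ebv": u, "reliability": rel})
    if corrected is None:
        resid = records[value_col].to_numpy(float) - X @ fit.beta
        corrected = pd.Series(resid).groupby(
            records[animal_col].astype(str).to_numpy()).mean()
    kpos = {str(a): i for i, a in enumerate(K.ids)}
    ebv_at = np.array([u[kpos[a]] for a in corrected.index.astype(str)])
    cvals = corrected.to_numpy(float)
    if np.std(cvals) > 0 and np.std(ebv_at) > 0:
        accuracy = float(np.corrcoef(cvals, ebv_at)[0, 1])
    else:
        accuracy = float("nan")
    return EBVTable(table=table, accuracy=accuracy)
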