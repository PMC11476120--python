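"""Association scans for corrected per-cow phenotypes.

Three per-SNP models are provided:

* GLM:      y = PCs + s + e           (population structure only)
* MLM:      y = PCs + s + g + e,  g ~ N(0, K sg2)  (kinship random effect,
            variance components estimated once on the null model — P3D —
            then generalized least squares per SNP via the eigendecomposition
            of K)
* FarmCPU:  iterates a fixed-effect step (each SNP tested with the current
            pseudo-QTNs as covariates) and a random-effect step (pseudo-QTNs
            re-selected as the best SNP per genomic bin, with bin size and
            QTN count chosen by maximizing the REML likelihood of a kinship
            built from the candidate set) until the pseudo-QTN set
            stabilizes.

Genome-wide significance uses the Bonferroni threshold alpha / m over the m
tested SNPs.  SNP QC drops loci and individuals below a 0.98 call rate and
loci with a 1-df Hardy-Weinberg chi-square p below 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .simdata import GenotypeMatrix

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549


@dataclass
class QCConfig:
    call_rate: float = 0.98
    hwe_p: float = 1e-4
    keep_chroms: tuple = tuple(str(c) for c in range(1, 30)) + ("X",)


@dataclass
class GwasResult:
    """Per-SNP effects and p-values from one scan."""

    table: pd.DataFrame          # snp, chrom, pos, effect, p, significant
    model: str
    threshold: float
    n_samples: int
    flagged: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def lambda_gc(self) -> float:
        chi2 = stats.chi2.isf(self.table["p"].clip(1e-300, 1.0), 1)
        return float(np.median(chi2) / CHI2_MEDIAN_1DF)


# ----------------------------------------------------------------------------
# QC


def hwe_chi2_p(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """1-df Hardy-Weinberg chi-square p from genotype counts (AA, AB, BB)."""
    n0, n1, n2 = (np.asarray(a, float) for a in (n0, n1, n2))
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1 - p
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        chi2 = np.zeros_like(n)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi2 += term
    pval = stats.chi2.sf(chi2, 1)
    pval[n == 0] = 1.0
    return pval


def snp_qc(geno: GenotypeMatrix, cfg: QCConfig | None = None
           ) -> tuple[GenotypeMatrix, dict]:
    """Call-rate filtering (SNPs first, then individuals) followed by the
    Hardy-Weinberg filter; returns the filtered matrix and a step report."""
    cfg = cfg or QCConfig()
    report = {"snps_in": geno.n_snps, "animals_in": geno.n_animals}
    keep_chrom = np.isin(geno.chrom.astype(str), cfg.keep_chroms)
    g = geno.subset_snps(keep_chrom)
    report["snps_chrom"] = g.n_snps

    called = np.isfinite(g.dosage)
    snp_rate = called.mean(axis=0)
    g = g.subset_snps(snp_rate >= cfg.call_rate)
    report["snps_callrate"] = g.n_snps

    ind_rate = np.isfinite(g.dosage).mean(axis=1)
    g = g.subset_animals(ind_rate >= cfg.call_rate)
    report["animals_callrate"] = g.n_animals

    d = g.dosage
    n0 = np.nansum(d == 0, axis=0)
    n1 = np.nansum(d == 1, axis=0)
    n2 = np.nansum(d == 2, axis=0)
    pvals = hwe_chi2_p(n0, n1, n2)
    g = g.subset_snps(pvals >= cfg.hwe_p)
    report["snps_hwe"] = g.n_snps
    if g.n_snps == 0:
        raise ValueError("no SNPs survive QC")
    return g, report


def impute_mean(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP mean imputation of missing dosages."""
    d = np.array(dosage, float)
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    return d


def pca_covariates(geno: GenotypeMatrix, k: int = 5, scale: bool = False
                   ) -> np.ndarray:
    """Top-k principal-component scores of the centered genotype matrix."""
    if k >= geno.n_animals:
        raise ValueError("k must be smaller than the number of samples")
    if k == 0:
        return np.empty((geno.n_animals, 0))
    Z = impute_mean(geno.dosage)
    Z = Z - Z.mean(axis=0)
    if scale:
        sd = Z.std(axis=0)
        Z = Z / np.where(sd > 0, sd, 1.0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    return U[:, :k] * s[:k]


# ----------------------------------------------------------------------------
# per-SNP regression helpers


def _residualize(Q: np.ndarray, *arrays):
    """Project out the column space of Q from each array."""
    Qq, _ = np.linalg.qr(Q)
    return [a - Qq @ (Qq.T @ a) for a in arrays]


def _marker_tests(y_res: np.ndarray, G_res: np.ndarray, df: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized effect estimates and two-sided t-test p-values of each
    residualized marker column against the residualized phenotype."""
    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    ok = gg > 1e-12
    beta = np.zeros(G_res.shape[1])
    beta[ok] = gy[ok] / gg[ok]
    sse = float(y_res @ y_res) - beta**2 * gg
    sse = np.maximum(sse, 0.0)
    pvals = np.ones(G_res.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = sse / df
        tstat = np.where(ok & (sigma2 > 0), beta / np.sqrt(sigma2 / np.where(ok, gg, 1.0)), 0.0)
    exact = ok & (sigma2 <= 1e-300)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    pvals[exact] = np.nextafter(0, 1)  # perfect fit: below machine floor
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    return beta, pvals


def _result_frame(geno: GenotypeMatrix, beta, pvals, model: str,
                  threshold: float) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": geno.snp_ids, "chrom": geno.chrom, "pos": geno.pos,
        "effect": beta, "p": pvals, "model": model,
        "significant": pvals < threshold})


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Genome-wide threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ----------------------------------------------------------------------------
# GLM


def glm_scan(pheno: np.ndarray, geno: GenotypeMatrix,
             pcs: np.ndarray | None = None, alpha: float = 0.05) -> GwasResult:
    """Least-squares scan: y on [1, PCs, dosage], Wald t-test per SNP."""
    y = np.asarray(pheno, float)
    if len(y) != geno.n_animals:
        raise ValueError("phenotype and genotype sample counts differ")
    G = impute_mean(geno.dosage)
    Q = np.column_stack([np.ones(len(y))] +
                        ([pcs] if pcs is not None and pcs.size else []))
    y_res, G_res = _residualize(Q, y, G)
    df = len(y) - Q.shape[1] - 1
    beta, pvals = _marker_tests(y_res, G_res, df)
    thr = bonferroni_threshold(alpha, geno.n_snps)
    return GwasResult(_result_frame(geno, beta, pvals, "GLM", thr),
                      "GLM", thr, len(y))


# ----------------------------------------------------------------------------
# MLM (P3D / EMMA-style)


def _reml_delta(y: np.ndarray, Q: np.ndarray, lam: np.ndarray,
                yy0: float = 0.0, Qy0=None, QQ0=None, n: int | None = None):
    """Profile-REML over delta = se2/sg2 for V = sg2 (diag(lam) + delta I).

    ``y``, ``Q`` live in the eigenbasis of the kinship (possibly only its
    non-null part, with the complement summarized by yy0/Qy0/QQ0 and total
    sample size ``n``).  Returns (delta, sg2, -2 restricted loglik).
    """
    n = n if n is not None else len(y)
    p = Q.shape[1]
    n_rest = n - len(lam)
    Qy0 = Qy0 if Qy0 is not None else np.zeros(p)
    QQ0 = QQ0 if QQ0 is not None else np.zeros((p, p))

    def m2l(log_delta: float) -> float:
        d = np.exp(log_delta)
        w = 1.0 / (lam + d)
        A = (Q * w[:, None]).T @ Q + QQ0 / d
        b = Q.T @ (w * y) + Qy0 / d
        yy = float(y @ (w * y)) + yy0 / d
        sign, logdetA = np.linalg.slogdet(A)
        rss = yy - float(b @ np.linalg.solve(A, b))
        rss = max(rss, 1e-300)
        return ((n - p) * np.log(rss / (n - p))
                + float(np.sum(np.log(lam + d))) + n_rest * np.log(d)
                + logdetA)

    grid = np.linspace(-8, 8, 33)
    vals = [m2l(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(m2l, bounds=(g0 - 1.0, g0 + 1.0), method="bounded")
    delta = float(np.exp(res.x))
    w = 1.0 / (lam + delta)
    A = (Q * w[:, None]).T @ Q + QQ0 / delta
    b = Q.T @ (w * y) + Qy0 / delta
    yy = float(y @ (w * y)) + yy0 / delta
    rss = yy - float(b @ np.linalg.solve(A, b))
    sg2 = max(rss, 1e-300) / (n - p)
    return delta, sg2, float(res.fun)


def mlm_scan(pheno: np.ndarray, geno: GenotypeMatrix, pcs: np.ndarray | None,
             K: np.ndarray, alpha: float = 0.05) -> GwasResult:
    """Mixed-model scan with a polygenic kinship effect.

    (sg2, se2) are estimated once on the null model and reused for every
    SNP (the population-parameters-previously-determined shortcut); each
    marker is then tested by generalized least squares in the eigenbasis
    of K.
    """
    y = np.asarray(pheno, float)
    K = np.asarray(K, float)
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6 * max(lam.max(), 1.0):
        raise ValueError("kinship matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    G = impute_mean(geno.dosage)
    Q = np.column_stack([np.ones(len(y))] +
                        ([pcs] if pcs is not None and pcs.size else []))
    yr, Qr, Gr = U.T @ y, U.T @ Q, U.T @ G
    delta, sg2, _ = _reml_delta(yr, Qr, lam)
    w = np.sqrt(1.0 / (lam + delta))
    ys, Qs, Gs = yr * w, Qr * w[:, None], Gr * w[:, None]
    y_res, G_res = _residualize(Qs, ys, Gs)
    df = len(y) - Q.shape[1] - 1
    beta, pvals = _marker_tests(y_res, G_res, df)
    thr = bonferroni_threshold(alpha, geno.n_snps)
    res = GwasResult(_result_frame(geno, beta, pvals, "MLM", thr),
                     "MLM", thr, len(y))
    res.extra = {"sg2": sg2, "se2": sg2 * delta, "delta": delta}
    return res


# ----------------------------------------------------------------------------
# FarmCPU


def _fixed_scan(y: np.ndarray, G: np.ndarray, Q: np.ndarray,
                pseudo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect step: every SNP tested with PCs + pseudo-QTN covariates;
    a pseudo-QTN is tested with itself excluded from the covariates."""
    n = len(y)
    C = np.column_stack([Q, G[:, pseudo]]) if pseudo.size else Q
    df = n - C.shape[1] - 1
    y_res, G_res = _residualize(C, y, G)
    beta, pvals = _marker_tests(y_res, G_res, df)
    for j in pseudo:
        others = pseudo[pseudo != j]
        Cj = np.column_stack([Q, G[:, others]]) if others.size else Q
        yj, gj = _residualize(Cj, y, G[:, [j]])
        bj, pj = _marker_tests(yj, gj, n - Cj.shape[1] - 1)
        beta[j], pvals[j] = bj[0], pj[0]
    return beta, pvals


def _bin_representatives(pvals: np.ndarray, chrom: np.ndarray,
                         pos: np.ndarray, bin_size: float) -> np.ndarray:
    """Most significant SNP per (chrom, bin) in ascending p order."""
    codes = pd.factorize(chrom)[0].astype(np.int64)
    bins = codes * 10_000_000 + (pos // int(bin_size))
    order = np.argsort(pvals, kind="stable")
    seen: set = set()
    reps = []
    for j in order:
        b = bins[j]
        if b not in seen:
            seen.add(b)
            reps.append(j)
    return np.array(reps, dtype=int)


def _candidate_kinship_ll(y: np.ndarray, Q: np.ndarray, Gc: np.ndarray
                          ) -> float:
    """REML log-likelihood (up to a constant, negated -2LL returned as LL)
    of y = Qb + g + e with kinship built from the candidate SNP columns."""
    p = Gc.mean(axis=0) / 2.0
    d = 2.0 * float(np.sum(p * (1 - p)))
    if d <= 0:
        return -np.inf
    Z = (Gc - 2 * p) / np.sqrt(d)
    # low-rank eigen: nonzero spectrum from the thin SVD of Z
    U1, sv, _ = np.linalg.svd(Z, full_matrices=False)
    lam = sv**2
    keep = lam > 1e-10
    U1, lam = U1[:, keep], lam[keep]
    y1, Q1 = U1.T @ y, U1.T @ Q
    yy0 = float(y @ y) - float(y1 @ y1)
    Qy0 = Q.T @ y - Q1.T @ y1
    QQ0 = Q.T @ Q - Q1.T @ Q1
    _, _, m2l = _reml_delta(y1, Q1, lam, yy0=yy0, Qy0=Qy0, QQ0=QQ0, n=len(y))
    return -0.5 * m2l


def farmcpu_scan(pheno: np.ndarray, geno: GenotypeMatrix,
                 pcs: np.ndarray | None = None, max_loops: int = 10,
                 alpha: float = 0.05, qtn_threshold: float = 0.01,
                 bin_sizes=(5e5, 5e6, 5e7), qtn_counts=(2, 5, 10, 20)
                 ) -> GwasResult:
    """Fixed and random model Circulating Probability Unification scan."""
    y = np.asarray(pheno, float)
    G = impute_mean(geno.dosage)
    Q = np.column_stack([np.ones(len(y))] +
                        ([pcs] if pcs is not None and pcs.size else []))
    m = geno.n_snps
    thr = bonferroni_threshold(alpha, m)

    pseudo = np.array([], dtype=int)
    beta, pvals = _fixed_scan(y, G, Q, pseudo)
    # a pseudo-QTN keeps the p-value (and effect) from the iteration in
    # which it was first tested as a candidate; later loops do not ratchet it
    stored_p: dict[int, float] = {}
    stored_b: dict[int, float] = {}
    flagged = ""
    if pvals.min() > thr:
        flagged = "no SNP significant in the first iteration; GLM result"
    else:
        for _ in range(max_loops):
            rank_p = pvals.copy()
            for j, pj in stored_p.items():
                rank_p[j] = pj
            cand = np.where(rank_p < qtn_threshold)[0]
            if cand.size == 0:
                break
            best = (-np.inf, pseudo)
            for bs in bin_sizes:
                reps = _bin_representatives(rank_p, geno.chrom, geno.pos, bs)
                reps = reps[rank_p[reps] < qtn_threshold]
                for t in qtn_counts:
                    sel = reps[:t]
                    if sel.size == 0:
                        continue
                    ll = _candidate_kinship_ll(y, Q, G[:, sel])
                    if ll > best[0]:
                        best = (ll, sel)
            new_pseudo = np.sort(best[1])
            if np.array_equal(new_pseudo, np.sort(pseudo)):
                break
            pseudo = new_pseudo
            beta, pvals = _fixed_scan(y, G, Q, pseudo)
            for j in pseudo:
                stored_p.setdefault(int(j), float(pvals[j]))
                stored_b.setdefault(int(j), float(beta[j]))
        for j, pj in stored_p.items():
            pvals[j] = pj
            beta[j] = stored_b[j]

    res = GwasResult(_result_frame(geno, beta, pvals, "FarmCPU", thr),
                     "FarmCPU", thr, len(y), flagged=flagged)
    res.extra = {"pseudo_qtns": geno.snp_ids[pseudo].tolist()}
    return res


# ----------------------------------------------------------------------------
# annotation


@dataclass
class AnnotationRecord:
    snp: str
    region: str                  # exonic/intronic/upstream/downstream/intergenic/unknown
    genes: list[str] = field(default_factory=list)
    distances: list[int] = field(default_factory=list)

    def label(self) -> str:
        if self.region == "intergenic":
            parts = [f"{g} (dist = {d})" for g, d in zip(self.genes, self.distances)]
            return ", ".join(parts)
        return ", ".join(self.genes)


def annotate_snps(snps: pd.DataFrame, genes: pd.DataFrame,
                  upstream_window: int = 2000) -> list[AnnotationRecord]:
    """Positional gene annotation.

    ``snps``: columns snp, chrom, pos.  ``genes``: columns gene, chrom,
    start, end, strand and optionally ``exons`` ("s1-e1;s2-e2", 1-based
    inclusive).  Region priority: exonic > intronic > upstream >
    downstream > intergenic (flanking genes with distances); SNPs on
    chromosomes absent from the annotation are 'unknown'.
    """
    out = []
    genes = genes.copy()
    genes["chrom"] = genes["chrom"].astype(str)
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}
    for _, row in snps.iterrows():
        snp, chrom, pos = str(row["snp"]), str(row["chrom"]), int(row["pos"])
        tab = by_chrom.get(chrom)
        if tab is None or len(tab) == 0:
            out.append(AnnotationRecord(snp, "unknown"))
            continue
        rec = None
        inside = tab[(tab["start"] <= pos) & (pos <= tab["end"])]
        if len(inside):
            g = inside.iloc[0]
            region = "intronic"
            if isinstance(g.get("exons"), str) and g["exons"]:
                for ex in g["exons"].split(";"):
                    s, e = (int(v) for v in ex.split("-"))
                    if s <= pos <= e:
                        region = "exonic"
                        break
            rec = AnnotationRecord(snp, region, [str(g["gene"])])
        if rec is None:
            for _, g in tab.iterrows():
                tss = g["start"] if g["strand"] == "+" else g["end"]
                tes = g["end"] if g["strand"] == "+" else g["start"]
                up = (tss - upstream_window <= pos < g["start"]) \
                    if g["strand"] == "+" else (g["end"] < pos <= tss + upstream_window)
                down = (g["end"] < pos <= tes + upstream_window) \
                    if g["strand"] == "+" else (tes - upstream_window <= pos < g["start"])
                if up:
                    rec = AnnotationRecord(snp, "upstream", [str(g["gene"])],
                                           [abs(int(tss) - pos)])
                    break
                if down and rec is None:
                    rec = AnnotationRecord(snp, "downstream", [str(g["gene"])],
                                           [abs(int(tes) - pos)])
        if rec is None:
            left = tab[tab["end"] < pos]
            right = tab[tab["start"] > pos]
            gs, ds = [], []
            if len(left):
                g = left.iloc[-1]
                gs.append(str(g["gene"]))
                ds.append(int(pos - g["end"]))
            if len(right):
                g = right.iloc[0]
                gs.append(str(g["gene"]))
                ds.append(int(g["start"] - pos))
            rec = AnnotationRecord(snp, "intergenic", gs, ds)
        out.append(rec)
    return out


def export_qq(result: GwasResult, path) -> None:
    """Observed vs expected -log10 p (plain TSV, for QQ plots)."""
    p = np.sort(result.table["p"].to_numpy())
    exp = (np.arange(1, len(p) + 1) - 0.5) / len(p)
    pd.DataFrame({"expected_neglog10p": -np.log10(exp),
                  "observed_neglog10p": -np.log10(np.clip(p, 1e-300, 1.0))}
                 ).to_csv(path, sep="\t", index=False)
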