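"""Independent-herd validation of candidate SNPs.

Each candidate SNP is tested by one-way fixed-effects ANOVA of the trait
across the AA / AB / BB genotype classes, with Bonferroni correction over
the number of SNPs carried into validation (p_adj = min(1, p * m)).  The
per-class means are also ordered (e.g. "AA > AB > BB") and classified as
dosage-monotone or heterozygote-extreme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPE_CLASSES = ("AA", "AB", "BB")


@dataclass
class ValidationResult:
    snp: str
    class_stats: pd.DataFrame    # class, n, mean, sd
    f_stat: float
    p_raw: float
    p_bonferroni: float = np.nan
    ordering: str = ""
    pattern: str = ""
    stars: str = ""


def genotype_anova(values, classes, min_class_size: int = 2
                   ) -> tuple[float, float]:
    """One-way ANOVA F and p across the present genotype classes.

    Classes with fewer than ``min_class_size`` observations are dropped with
    a warning; with fewer than 2 usable classes the test is undefined and
    (nan, nan) is returned.
    """
    values = np.asarray(values, float)
    classes = np.asarray(classes)
    groups = []
    for g in pd.unique(classes):
        v = values[classes == g]
        v = v[np.isfinite(v)]
        if len(v) < min_class_size:
            warnings.warn(f"genotype class {g!r} has {len(v)} observations; dropped")
            continue
        groups.append(v)
    if len(groups) < 2:
        warnings.warn("fewer than 2 usable genotype classes; p undefined")
        return float("nan"), float("nan")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b, df_w = k - 1, n - k
    if ssw == 0:
        return float("inf"), 0.0 if ssb > 0 else 1.0
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))


def bonferroni_adjust(p_raw, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, p * m); m defaults to the list length."""
    p = np.asarray(p_raw, float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    return np.minimum(p * m, 1.0)


def effect_ordering(class_means: dict[str, float]) -> tuple[str, str]:
    """Classes sorted by mean descending ('AA > AB > BB'; ties use '=').

    The pattern note distinguishes dosage-monotone orderings (the
    heterozygote mean lies between the homozygotes) from
    heterozygote-extreme ones.
    """
    if len(class_means) < 2:
        raise ValueError("need at least 2 classes")
    items = sorted(class_means.items(), key=lambda kv: (-kv[1], kv[0]))
    parts = [items[0][0]]
    for (g_prev, m_prev), (g, m_cur) in zip(items, items[1:]):
        parts.append("=" if np.isclose(m_prev, m_cur) else ">")
        parts.append(g)
    ordering = " ".join(parts)
    pattern = ""
    if {"AA", "AB", "BB"} <= set(class_means):
        lo = min(class_means["AA"], class_means["BB"])
        hi = max(class_means["AA"], class_means["BB"])
        if lo <= class_means["AB"] <= hi:
            pattern = "monotone"
        else:
            pattern = "heterozygote-extreme"
    return ordering, pattern


def validate_snps(genotype_table: pd.DataFrame, trait_table: pd.DataFrame,
                  trait: str, m: int | None = None,
                  alpha: float = 0.05) -> list[ValidationResult]:
    """Run the genotype-class ANOVA for every SNP in the validation herd.

    ``genotype_table``: columns sample, snp, genotype (AA/AB/BB);
    ``trait_table``: columns sample and the trait.  ``m`` is the Bonferroni
    multiplier (defaults to the number of SNPs tested).
    """
    merged = genotype_table.merge(trait_table[["sample", trait]], on="sample")
    snps = list(pd.unique(merged["snp"]))
    if m is None:
        m = len(snps)
    results = []
    for snp in snps:
        sub = merged[merged["snp"] == snp]
        f, p = genotype_anova(sub[trait], sub["genotype"])
        cs = sub.groupby("genotype")[trait].agg(["count", "mean", "std"])
        cs = cs.rename(columns={"count": "n", "std": "sd"}).reset_index()
        padj = float(bonferroni_adjust([p], m)[0]) if np.isfinite(p) else np.nan
        means = {g: v for g, v in zip(cs["genotype"], cs["mean"])
                 if cs.loc[cs["genotype"] == g, "n"].iloc[0] >= 2}
        ordering, pattern = effect_ordering(means) if len(means) >= 2 else ("", "")
        stars = ""
        if np.isfinite(padj):
            if padj < 0.01:
                stars = "**"
            elif padj < alpha:
                stars = "*"
        results.append(ValidationResult(
            snp=str(snp), class_stats=cs, f_stat=f, p_raw=p,
            p_bonferroni=padj, ordering=ordering, pattern=pattern,
            stars=stars))
    return results


def validation_table(results: list[ValidationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"snp": r.snp, "F": r.f_stat, "p_raw": r.p_raw,
               "p_bonferroni": r.p_bonferroni, "ordering": r.ordering,
               "pattern": r.pattern, "stars": r.stars}
        for _, cs in r.class_stats.iterrows():
            g = cs["genotype"]
            row[f"n_{g}"] = cs["n"]
            row[f"mean_{g}"] = cs["mean"]
            row[f"sd_{g}"] = cs["sd"]
        rows.append(row)
    return pd.DataFrame(rows)
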