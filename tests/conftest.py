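"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately written with different algorithms than
the package (path-counting coancestry instead of the tabular method,
normal-equation least squares instead of PLS deflation, textbook
sums-of-squares ANOVA) so they can serve as cross-checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirfa.simdata import (SimConfig, simulate_genotypes, simulate_pedigree,
                           simulate_phenotypes)


# ----------------------------------------------------------------------------
# oracles


def kinship_oracle(animal, sire, dam):
    """Additive relationship matrix from recursive coancestry
    (f(i,j) = kinship; a_ij = 2 f(i,j)); independent of the tabular method."""
    idx = {int(a): k for k, a in enumerate(animal)}
    parents = {int(a): (int(s), int(d))
               for a, s, d in zip(animal, sire, dam)}
    order = {int(a): k for k, a in enumerate(animal)}
    cache: dict[tuple[int, int], float] = {}

    def f(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        si, di = parents[i]
        if i == j:
            val = 0.5 * (1.0 + f(si, di))
        else:
            val = 0.5 * (f(si, j) + f(di, j))
        cache[key] = val
        return val

    n = len(animal)
    A = np.empty((n, n))
    for i, ai in enumerate(animal):
        for j, aj in enumerate(animal):
            A[i, j] = 2.0 * f(int(ai), int(aj))
    return A


def ols_predictions(X, y):
    """Least squares via the normal equations (pinv), with intercept."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.pinv(Xc.T @ Xc) @ Xc.T @ y
    return Xc @ beta


def anova_oracle(groups):
    """Textbook one-way ANOVA from explicit sums of squares."""
    from scipy import stats

    groups = [np.asarray(g, float) for g in groups]
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    F = (ssb / (k - 1)) / (ssw / (n - k))
    return F, stats.f.sf(F, k - 1, n - k)


def anova_icc(records: pd.DataFrame, value_col="y", group_col="animal"):
    """Balanced one-way ANOVA moment estimator of the intraclass
    correlation (repeatability) of repeated records."""
    g = records.groupby(group_col)[value_col]
    counts = g.count()
    m = counts.iloc[0]
    assert (counts == m).all(), "oracle requires balanced records"
    k = len(counts)
    grand = records[value_col].mean()
    msb = m * ((g.mean() - grand) ** 2).sum() / (k - 1)
    msw = ((records[value_col] - g.transform("mean")) ** 2).sum() / (k * (m - 1))
    sb = (msb - msw) / m
    return sb / (sb + msw)


# ----------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_herd():
    """Small multi-generation herd with genotypes and repeated records."""
    cfg = SimConfig(n_founders=60, n_generations=2, matings_per_generation=120,
                    n_snps=300, n_qtn=3, records_per_cow=(2, 4), seed=42)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    records, truth = simulate_phenotypes(ped, geno, cfg)
    return {"cfg": cfg, "ped": ped, "geno": geno, "records": records,
            "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
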