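"""Fixed-effect correction of predicted test-day phenotypes.

The correction model for each trait is

    Y_ijkm = mu + P_i + L_j + S_k + HTD_m + e_ijkm

with parity P in 5 levels (1, 2, 3, 4, 5-10), lactation stage L in 12
30-day levels over days-in-milk 5-365, calving season S in 4 levels, and a
random herd-test-date contemporary-group effect.  Fixed effects use a
corner (first-level-zero) constraint; HTD and residual variances come from
the same REML engine as the animal model, with identity structure.

The corrected phenotype of a cow is the mean over her records of
Y - (mu + P + L + S): the random HTD prediction is deliberately not
subtracted — it is absorbed in the record residual and averages toward
zero across test dates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genparams import MixedModelFit, RandomTerm, aireml
from .simdata import season_of_month

N_LACT_LEVELS = 12


@dataclass
class CorrectionModel:
    trait: str
    mu: float
    parity_effects: dict[int, float]     # level -> effect, level 1 = 0
    lactation_effects: dict[int, float]  # level -> effect, level 1 = 0
    season_effects: dict[str, float]     # season -> effect, reference = 0
    htd_variance: float
    residual_variance: float
    htd_predictions: dict[str, float] = field(default_factory=dict)
    reference_season: str = ""


def assign_levels(parity, dim, calving_month):
    """(parity level 1-5, lactation level 1-12, season) for one record.

    Parity 5-10 collapses to level 5; lactation level is
    floor((DIM-5)/30)+1 clamped to 12 (DIM 365 would otherwise spill one
    day past bin 12).  Raises for inputs outside parity 1-10 / DIM 5-365.
    """
    parity = int(parity)
    dim = int(dim)
    if not 1 <= parity <= 10:
        raise ValueError(f"parity {parity} outside [1, 10]")
    if not 5 <= dim <= 365:
        raise ValueError(f"days in milk {dim} outside [5, 365]")
    parity_level = parity if parity <= 4 else 5
    lact_level = min((dim - 5) // 30 + 1, N_LACT_LEVELS)
    return parity_level, lact_level, season_of_month(int(calving_month))


def add_level_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized level assignment; records with DIM outside [5, 365] or
    parity outside [1, 10] are flagged (``level_ok``) and excluded by the
    fitting routines."""
    rec = records.copy()
    parity = rec["parity"].to_numpy(int)
    dim = rec["dim"].to_numpy(int)
    ok = (parity >= 1) & (parity <= 10) & (dim >= 5) & (dim <= 365)
    rec["level_ok"] = ok
    rec["parity_level"] = np.where(parity <= 4, parity, 5)
    rec["lact_level"] = np.minimum((dim - 5) // 30 + 1, N_LACT_LEVELS)
    if "season" not in rec.columns:
        rec["season"] = [season_of_month(m) for m in rec["calving_month"]]
    return rec


def fit_correction(records: pd.DataFrame, trait: str = "y",
                   htd_col: str = "htd") -> tuple[CorrectionModel,
                                                  MixedModelFit]:
    """REML fit of the correction model; returns estimated effects and the
    HTD/residual variances."""
    rec = records if "parity_level" in records.columns \
        else add_level_columns(records)
    if "level_ok" in rec.columns:
        n_bad = int((~rec["level_ok"]).sum())
        if n_bad:
            warnings.warn(f"excluding {n_bad} records outside parity/DIM range")
            rec = rec[rec["level_ok"]]
    y = rec[trait].to_numpy(float)
    n = len(rec)

    cols = [np.ones(n)]
    names = ["mu"]
    factors = {"parity_level": sorted(rec["parity_level"].unique()),
               "lact_level": sorted(rec["lact_level"].unique()),
               "season": sorted(rec["season"].unique())}
    for f, levels in factors.items():
        if len(levels) < 2:
            warnings.warn(f"factor {f} has a single observed level; dropped")
            continue
        for lev in levels[1:]:
            col = (rec[f] == lev).to_numpy(float)
            cols.append(col)
            names.append(f"{f}:{lev}")
    X = np.column_stack(cols)
    # drop perfectly aliased columns
    rank_keep = _independent_columns(X)
    dropped = [names[i] for i in range(X.shape[1]) if i not in rank_keep]
    if dropped:
        warnings.warn(f"dropping aliased fixed-effect columns: {dropped}")
        X = X[:, sorted(rank_keep)]
        names = [names[i] for i in sorted(rank_keep)]

    htd_levels = np.array(sorted(rec[htd_col].astype(str).unique()))
    hpos = {h: i for i, h in enumerate(htd_levels)}
    Z = np.zeros((n, len(htd_levels)))
    Z[np.arange(n), rec[htd_col].astype(str).map(hpos)] = 1.0
    fit = aireml(y, X, [RandomTerm("htd", Z, None, 0.0)])

    eff = dict(zip(names, fit.beta))
    parity_eff = {lev: 0.0 for lev in factors["parity_level"]}
    lact_eff = {lev: 0.0 for lev in factors["lact_level"]}
    season_eff = {lev: 0.0 for lev in factors["season"]}
    for name, v in eff.items():
        if name.startswith("parity_level:"):
            parity_eff[int(name.split(":")[1])] = float(v)
        elif name.startswith("lact_level:"):
            lact_eff[int(name.split(":")[1])] = float(v)
        elif name.startswith("season:"):
            season_eff[name.split(":", 1)[1]] = float(v)
    model = CorrectionModel(
        trait=trait, mu=float(eff["mu"]),
        parity_effects=parity_eff, lactation_effects=lact_eff,
        season_effects=season_eff,
        htd_variance=fit.variances["htd"],
        residual_variance=fit.variances["e"],
        htd_predictions=dict(zip(htd_levels, fit.effects["htd"])),
        reference_season=str(factors["season"][0]))
    return model, fit


def _independent_columns(X: np.ndarray) -> set[int]:
    """Greedy rank-revealing QR column selection."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return set(keep)


def corrected_phenotype(records: pd.DataFrame, model: CorrectionModel,
                        trait: str | None = None) -> pd.Series:
    """Per-cow corrected phenotype: mean over the cow's records of
    Y minus the estimated fixed part (mu + parity + lactation + season)."""
    trait = trait or model.trait
    rec = records if "parity_level" in records.columns \
        else add_level_columns(records)
    if "level_ok" in rec.columns:
        rec = rec[rec["level_ok"]]
    fixed = (model.mu
             + rec["parity_level"].map(model.parity_effects).fillna(0.0)
             + rec["lact_level"].map(model.lactation_effects).fillna(0.0)
             + rec["season"].map(model.season_effects).fillna(0.0))
    resid = rec[trait].astype(float) - fixed
    out = resid.groupby(rec["animal"]).mean()
    out.name = f"{trait}_corrected"
    return out
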