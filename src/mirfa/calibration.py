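"""PLSR calibration of fatty-acid traits from preprocessed FT-MIR spectra.

One model per trait: a two-pass derivative recipe, a characteristic-wave
subset, and a PLS1 regression with a small number of latent components
(8-10 by default).  Performance is summarized by the cross-validation and
test-set metrics

    RMSE = sqrt( sum (y - yhat)^2 / N )
    R^2  = 1 - sum (y - yhat)^2 / sum (y - ybar)^2
    RPD  = STD / RMSE

where STD is the population (denominator N) standard deviation of the
reference values, so that R^2 = 1 - 1/RPD^2 holds exactly on the same set.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import SpectrumSet, select_waves, stack_preprocess

RECIPES = ("D1+D1", "D2+D2", "D1+D2")


@dataclass
class ModelMetrics:
    r2_cv: float = np.nan
    rmse_cv: float = np.nan
    rpd_cv: float = np.nan
    r2_t: float = np.nan
    rmse_t: float = np.nan
    n_cv: int = 0
    n_t: int = 0


@dataclass
class CalibrationModel:
    """Fitted per-trait PLSR prediction model."""

    trait: str
    recipe: str
    wave_indices: np.ndarray
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray              # on centered X (selected waves)
    train_ids: np.ndarray = field(default_factory=lambda: np.array([]))
    metrics: ModelMetrics = field(default_factory=ModelMetrics)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict from an already preprocessed+subset design matrix."""
        return (X - self.x_mean) @ self.coef + self.y_mean

    def predict(self, s: SpectrumSet, window: int = 9, polyorder: int = 3
                ) -> np.ndarray:
        """Preprocess raw spectra with the stored recipe and predict."""
        sp = stack_preprocess(s, self.recipe, window=window, polyorder=polyorder)
        return self.predict_matrix(sp.absorbance[:, self.wave_indices])


# ----------------------------------------------------------------------------
# splitting


def split_train_test(sample_ids, fraction: float = 0.75, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Random, reproducible, disjoint and exhaustive train/test split."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    ids = np.asarray(sample_ids)
    if len(ids) < 8:
        raise ValueError("need at least 8 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    return ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]


def _fold_of(ids, k: int, seed: int) -> np.ndarray:
    """Fold assignment by hashing sample ids: invariant to sample order."""
    return np.array([zlib.crc32(f"{seed}:{i}".encode()) % k for i in ids])


# ----------------------------------------------------------------------------
# PLS1 (NIPALS)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int,
             trait: str = "", recipe: str = "",
             wave_indices: np.ndarray | None = None) -> CalibrationModel:
    """NIPALS PLS1: latent components maximizing covariance with the
    deflated response; returns centered-data coefficients plus intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] != len(y):
        raise ValueError("X row count must equal y length")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values are not allowed")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    n, m = Xd.shape
    a_max = min(n_components, n - 1, m)
    W = np.zeros((m, a_max))
    P = np.zeros((m, a_max))
    q = np.zeros(a_max)
    used = 0
    for a in range(a_max):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a] = w, p, qa
        used += 1
    if used == 0:
        coef = np.zeros(m)
    else:
        W, P, q = W[:, :used], P[:, :used], q[:used]
        coef = W @ np.linalg.solve(P.T @ W, q)
    if wave_indices is None:
        wave_indices = np.arange(m)
    return CalibrationModel(trait=trait, recipe=recipe,
                            wave_indices=np.asarray(wave_indices),
                            n_components=used, x_mean=x_mean, y_mean=y_mean,
                            coef=coef)


# ----------------------------------------------------------------------------
# metrics


def evaluate(y, yhat) -> tuple[float, float, float]:
    """(RMSE, R^2, RPD) with population-denominator STD."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst if sst > 0 else np.nan
    std = float(np.std(y))  # population denominator N
    rpd = std / rmse if rmse > 0 else float("inf")
    return rmse, r2, rpd


# ----------------------------------------------------------------------------
# cross-validation


def cross_validate(s: SpectrumSet, y: np.ndarray, recipe: str,
                   n_components: int, k: int = 10, seed: int = 0,
                   n_keep: int | None = 600,
                   windows=None) -> ModelMetrics:
    """k-fold CV with pooled out-of-fold predictions.

    Derivative preprocessing is per-sample and applied once; wave selection
    (target-dependent) is redone inside each training fold to keep the
    out-of-fold predictions honest.
    """
    y = np.asarray(y, float)
    if k > s.n_samples:
        raise ValueError("k cannot exceed the sample count")
    sp = stack_preprocess(s, recipe) if recipe else s
    folds = _fold_of(s.sample_ids, k, seed)
    yhat = np.full(len(y), np.nan)
    for f in range(k):
        test = folds == f
        if not test.any():
            continue
        train = ~test
        tr = sp.subset(train)
        if n_keep is not None and n_keep < sp.n_waves:
            waves = select_waves(tr, y[train], windows=windows, n_keep=n_keep)
        else:
            waves = np.arange(sp.n_waves)
        model = fit_plsr(tr.absorbance[:, waves], y[train], n_components)
        yhat[test] = model.predict_matrix(sp.absorbance[test][:, waves])
    ok = np.isfinite(yhat)
    rmse, r2, rpd = evaluate(y[ok], yhat[ok])
    return ModelMetrics(r2_cv=r2, rmse_cv=rmse, rpd_cv=rpd, n_cv=int(ok.sum()))


# ----------------------------------------------------------------------------
# model selection


def select_model(s: SpectrumSet, y: np.ndarray, trait: str = "",
                 recipes=RECIPES, components=(8, 9, 10),
                 n_keeps=(600,), k: int = 10, seed: int = 0,
                 test_spectra: SpectrumSet | None = None,
                 test_y: np.ndarray | None = None,
                 windows=None) -> CalibrationModel:
    """Grid search over recipe x component count x wave count, ranked by
    R^2_cv (ties: lower RMSE_cv, then fewer components); the winner is refit
    on all training samples and, if a held-out test set is supplied,
    evaluated on it exactly once."""
    candidates = [(rec, nc, nk) for rec in recipes for nc in components
                  for nk in n_keeps]
    if not candidates:
        raise ValueError("empty candidate grid")
    best = None
    for rec, nc, nk in candidates:
        m = cross_validate(s, y, rec, nc, k=k, seed=seed, n_keep=nk,
                           windows=windows)
        key = (-round(m.r2_cv, 12), round(m.rmse_cv, 12), nc, nk)
        if best is None or key < best[0]:
            best = (key, rec, nc, nk, m)
    _, rec, nc, nk, metrics = best
    sp = stack_preprocess(s, rec)
    if nk is not None and nk < sp.n_waves:
        waves = select_waves(sp, y, windows=windows, n_keep=nk)
    else:
        waves = np.arange(sp.n_waves)
    model = fit_plsr(sp.absorbance[:, waves], y, nc, trait=trait, recipe=rec,
                     wave_indices=waves)
    model.train_ids = np.asarray(s.sample_ids)
    model.metrics = metrics
    if test_spectra is not None and test_y is not None:
        yhat_t = model.predict(test_spectra)
        rmse_t, r2_t, _ = evaluate(test_y, yhat_t)
        model.metrics.rmse_t = rmse_t
        model.metrics.r2_t = r2_t
        model.metrics.n_t = len(test_y)
    return model


def predict_traits(models: list[CalibrationModel], s: SpectrumSet
                   ) -> pd.DataFrame:
    """Apply each trait model to raw spectra; one predicted column per trait."""
    out = pd.DataFrame({"sample_id": s.sample_ids})
    for model in models:
        if model.wave_indices.max() >= s.n_waves:
            raise ValueError("spectra grid does not match training grid")
        out[model.trait] = model.predict(s)
    return out


# ----------------------------------------------------------------------------
# model archive (JSON metadata + coefficient TSV, diffable)


def save_model(outdir, model: CalibrationModel) -> None:
    d = Path(outdir) / (model.trait or "trait")
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "trait": model.trait,
        "recipe": model.recipe,
        "n_components": model.n_components,
        "y_mean": model.y_mean,
        "metrics": vars(model.metrics),
        "train_ids": [str(i) for i in model.train_ids],
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame({"wave_index": model.wave_indices, "x_mean": model.x_mean,
                  "coef": model.coef}).to_csv(d / "coefficients.tsv",
                                              sep="\t", index=False)


def load_model(trait_dir) -> CalibrationModel:
    d = Path(trait_dir)
    meta = json.loads((d / "model.json").read_text())
    tab = pd.read_csv(d / "coefficients.tsv", sep="\t")
    mm = ModelMetrics(**meta["metrics"])
    return CalibrationModel(
        trait=meta["trait"], recipe=meta["recipe"],
        wave_indices=tab["wave_index"].to_numpy(int),
        n_components=meta["n_components"],
        x_mean=tab["x_mean"].to_numpy(float), y_mean=meta["y_mean"],
        coef=tab["coef"].to_numpy(float),
        train_ids=np.array(meta["train_ids"]), metrics=mm)
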