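"""FT-MIR spectra: container, derivative preprocessing, wave selection and QC.

A milk spectrum is 1060 absorbances on the 925.66-5010.15 cm^-1 grid.
Preprocessing is one or two Savitzky-Golay derivative passes (D1/D2) applied
with respect to the grid index (the grid is uniform).  Sample-level QC
combines composition bounds (fat, protein, SCC), a duplicate-measurement
relative-error rule and the GH statistic: the squared Mahalanobis distance
of a sample's PCA scores from the calibration-set centroid divided by the
number of components, with GH <= 3 retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .simdata import N_WAVES

VALID_TAGS = {"raw", "D1", "D2", "D1+D1", "D1+D2", "D2+D2"}


@dataclass
class SpectrumSet:
    """Wavenumber grid + absorbance matrix + sample ids + preprocessing tag."""

    wavenumbers: np.ndarray          # ascending, cm^-1
    absorbance: np.ndarray           # samples x waves
    sample_ids: np.ndarray
    tag: str = "raw"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, float))
        self.sample_ids = np.asarray(self.sample_ids)
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.absorbance.shape != (len(self.sample_ids), len(self.wavenumbers)):
            raise ValueError("absorbance shape does not match ids x wavenumbers")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_waves(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, mask: np.ndarray) -> "SpectrumSet":
        return SpectrumSet(self.wavenumbers, self.absorbance[mask],
                           self.sample_ids[mask], self.tag)


@dataclass
class QCRule:
    """Sample-screening bounds; each rule can be toggled off with None."""

    fat_range: tuple[float, float] | None = (1.5, 9.0)
    protein_range: tuple[float, float] | None = (1.0, 7.0)
    scc_max: float | None = 1_000_000.0
    duplicate_rel_error_max: float | None = 0.10
    gh_max: float | None = 3.0


# ----------------------------------------------------------------------------
# preprocessing


def sg_derivative(s: SpectrumSet, order: int, window: int = 9,
                  polyorder: int = 3) -> SpectrumSet:
    """Savitzky-Golay derivative of each spectrum w.r.t. grid index."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    deriv = savgol_filter(s.absorbance, window_length=window,
                          polyorder=polyorder, deriv=order, delta=1.0, axis=1)
    tag = f"D{order}" if s.tag == "raw" else f"{s.tag}+D{order}"
    return replace(s, absorbance=deriv, tag=tag)


def stack_preprocess(s: SpectrumSet, recipe: str, window: int = 9,
                     polyorder: int = 3) -> SpectrumSet:
    """Apply a two-pass derivative recipe ('D1+D1', 'D2+D2' or 'D1+D2')."""
    if recipe not in ("D1+D1", "D2+D2", "D1+D2"):
        raise ValueError(f"unknown preprocessing recipe {recipe!r}")
    out = s
    for token in recipe.split("+"):
        out = sg_derivative(out, order=int(token[1]), window=window,
                            polyorder=polyorder)
    return out


# ----------------------------------------------------------------------------
# wave selection


def select_waves(s: SpectrumSet, target: np.ndarray,
                 windows: list[tuple[float, float]] | None = None,
                 n_keep: int = 600) -> np.ndarray:
    """Deterministic characteristic-wave selection.

    Within the union of the wavenumber ``windows`` (whole grid by default;
    the water bands are deliberately not excluded), waves are ranked by
    absolute Pearson correlation with ``target`` and the top ``n_keep``
    kept; ties break toward the lower wavenumber.  Returns sorted indices.
    """
    target = np.asarray(target, float)
    if len(target) != s.n_samples:
        raise ValueError("target length must equal sample count")
    if windows is None:
        candidate = np.arange(s.n_waves)
    else:
        mask = np.zeros(s.n_waves, bool)
        for lo, hi in windows:
            mask |= (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
        candidate = np.where(mask)[0]
    if n_keep > candidate.size:
        raise ValueError("n_keep exceeds number of candidate waves")
    X = s.absorbance[:, candidate]
    Xc = X - X.mean(axis=0)
    tc = target - target.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(Xc.T @ tc) / (sx * st)
    r[~np.isfinite(r)] = 0.0  # zero-variance columns get correlation 0
    # stable sort on (-|r|, index): ties break toward lower wavenumber
    order = np.lexsort((candidate, -r))
    return np.sort(candidate[order[:n_keep]])


# ----------------------------------------------------------------------------
# GH outlier filter


def gh_filter(s: SpectrumSet, n_components: int = 10, threshold: float = 3.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Standardized Mahalanobis (GH) outlier statistic in PCA-score space.

    The spectra are projected on the leading ``n_components`` principal
    components fitted on the same set; GH_i is the squared Mahalanobis
    distance of sample i's scores from their centroid, divided by
    ``n_components`` so that the average GH is about 1.  Returns
    ``(gh_values, keep_mask)`` with ``keep = GH <= threshold``.
    """
    if s.n_samples < n_components + 2:
        raise ValueError("need at least n_components + 2 samples")
    X = s.absorbance - s.absorbance.mean(axis=0)
    # scores via thin SVD
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * sv[:n_components]
    S = np.cov(scores, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular score covariance; ridge-regularizing")
        Sinv = np.linalg.inv(S + 1e-8 * np.trace(S) / len(S) * np.eye(len(S)))
    d = scores - scores.mean(axis=0)
    gh = np.einsum("ij,jk,ik->i", d, Sinv, d) / n_components
    return gh, gh <= threshold


# ----------------------------------------------------------------------------
# record-level QC


def qc_records(records: pd.DataFrame, rules: QCRule
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the sample-screening rules; returns (kept, rejection log).

    The rejection log has one row per (sample, violated rule).  A sample is
    kept iff it violates no enabled rule, so kept + rejected = input.
    """
    def need(col: str, rule: str) -> pd.Series:
        if col not in records.columns:
            raise KeyError(f"QC rule {rule!r} requires missing column {col!r}")
        return records[col]

    bad = pd.Series(False, index=records.index)
    log_rows = []

    def apply_rule(name: str, mask: pd.Series, value: pd.Series, bound: str):
        nonlocal bad
        for i in records.index[mask.fillna(False)]:
            log_rows.append((records.loc[i].get("sample_id", i), name,
                             value.loc[i], bound))
        bad |= mask.fillna(False)

    if rules.fat_range is not None:
        v = need("fat_pct", "fat")
        lo, hi = rules.fat_range
        apply_rule("fat", (v < lo) | (v > hi), v, f"[{lo}, {hi}]")
    if rules.protein_range is not None:
        v = need("protein_pct", "protein")
        lo, hi = rules.protein_range
        apply_rule("protein", (v < lo) | (v > hi), v, f"[{lo}, {hi}]")
    if rules.scc_max is not None:
        v = need("scc", "scc")
        apply_rule("scc", v > rules.scc_max, v, f"<= {rules.scc_max:g}")
    if rules.duplicate_rel_error_max is not None:
        m1 = need("dup1", "duplicate")
        m2 = need("dup2", "duplicate")
        rel = duplicate_relative_error(m1, m2)
        apply_rule("duplicate", rel > rules.duplicate_rel_error_max, rel,
                   f"<= {rules.duplicate_rel_error_max:g}")
    if rules.gh_max is not None and "gh" in records.columns:
        v = records["gh"]
        apply_rule("gh", v > rules.gh_max, v, f"<= {rules.gh_max:g}")

    log = pd.DataFrame(log_rows, columns=["sample_id", "rule", "value", "bound"])
    return records[~bad].copy(), log


def duplicate_relative_error(m1, m2):
    """|m1 - m2| / mean(m1, m2)."""
    m1 = pd.Series(np.asarray(m1, float))
    m2 = pd.Series(np.asarray(m2, float))
    return (m1 - m2).abs() / ((m1 + m2) / 2.0)


# ----------------------------------------------------------------------------
# IO


def write_spectra_csv(path, s: SpectrumSet) -> None:
    """CSV with sample_id then one column per wavenumber (2-decimal cm^-1)."""
    df = pd.DataFrame(s.absorbance,
                      columns=[f"{w:.2f}" for w in s.wavenumbers])
    df.insert(0, "sample_id", s.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path, strict: bool = True) -> SpectrumSet:
    df = pd.read_csv(path)
    wav = np.array([float(c) for c in df.columns[1:]])
    if strict and len(wav) != N_WAVES:
        raise ValueError(f"expected {N_WAVES} wavenumber columns, got {len(wav)}")
    return SpectrumSet(wavenumbers=wav,
                       absorbance=df.iloc[:, 1:].to_numpy(float),
                       sample_ids=df.iloc[:, 0].to_numpy())
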