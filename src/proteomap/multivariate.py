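"""Multivariate layer: PCA, linear regression, and normality via PPCC.

PCA is computed by singular-value decomposition of the column-centered
(optionally unit-variance-scaled) data matrix and reports scores, loadings,
explained-variance fractions, per-sample leverage (the diagonal of the hat
matrix over the kept score space, i.e. Hotelling-style influence) and per
sample Q residuals (squared reconstruction error) — the quantities shown on
chemometric score/loading/influence plots.

The PPCC (normal probability plot correlation coefficient) is the Pearson
correlation between the ordered sample and normal quantiles at Blom plotting
positions (i − 0.375)/(n + 0.25); values near 1 indicate normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PCAResult", "RegressionResult", "pca", "linreg", "ppcc",
           "species_feature_matrix"]


@dataclass
class PCAResult:
    scores: np.ndarray             # samples × components
    loadings: np.ndarray           # variables × components
    explained_variance: np.ndarray  # fraction of total variance per component
    leverage: np.ndarray           # per-sample
    q_residuals: np.ndarray        # per-sample squared reconstruction error
    centered: bool
    scaled: bool
    mean_: np.ndarray
    scale_: np.ndarray


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    n: int


def pca(X: np.ndarray, center: bool = True, scale: bool = False,
        k: int | None = None) -> PCAResult:
    """Principal component analysis via SVD.

    Component signs are fixed so each loading vector's largest-magnitude entry
    is positive, making the decomposition deterministic.  A constant column
    with ``scale=True`` is an error (its variance is zero).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("X must be a matrix with >=2 samples and >=2 variables")
    n, p = X.shape
    if k is None:
        k = min(n - 1, p)
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k={k} out of range for a {n}x{p} matrix")

    mean = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1) if center else X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(f"constant column(s) {zero.tolist()} cannot be scaled")
        scale_ = sd
    else:
        scale_ = np.ones(p)
    Z = Xc / scale_

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total_var = float((s ** 2).sum())
    # Deterministic sign: largest-|loading| entry of each component positive.
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0

    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)

    # Scores are orthogonal, so T(TᵀT)⁻¹Tᵀ has diagonal Σ_k t_ik² / Σ_i t_ik².
    with np.errstate(invalid="ignore", divide="ignore"):
        col_ss = (scores ** 2).sum(axis=0)
        lev_terms = np.where(col_ss > 0, scores ** 2 / col_ss, 0.0)
    leverage = lev_terms.sum(axis=1)

    recon = scores @ loadings.T
    q = ((Z - recon) ** 2).sum(axis=1)

    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance=explained, leverage=leverage,
                     q_residuals=q, centered=center, scaled=scale,
                     mean_=mean, scale_=scale_)


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(fit.rvalue), r_squared=float(fit.rvalue) ** 2,
                            n=int(x.size))


def ppcc(sample) -> float:
    """Normal probability plot correlation coefficient (Blom positions)."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 10:
        raise ValueError("need n >= 10 for a stable PPCC")
    if np.ptp(x) == 0:
        raise ValueError("constant sample; PPCC undefined")
    i = np.arange(1, n + 1)
    q = stats.norm.ppf((i - 0.375) / (n + 0.25))
    r, _ = stats.pearsonr(x, q)
    return float(r)


def species_feature_matrix(species_frame: pd.DataFrame,
                           include_composition: bool = True) -> tuple[np.ndarray, list[str], list[str]]:
    """Feature matrix for species-level PCA.

    Rows are species; columns are the pI-class percentages (acidic / basic /
    neutral) and, optionally, the 20-residue composition percentages.  Returns
    (X, sample_labels, variable_names).
    """
    cols = ["pct_acidic", "pct_basic", "pct_neutral"]
    if include_composition:
        cols += [c for c in species_frame.columns
                 if c.startswith("pct_") and len(c) == 5 and c[4].isalpha()
                 and c[4].isupper()]
    X = species_frame[cols].to_numpy(dtype=float)
    return X, species_frame["species"].astype(str).tolist(), cols
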