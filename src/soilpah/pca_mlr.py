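"""PCA source identification with varimax rotation and MLR apportionment.

Compound concentrations are standardized to z-scores, principal components
with eigenvalue > 1 are retained (the Kaiser criterion), and the loading
matrix (eigenvectors scaled by sqrt(eigenvalue)) is varimax-rotated for
interpretability. The per-sample total PAH concentration, standardized, is
then regressed on the rotated component scores; each component's share of the
total is its regression coefficient divided by the sum of the positive
coefficients (negative coefficients contribute zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .concentrations import ConcentrationMatrix

__all__ = ["PCAResult", "run_pca", "apportion_mlr", "pca_mlr_table"]

BOLD_LOADING = 0.50  # |loading| at or above this is reported as a defining compound


@dataclass
class PCAResult:
    """Retained, rotated principal components of a standardized PAH matrix."""

    n_components: int
    loadings: pd.DataFrame  # compounds x PCs, varimax-rotated
    eigenvalues: np.ndarray  # all eigenvalues of the correlation matrix
    variance_fraction: np.ndarray  # per retained PC, of total variance
    cumulative_variance: np.ndarray
    scores: np.ndarray  # samples x retained PCs
    rotation_matrix: np.ndarray | None = None  # orthogonal varimax rotation T
    unrotated_loadings: np.ndarray | None = None
    dropped_compounds: list[str] = field(default_factory=list)
    mlr_coefficients: np.ndarray | None = None
    contribution_fractions: np.ndarray | None = None


def run_pca(matrix: ConcentrationMatrix, eigenvalue_cutoff: float = 1.0) -> PCAResult:
    """Retain eigenvalue > cutoff components of the correlation matrix, varimax-rotated.

    Constant compounds are dropped with a warning (their correlation is
    undefined). Each rotated component is sign-flipped so its largest-magnitude
    loading is positive.
    """
    X = matrix.values
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    names = list(matrix.catalog.abbreviations)

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant compound column(s): {dropped}")
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]

    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    n_keep = int((eigvals > eigenvalue_cutoff).sum())
    if n_keep == 0:
        raise ValueError("no principal component exceeds the eigenvalue cutoff")
    L = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])

    if n_keep > 1:
        L_rot, T = rotate_factors(L, "varimax")
    else:
        L_rot, T = L.copy(), np.eye(1)
    # sign convention: largest-|loading| positive per component
    signs = np.array([-1.0 if L_rot[np.argmax(np.abs(L_rot[:, k])), k] < 0 else 1.0 for k in range(n_keep)])
    L_rot = L_rot * signs
    T = T * signs

    # variance share per rotated component = its sum of squared loadings / m
    ssq = (L_rot**2).sum(axis=0)
    order_rot = np.argsort(ssq)[::-1]
    L_rot = L_rot[:, order_rot]
    T = T[:, order_rot]
    ssq = ssq[order_rot]
    m = len(names)
    variance_fraction = ssq / m

    # regression-method component scores (unit variance, mutually uncorrelated
    # up to rotation): Z L (L'L)^-1
    scores = Z @ L_rot @ np.linalg.inv(L_rot.T @ L_rot)

    return PCAResult(
        n_components=n_keep,
        loadings=pd.DataFrame(L_rot, index=names, columns=[f"PC{k + 1}" for k in range(n_keep)]),
        eigenvalues=eigvals,
        variance_fraction=variance_fraction,
        cumulative_variance=np.cumsum(variance_fraction),
        scores=scores,
        rotation_matrix=T,
        unrotated_loadings=L,
        dropped_compounds=dropped,
    )


def apportion_mlr(result: PCAResult, totals: np.ndarray) -> np.ndarray:
    """Apportion total PAHs to components by regressing standardized totals on scores.

    Components with non-positive coefficients get a zero share; the remaining
    coefficients are renormalized to sum to one. Raises if every coefficient
    is non-positive. The coefficients and fractions are stored on ``result``.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.shape[0] != result.scores.shape[0]:
        raise ValueError("totals and component scores must be aligned by sample")
    z_tot = (totals - totals.mean()) / totals.std(ddof=1)
    design = np.column_stack([np.ones_like(z_tot), result.scores])
    coef, *_ = np.linalg.lstsq(design, z_tot, rcond=None)
    b = coef[1:]
    positive = np.clip(b, 0.0, None)
    if positive.sum() <= 0:
        raise ValueError("apportionment undefined: no component has a positive coefficient")
    fractions = positive / positive.sum()
    result.mlr_coefficients = b
    result.contribution_fractions = fractions
    return fractions


def pca_mlr_table(result: PCAResult) -> pd.DataFrame:
    """Loadings/eigenvalues/variance/contributions in reporting layout."""
    table = result.loadings.copy()
    extra = pd.DataFrame(
        {
            col: [
                result.eigenvalues[k],
                100 * result.variance_fraction[k],
                100 * result.cumulative_variance[k],
                result.contribution_fractions[k] if result.contribution_fractions is not None else np.nan,
            ]
            for k, col in enumerate(table.columns)
        },
        index=["Eigenvalue", "Variance %", "Cumulative variance %", "Contribution"],
    )
    return pd.concat([table, extra])
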