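"""Voxel-wise GLM against the HRF design and per-subject FDR thresholding.

Ordinary least squares per voxel against the stimulus regressors plus drift
terms; t and two-sided p per predictor against zero; Benjamini-Hochberg
step-up control of the false-discovery rate at the subject level, per
predictor, within the brain mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .paradigm import DesignMatrix
from .preprocess import VolumeSeries

__all__ = ["GLMResult", "ActivationMask", "fit_glm", "fdr_threshold", "activation_mask"]


@dataclass
class GLMResult:
    """Per-voxel betas, t statistics and two-sided p values per predictor.

    Maps are stored flattened as (n_voxels, n_predictors); ``shape`` holds
    the spatial grid for reshaping. Voxels with zero residual variance are
    flagged (t and p set to NaN).
    """

    betas: np.ndarray
    tvals: np.ndarray
    pvals: np.ndarray
    resid_var: np.ndarray
    columns: tuple[str, ...]
    stim_columns: tuple[str, ...]
    shape: tuple[int, int, int]
    dof: int

    def map(self, which: str, predictor: str) -> np.ndarray:
        """3D map of ``which`` in {"beta", "t", "p"} for one predictor."""
        arr = {"beta": self.betas, "t": self.tvals, "p": self.pvals}[which]
        return arr[:, self.columns.index(predictor)].reshape(self.shape)


@dataclass
class ActivationMask:
    """Boolean masks of significantly activated voxels, one per predictor."""

    masks: dict[str, np.ndarray]
    q: float

    def mask(self, predictor: str) -> np.ndarray:
        return self.masks[predictor]


def fit_glm(series: VolumeSeries, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per voxel.

    Requires design rows = number of volumes and full column rank; a
    rank-deficient design is rejected naming the collinear columns.
    """
    X = design.matrix
    t, k = X.shape
    if t != series.n_volumes:
        raise ValueError(
            f"design has {t} rows but the series has {series.n_volumes} volumes"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, r = np.linalg.qr(X)
        d = np.abs(np.diag(r))
        bad = [design.columns[i] for i in np.where(d < d.max() * 1e-10)[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = series.data.reshape(-1, t).T  # (t, V)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = t - k
    rss = np.einsum("tv,tv->v", resid, resid)
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # (k, V)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return GLMResult(
        betas=beta.T,
        tvals=tvals.T,
        pvals=pvals.T,
        resid_var=sigma2,
        columns=design.columns,
        stim_columns=design.stim_columns,
        shape=series.data.shape[:3],
        dof=dof,
    )


def fdr_threshold(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over one subject/predictor's p values.

    Returns a boolean rejection mask aligned with the input; NaN entries are
    never rejected.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    out = np.zeros(p.size, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return out


def activation_mask(
    glm: GLMResult,
    predictor: str,
    q: float = 0.05,
    brain_mask: np.ndarray | None = None,
) -> ActivationMask:
    """FDR-threshold one predictor's p map within the brain mask."""
    if predictor not in glm.columns:
        raise KeyError(f"unknown predictor {predictor!r}")
    p = glm.map("p", predictor)
    if brain_mask is None:
        brain_mask = np.ones(glm.shape, dtype=bool)
    mask = np.zeros(glm.shape, dtype=bool)
    mask[brain_mask] = fdr_threshold(p[brain_mask], q)
    return ActivationMask(masks={predictor: mask}, q=q)
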