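"""PCA and PLS views of the proteome with trait-variance accounting.

Both decompositions operate on complete-case entries only (entries with no
missing level in any line/sex sample), centered per entry and unscaled by
default. PCA summarizes proteome variance; single-response PLS (NIPALS, as
in sklearn's PLSRegression) extracts components that maximize covariance
with a wing-size trait, and is the view used to order samples by size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

__all__ = ["LatentProjection", "pca_complete", "pls_fit", "correlation_loadings"]


@dataclass
class LatentProjection:
    """Scores/loadings of a latent decomposition of the level matrix."""

    method: str  # "PCA" or "PLS"
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # entries x components
    explained_variance: np.ndarray  # fraction of matrix variance per component
    trait_variance: np.ndarray | None = None  # fraction of trait variance (PLS / PCA-vs-trait)

    @property
    def cumulative_trait_variance(self) -> np.ndarray | None:
        return None if self.trait_variance is None else np.cumsum(self.trait_variance)


def _complete_cases(levels: pd.DataFrame) -> pd.DataFrame:
    return levels.dropna(axis=0)


def _trait_r2_per_component(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fraction of trait variance explained by components 1..k, incremental."""
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    r2 = []
    prev = 0.0
    for k in range(1, scores.shape[1] + 1):
        X = np.column_stack([np.ones(len(y)), scores[:, :k]])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        cur = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        r2.append(cur - prev)
        prev = cur
    return np.asarray(r2)


def _orient(scores: np.ndarray, loadings: np.ndarray, y: np.ndarray | None) -> None:
    """Flip component signs in place toward positive correlation with y."""
    if y is None:
        return
    yc = y - y.mean()
    for k in range(scores.shape[1]):
        if np.dot(scores[:, k] - scores[:, k].mean(), yc) < 0:
            scores[:, k] *= -1.0
            loadings[:, k] *= -1.0


def pca_complete(
    levels: pd.DataFrame,
    trait: pd.Series | None = None,
    n_components: int | None = None,
) -> LatentProjection:
    """Centered PCA on the complete-case entries.

    Rows of ``levels`` are entries, columns line/sex samples. If ``trait``
    is given, component signs are fixed so each score correlates
    non-negatively with the trait, and the fraction of trait variance
    explained by the leading components (via OLS on the scores) is reported.
    """
    cc = _complete_cases(levels)
    if cc.shape[0] < 2:
        raise ValueError("need at least 2 complete-case entries")
    if cc.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = cc.to_numpy(dtype=float).T  # samples x entries
    X = X - X.mean(axis=0)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    y = None
    if trait is not None:
        y = trait.reindex(cc.columns).to_numpy(dtype=float)
    _orient(scores, loadings, y)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return LatentProjection(
        method="PCA",
        scores=pd.DataFrame(scores, index=cc.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=cc.index, columns=comp_names),
        explained_variance=pca.explained_variance_ratio_,
        trait_variance=None if y is None else _trait_r2_per_component(scores, y),
    )


def pls_fit(
    levels: pd.DataFrame,
    trait: pd.Series,
    n_components: int = 2,
    scale: bool = False,
) -> LatentProjection:
    """Single-response PLS regression of a size trait on the proteome.

    Reports, per component, the fraction of trait variance explained
    (incremental R^2 of the trait on the leading scores) and of matrix
    variance. Components are sign-fixed to correlate positively with the
    trait. ``n_components`` beyond the matrix rank is truncated with a
    warning.
    """
    cc = _complete_cases(levels)
    if cc.shape[0] < 2:
        raise ValueError("need at least 2 complete-case entries")
    y = trait.reindex(cc.columns).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait missing for some samples")
    X = cc.to_numpy(dtype=float).T
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = n_components
    if k > rank:
        warnings.warn(f"n_components={n_components} exceeds matrix rank {rank}; truncating")
        k = rank
    pls = PLSRegression(n_components=k, scale=scale)
    pls.fit(X, y)
    scores = pls.x_scores_.copy()
    loadings = pls.x_loadings_.copy()
    _orient(scores, loadings, y)
    Xc = X - X.mean(axis=0)
    total_var = float((Xc**2).sum())
    x_var = np.array(
        [
            float((np.outer(scores[:, j], loadings[:, j]) ** 2).sum()) / total_var
            if total_var > 0
            else 0.0
            for j in range(k)
        ]
    )
    comp_names = [f"PLS{i + 1}" for i in range(k)]
    return LatentProjection(
        method="PLS",
        scores=pd.DataFrame(scores, index=cc.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=cc.index, columns=comp_names),
        explained_variance=x_var,
        trait_variance=_trait_r2_per_component(scores, y),
    )


def correlation_loadings(levels: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each entry's profile with each component score.

    Constant entries get NaN correlations (flagged via the result itself).
    """
    cols = list(scores.index)
    lv = levels[cols].to_numpy(dtype=float)
    sc = scores.to_numpy(dtype=float)
    out = np.full((lv.shape[0], sc.shape[1]), np.nan)
    sc_c = sc - sc.mean(axis=0)
    sc_norm = np.sqrt((sc_c**2).sum(axis=0))
    for i in range(lv.shape[0]):
        x = lv[i]
        mask = ~np.isnan(x)
        if mask.sum() < 3:
            continue
        xc = x[mask] - x[mask].mean()
        xn = np.sqrt((xc**2).sum())
        if xn == 0:
            continue
        if mask.all():
            out[i] = (xc @ sc_c) / (xn * sc_norm)
        else:
            s = sc[mask] - sc[mask].mean(axis=0)
            sn = np.sqrt((s**2).sum(axis=0))
            out[i] = (xc @ s) / (xn * sn)
    return pd.DataFrame(out, index=levels.index, columns=scores.columns)
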