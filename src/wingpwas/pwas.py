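"""Proteome-wide association scan of protein entry levels against wing size.

Two per-entry linear models are scanned across all quantified entries:

* relative CS = sex + protein level (log2) + e
* absolute CS = protein level (log2) + e   (sex dimorphism kept in the trait)

The protein slope's two-sided t-test p-value is corrected across entries by
the Benjamini-Hochberg step-up procedure. A sex x protein interaction check
accompanies the relative-CS model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["bh_adjust", "pwas_scan", "interaction_check"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, returned in the input
    order. NaNs propagate and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(ranked, 1.0)
        q[ok] = qv
    return q


def _slope_test(y: np.ndarray, X: np.ndarray, j: int) -> tuple[float, float]:
    """Two-sided t-test for coefficient ``j`` of y = X b + e."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k or n <= k:
        return np.nan, np.nan
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    if rss <= 0:
        return float(coef[j]), 0.0 if coef[j] != 0 else np.nan
    se = np.sqrt(rss / df * xtx_inv[j, j])
    t = coef[j] / se
    return float(coef[j]), float(2.0 * stats.t.sf(abs(t), df))


def _male_indicator(columns) -> np.ndarray:
    return np.array([1.0 if c.rsplit("_", 1)[1] == "M" else 0.0 for c in columns])


def pwas_scan(
    levels: pd.DataFrame,
    trait: pd.Series,
    model: str = "relative",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Associate every protein entry with a wing-size trait.

    Parameters
    ----------
    levels : DataFrame
        Entries x line_sex log2 levels (columns named ``<line>_<F|M>``).
    trait : Series
        Trait value per line_sex, indexed like the level columns.
    model : {"relative", "absolute"}
        "relative" includes a sex covariate; "absolute" is a simple
        regression (the trait itself carries the sex dimorphism).
    fdr : float
        BH threshold for the significance flag.

    Each entry is fit on its complete (level, trait) pairs; entries with a
    constant level are flagged and excluded from the BH correction.
    """
    if model not in ("relative", "absolute"):
        raise ValueError("model must be 'relative' or 'absolute'")
    cols = [c for c in levels.columns if c in trait.index]
    if len(cols) < 3:
        raise ValueError("need at least 3 samples with trait values")
    y_all = trait.reindex(cols).to_numpy(dtype=float)
    male = _male_indicator(cols)
    lv = levels[cols].to_numpy(dtype=float)

    rows = []
    for i, entry in enumerate(levels.index):
        x = lv[i]
        mask = ~np.isnan(x) & ~np.isnan(y_all)
        n = int(mask.sum())
        if n < 3 or np.ptp(x[mask]) == 0:
            rows.append({"entry_id": entry, "n": n, "slope": np.nan, "p": np.nan, "flagged": True})
            continue
        if model == "relative":
            if len(np.unique(male[mask])) < 2:
                rows.append({"entry_id": entry, "n": n, "slope": np.nan, "p": np.nan, "flagged": True})
                continue
            X = np.column_stack([np.ones(n), male[mask], x[mask]])
            slope, p = _slope_test(y_all[mask], X, 2)
        else:
            X = np.column_stack([np.ones(n), x[mask]])
            slope, p = _slope_test(y_all[mask], X, 1)
        rows.append({"entry_id": entry, "n": n, "slope": slope, "p": p, "flagged": False})
    out = pd.DataFrame(rows).set_index("entry_id")
    out["trait"] = model
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["sig"] = out["q"] < fdr
    return out


def interaction_check(levels: pd.DataFrame, trait: pd.Series, fdr: float = 0.05) -> pd.DataFrame:
    """Sex x protein interaction test under the relative-CS model.

    Fits trait ~ sex + level + sex:level per entry and BH-adjusts the
    interaction p-values across entries.
    """
    cols = [c for c in levels.columns if c in trait.index]
    y_all = trait.reindex(cols).to_numpy(dtype=float)
    male = _male_indicator(cols)
    lv = levels[cols].to_numpy(dtype=float)
    rows = []
    for i, entry in enumerate(levels.index):
        x = lv[i]
        mask = ~np.isnan(x) & ~np.isnan(y_all)
        n = int(mask.sum())
        if n < 5 or np.ptp(x[mask]) == 0 or len(np.unique(male[mask])) < 2:
            rows.append({"entry_id": entry, "n": n, "p_interaction": np.nan, "flagged": True})
            continue
        X = np.column_stack([np.ones(n), male[mask], x[mask], male[mask] * x[mask]])
        _, p = _slope_test(y_all[mask], X, 3)
        rows.append({"entry_id": entry, "n": n, "p_interaction": p, "flagged": False})
    out = pd.DataFrame(rows).set_index("entry_id")
    out["q_interaction"] = bh_adjust(out["p_interaction"].to_numpy())
    out["sig_interaction"] = out["q_interaction"] < fdr
    return out
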