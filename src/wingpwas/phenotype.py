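"""Wing-size phenotype derivation from raw morphometrics.

Raw centroid size (CS) is adjusted two ways:

* absolute CS — raw CS with fitted foodbatch and genomic-inversion effects
  removed but the sex effect retained, so sex dimorphism stays in the trait:
  CS_raw = mu + S + FB + GI + e; absolute CS = CS_raw - FB_hat - GI_hat.
* relative CS — the residual of CS_raw = mu + IOD + S + FB + e, i.e. wing
  size relative to body size (interocular distance IOD as body proxy).

Lines are then classified big/small by the sign of their mean relative CS.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["absolute_cs", "relative_cs", "classify_size", "centroid_size"]


def _inversion_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("inversion")]


def _design(table: pd.DataFrame, *, sex: bool, iod: bool, foodbatch: bool, inversions: bool):
    """Design matrix (with intercept) and column-group slices."""
    n = len(table)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    groups: dict[str, slice] = {}
    pos = 1
    if iod:
        blocks.append(table["iod"].to_numpy(dtype=float)[:, None])
        groups["iod"] = slice(pos, pos + 1)
        pos += 1
    if sex:
        male = (table["sex"].astype(str) == "M").to_numpy(dtype=float)[:, None]
        blocks.append(male)
        groups["sex"] = slice(pos, pos + 1)
        pos += 1
    if foodbatch:
        fb = table["foodbatch"]
        levels = sorted(fb.unique())
        counts = fb.value_counts()
        lonely = [lv for lv in levels if counts[lv] == 1]
        if lonely:
            warnings.warn(
                f"foodbatch level(s) {lonely} have a single observation; "
                "effect estimable but noisy",
                stacklevel=3,
            )
        cols = [(fb == lv).to_numpy(dtype=float) for lv in levels[1:]]
        dummies = np.column_stack(cols) if cols else np.empty((n, 0))
        if dummies.size:
            blocks.append(dummies)
            groups["foodbatch"] = slice(pos, pos + dummies.shape[1])
            pos += dummies.shape[1]
    if inversions:
        inv_cols = _inversion_columns(table)
        if inv_cols:
            blocks.append(table[inv_cols].to_numpy(dtype=float))
            groups["inversions"] = slice(pos, pos + len(inv_cols))
            pos += len(inv_cols)
    return np.hstack(blocks), groups


def absolute_cs(table: pd.DataFrame) -> pd.Series:
    """Absolute CS: raw CS minus fitted foodbatch and inversion contributions.

    The model CS_raw ~ sex + foodbatch + inversions is fit by least squares;
    the fitted foodbatch and inversion contributions are centered before
    subtraction so the grand mean of raw CS is preserved (the adjustment is
    identifiable only up to a constant). Sex effect and residual are retained.
    """
    for col in ("raw_cs", "foodbatch"):
        if col not in table.columns:
            raise KeyError(f"column {col!r} required")
    y = table["raw_cs"].to_numpy(dtype=float)
    X, groups = _design(table, sex=True, iod=False, foodbatch=True, inversions=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    adjust = np.zeros_like(y)
    for grp in ("foodbatch", "inversions"):
        if grp in groups:
            contrib = X[:, groups[grp]] @ coef[groups[grp]]
            adjust += contrib - contrib.mean()
    return pd.Series(y - adjust, index=table.index, name="absolute_cs")


def relative_cs(table: pd.DataFrame) -> pd.Series:
    """Relative CS: residual of CS_raw ~ IOD + sex + foodbatch."""
    for col in ("raw_cs", "iod", "foodbatch"):
        if col not in table.columns:
            raise KeyError(f"column {col!r} required")
    if np.ptp(table["iod"].to_numpy(dtype=float)) == 0:
        raise ValueError("IOD is constant; its coefficient is unidentifiable")
    y = table["raw_cs"].to_numpy(dtype=float)
    X, _ = _design(table, sex=True, iod=True, foodbatch=True, inversions=False)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ coef, index=table.index, name="relative_cs")


def classify_size(table: pd.DataFrame, value_col: str = "relative_cs") -> pd.DataFrame:
    """Big/small wing classification per line.

    Each line's relative CS values (both sexes) are averaged; lines with a
    positive mean are 'big', the rest — including exact zeros — 'small'.
    """
    if value_col not in table.columns:
        raise KeyError(f"column {value_col!r} required")
    per_line = table.groupby("line")[value_col].mean()
    labels = np.where(per_line > 0, "big", "small")
    out = pd.DataFrame({"line": per_line.index, value_col: per_line.to_numpy(), "size_class": labels})
    out.attrs["n_big"] = int((labels == "big").sum())
    out.attrs["n_small"] = int((labels == "small").sum())
    return out.reset_index(drop=True)


def centroid_size(coords: np.ndarray) -> np.ndarray:
    """Centroid size of landmark configurations.

    ``coords`` has shape (n_wings, n_landmarks, 2); CS is the square root of
    the summed squared distances of the landmarks from their centroid.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    centered = coords - coords.mean(axis=1, keepdims=True)
    return np.sqrt((centered**2).sum(axis=(1, 2)))
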