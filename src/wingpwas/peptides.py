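"""Peptide-level matrix transforms and quality control.

The entry point of the pipeline is a peptide x sample intensity matrix.
Raw intensities are log2-transformed and median-centered per sample, peptides
with excessive missingness are removed, and replicate reproducibility is
summarized with pairwise Spearman rank correlations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "log2_median_center",
    "filter_missingness",
    "replicate_reproducibility",
    "drop_samples",
]


def log2_median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform raw intensities and median-center each sample.

    Every sample's median over observed values is shifted to the common
    target, defined as the median of the per-sample log2 medians before
    centering. Missing entries (NaN) are untouched.

    Parameters
    ----------
    matrix : DataFrame
        Peptides x samples, raw (linear-scale) intensities, NaN for missing.

    Raises
    ------
    ValueError
        If any observed intensity is not strictly positive; the message names
        the offending peptide and sample.
    """
    values = matrix.to_numpy(dtype=float)
    bad = np.asarray((values <= 0) & ~np.isnan(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive intensity for peptide {matrix.index[i]!r} "
            f"in sample {matrix.columns[j]!r}"
        )
    log2 = np.log2(values)
    sample_medians = np.nanmedian(log2, axis=0)
    target = float(np.median(sample_medians))
    centered = log2 - sample_medians[None, :] + target
    out = pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)
    out.attrs["centering_target"] = target
    return out


def missingness_floor(n_samples: int, max_missing_frac: float = 0.2) -> int:
    """Largest missing-sample count a peptide may have and still be retained."""
    return math.floor(max_missing_frac * n_samples)


def filter_missingness(
    matrix: pd.DataFrame, max_missing_frac: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove peptides missing in more than ``max_missing_frac`` of samples.

    A peptide is retained iff its missing-sample count is at most
    floor(max_missing_frac * n_samples), i.e. strictly more than the
    fraction is required for removal.

    Returns the filtered matrix and a removal report (peptide, n_missing,
    n_samples) for the peptides dropped. Idempotent.
    """
    if not (0.0 <= max_missing_frac < 1.0):
        raise ValueError("max_missing_frac must lie in [0, 1)")
    n_samples = matrix.shape[1]
    floor = missingness_floor(n_samples, max_missing_frac)
    n_missing = matrix.isna().sum(axis=1)
    keep = n_missing <= floor
    report = pd.DataFrame(
        {
            "peptide": matrix.index[~keep],
            "n_missing": n_missing[~keep].to_numpy(),
            "n_samples": n_samples,
        }
    ).reset_index(drop=True)
    return matrix.loc[keep], report


def drop_samples(
    matrix: pd.DataFrame, design: pd.DataFrame, exclude: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove failed/excluded samples from the matrix and design together."""
    unknown = set(exclude) - set(matrix.columns)
    if unknown:
        raise KeyError(f"samples not in matrix: {sorted(unknown)}")
    keep_cols = [c for c in matrix.columns if c not in set(exclude)]
    return matrix[keep_cols], design[design["sample_id"].isin(keep_cols)].reset_index(drop=True)


def replicate_reproducibility(
    matrix: pd.DataFrame, design: pd.DataFrame, min_shared: int = 3
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise Spearman correlations between samples, split by replicate status.

    For every unordered sample pair, Spearman's rho is computed over the
    peptides observed in both samples (average ranks on ties). Pairs of the
    same line and sex are biological replicates; all other pairs are
    non-replicates. Pairs sharing fewer than ``min_shared`` observed peptides
    get rho=NaN, are flagged, and are excluded from the group medians.

    Returns (pair table, {"replicate_median": ..., "nonreplicate_median": ...}).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    meta = design.set_index("sample_id")
    cols = list(matrix.columns)
    values = matrix.to_numpy(dtype=float)
    rows = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            x, y = values[:, a], values[:, b]
            shared = ~np.isnan(x) & ~np.isnan(y)
            n = int(shared.sum())
            if n < min_shared:
                rho = np.nan
            else:
                rho = float(stats.spearmanr(x[shared], y[shared]).statistic)
            same = (
                meta.loc[cols[a], "line"] == meta.loc[cols[b], "line"]
                and meta.loc[cols[a], "sex"] == meta.loc[cols[b], "sex"]
            )
            rows.append(
                {
                    "sample_a": cols[a],
                    "sample_b": cols[b],
                    "n_shared": n,
                    "rho": rho,
                    "replicate": bool(same),
                    "undefined": n < min_shared,
                }
            )
    pairs = pd.DataFrame(rows)
    ok = pairs[~pairs["undefined"]]
    medians = {
        "replicate_median": float(ok.loc[ok["replicate"], "rho"].median()),
        "nonreplicate_median": float(ok.loc[~ok["replicate"], "rho"].median()),
    }
    return pairs, medians
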