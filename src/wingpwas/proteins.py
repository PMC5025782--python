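"""Peptide-to-protein roll-up and protein-entry statistics.

A protein *entry* is the quantifiable unit defined by a distinct constituent
peptide set: a uniquely-identified protein, one annotated sequence variant of
a protein (numbered), or an indistinguishable isoform group (named by
combining the isoform names).

Entry levels per line/sex are obtained from a two-way additive linear model
per entry,

    intensity(peptide, sample) = MS feature (peptide) + biological feature
                                 (line x sex) + error (across replicates),

fit by least squares on the observed cells; the level of an entry in a
biological sample is the mean over its constituent peptides of the model's
fitted values, so peptide ionization offsets cancel out of every
between-sample comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_entries",
    "fit_entry_model",
    "entry_levels",
    "quantify",
    "test_sex_line",
    "entry_dispersion",
    "EntryFit",
]


def _protein_of(annotation: str) -> str:
    """Protein name of an annotation id ('CG1234-PA' -> 'CG1234')."""
    return annotation.rsplit("-", 1)[0] if "-" in annotation else annotation


def classify_entries(
    peptide_map: dict[str, tuple[str, ...] | list[str] | str],
    protein_of=None,
) -> pd.DataFrame:
    """Group peptides into protein entries by their annotation signature.

    ``peptide_map`` maps each peptide to the annotation id(s) (protein or
    isoform identifiers) it matches. Peptides with identical signatures form
    one entry. A multi-annotation signature is an indistinguishable isoform
    group (class ``isoform-group``; id combines the names). A protein whose
    annotated variants yield several distinct single-annotation signatures
    gets one numbered entry per signature (class ``numbered-variant``);
    otherwise the protein forms a single ``unique`` entry.

    Returns a table with columns entry_id, entry_class, proteins, peptides.
    """
    if not peptide_map:
        raise ValueError("peptide map is empty")
    if protein_of is None:
        protein_of = _protein_of
    signatures: dict[frozenset, list[str]] = {}
    for pep, annots in peptide_map.items():
        if isinstance(annots, str):
            annots = (annots,)
        sig = frozenset(annots)
        if not sig:
            raise ValueError(f"peptide {pep!r} maps to zero proteins")
        signatures.setdefault(sig, []).append(pep)

    single_by_protein: dict[str, list[frozenset]] = {}
    for sig in signatures:
        if len(sig) == 1:
            prot = protein_of(next(iter(sig)))
            single_by_protein.setdefault(prot, []).append(sig)

    rows = []
    for sig, peps in signatures.items():
        annots = sorted(sig)
        if len(sig) > 1:
            entry_id = "+".join(annots)
            cls = "isoform-group"
            prots = sorted({protein_of(a) for a in annots})
        else:
            prot = protein_of(annots[0])
            sibs = sorted(single_by_protein[prot], key=lambda s: sorted(s))
            if len(sibs) > 1:
                entry_id = f"{prot}#{sibs.index(sig) + 1}"
                cls = "numbered-variant"
            else:
                entry_id = prot
                cls = "unique"
            prots = [prot]
        rows.append(
            {
                "entry_id": entry_id,
                "entry_class": cls,
                "proteins": ";".join(prots),
                "peptides": sorted(peps),
            }
        )
    return pd.DataFrame(rows).sort_values("entry_id", kind="stable").reset_index(drop=True)


@dataclass
class EntryFit:
    """Fitted two-way additive model for one protein entry."""

    peptides: list[str]
    biosamples: list[str]  # line_sex labels in design order
    intercept: float
    peptide_effects: pd.Series
    bio_effects: pd.Series  # NaN where the biological sample was never observed
    fitted: pd.DataFrame  # peptides x biosamples fitted cell values
    rss: float
    df_resid: int
    p_bio: float  # F-test p-value for the biological-feature term
    n_obs: int
    unquantifiable: list[str]  # biosamples with no observed peptide


def _biosample_of(design: pd.DataFrame) -> pd.Series:
    return pd.Series(
        (design["line"].astype(str) + "_" + design["sex"].astype(str)).to_numpy(),
        index=design["sample_id"].to_numpy(),
    )


def fit_entry_model(submatrix: pd.DataFrame, design: pd.DataFrame) -> EntryFit:
    """Least-squares fit of intensity ~ peptide + biological sample.

    ``submatrix`` holds the entry's constituent peptides (rows) by sample
    columns, log2 scale, NaN missing. Replicate samples of the same line/sex
    share one biological-feature level; their scatter estimates the error
    variance. Biological samples with no observed value in any peptide are
    flagged unquantifiable and receive NaN effects.
    """
    bio_of = _biosample_of(design)
    biosamples = list(dict.fromkeys(bio_of[c] for c in submatrix.columns))
    peptides = list(submatrix.index)
    values = submatrix.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    if not obs.any():
        raise ValueError("entry has no observed values")

    pep_idx, samp_idx = np.nonzero(obs)
    y = values[pep_idx, samp_idx]
    bio_labels = np.array([biosamples.index(bio_of[submatrix.columns[j]]) for j in samp_idx])
    seen_bio = sorted(set(bio_labels))
    unquantifiable = [b for i, b in enumerate(biosamples) if i not in seen_bio]

    n = len(y)
    n_pep, n_bio = len(peptides), len(seen_bio)
    bio_pos = {b: k for k, b in enumerate(seen_bio)}

    # dummy coding, first level dropped for each factor; fitted cell values
    # are invariant to this choice
    X = np.ones((n, 1 + (n_pep - 1) + (n_bio - 1)))
    for k in range(1, n_pep):
        X[:, k] = pep_idx == k
    for k in range(1, n_bio):
        X[:, n_pep - 1 + k] = np.array([bio_pos[b] for b in bio_labels]) == k

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    df_resid = n - int(rank)

    # reduced model without the biological term, for the F-test
    Xr = X[:, :n_pep]
    coef_r, _, rank_r, _ = np.linalg.lstsq(Xr, y, rcond=None)
    resid_r = y - Xr @ coef_r
    rss_r = float(resid_r @ resid_r)
    df_num = int(rank) - int(rank_r)
    if df_num > 0 and df_resid > 0 and rss > 0:
        f = ((rss_r - rss) / df_num) / (rss / df_resid)
        p_bio = float(stats.f.sf(f, df_num, df_resid))
    elif df_num > 0 and rss_r > rss:
        p_bio = 0.0  # saturated fit separates the term perfectly
    else:
        p_bio = np.nan

    intercept = float(coef[0])
    alpha = np.concatenate([[0.0], coef[1:n_pep]])
    beta_seen = np.concatenate([[0.0], coef[n_pep:]])
    beta = np.full(len(biosamples), np.nan)
    for b, k in bio_pos.items():
        beta[b] = beta_seen[k]

    fitted = intercept + alpha[:, None] + beta[None, :]
    return EntryFit(
        peptides=peptides,
        biosamples=biosamples,
        intercept=intercept,
        peptide_effects=pd.Series(alpha, index=peptides),
        bio_effects=pd.Series(beta, index=biosamples),
        fitted=pd.DataFrame(fitted, index=peptides, columns=biosamples),
        rss=rss,
        df_resid=df_resid,
        p_bio=p_bio,
        n_obs=n,
        unquantifiable=unquantifiable,
    )


def entry_levels(fit: EntryFit) -> pd.Series:
    """Entry level per line/sex: mean over constituent peptides of the fitted
    values, i.e. intercept + biological effect + mean peptide effect."""
    return fit.fitted.mean(axis=0)


def quantify(
    matrix: pd.DataFrame, design: pd.DataFrame, entries: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll up a peptide matrix to entry levels for every entry.

    Returns (levels, stats): levels is entries x line_sex (replicates
    collapsed by the model); stats holds n_peptides, n_obs, the biological-
    feature F-test p-value, the across-sample s.d. and mean of each entry's
    levels, and an unquantifiable flag.
    """
    bio_of = _biosample_of(design)
    biosamples = list(dict.fromkeys(bio_of[c] for c in matrix.columns))
    level_rows, stat_rows, index = [], [], []
    present = set(matrix.index)
    for _, row in entries.iterrows():
        peps = [p for p in row["peptides"] if p in present]
        if not peps:
            continue
        sub = matrix.loc[peps]
        if not sub.notna().to_numpy().any():
            continue
        fit = fit_entry_model(sub, design)
        lv = entry_levels(fit).reindex(biosamples)
        index.append(row["entry_id"])
        level_rows.append(lv)
        vals = lv.dropna()
        stat_rows.append(
            {
                "entry_class": row["entry_class"],
                "n_peptides": len(peps),
                "n_obs": fit.n_obs,
                "p_bio": fit.p_bio,
                "mean_level": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "unquantifiable": len(fit.unquantifiable) > 0,
            }
        )
    levels = pd.DataFrame(level_rows, index=index)
    stats_df = pd.DataFrame(stat_rows, index=index)
    return levels, stats_df


def _factor_f_tests(y: np.ndarray, male: np.ndarray, line_codes: np.ndarray) -> tuple[float, float]:
    """Type-II F-test p-values for sex and line in level ~ sex + line."""

    def _design(with_sex: bool, with_line: bool) -> np.ndarray:
        cols = [np.ones_like(y)]
        if with_sex:
            cols.append(male)
        if with_line:
            n_lines = line_codes.max() + 1
            for k in range(1, n_lines):
                cols.append((line_codes == k).astype(float))
        return np.column_stack(cols)

    def _fit(X: np.ndarray) -> tuple[float, int]:
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r), int(rank)

    rss_f, rank_f = _fit(_design(True, True))
    df_resid = len(y) - rank_f
    out = []
    for drop_sex in (True, False):
        rss_r, rank_r = _fit(_design(not drop_sex, drop_sex))
        df_num = rank_f - rank_r
        if df_num <= 0 or df_resid <= 0 or rss_f <= 0:
            out.append(np.nan if df_num <= 0 else 0.0 if rss_r > rss_f else np.nan)
            continue
        f = ((rss_r - rss_f) / df_num) / (rss_f / df_resid)
        out.append(float(stats.f.sf(f, df_num, df_resid)))
    return out[0], out[1]


def test_sex_line(levels: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-entry significance of sex and line variation.

    Entry levels (one value per line/sex) are regressed on sex and line as
    additive factors; per-factor F-test p-values are reported with
    significance flags at ``alpha``. With a single line the line factor is
    skipped and flagged.
    """
    cols = list(levels.columns)
    parsed = [c.rsplit("_", 1) for c in cols]
    lines = sorted({ln for ln, _ in parsed})
    if len({sx for _, sx in parsed}) < 2:
        raise ValueError("both sexes are required")
    male_all = np.array([1.0 if sx == "M" else 0.0 for _, sx in parsed])
    line_all = np.array([lines.index(ln) for ln, _ in parsed])

    rows = []
    for entry, series in levels.iterrows():
        mask = series.notna().to_numpy()
        y = series.to_numpy(dtype=float)[mask]
        male = male_all[mask]
        codes = line_all[mask]
        _, uniq_codes = np.unique(codes, return_inverse=True)
        if len(np.unique(codes)) < 2:
            p_sex, _ = _factor_f_tests(y, male, np.zeros_like(uniq_codes))
            rows.append(
                {"p_sex": p_sex, "p_line": np.nan, "sig_sex": p_sex < alpha, "sig_line": False, "line_skipped": True}
            )
            continue
        p_sex, p_line = _factor_f_tests(y, male, uniq_codes)
        rows.append(
            {
                "p_sex": p_sex,
                "p_line": p_line,
                "sig_sex": bool(p_sex < alpha),
                "sig_line": bool(p_line < alpha),
                "line_skipped": False,
            }
        )
    return pd.DataFrame(rows, index=levels.index)


def entry_dispersion(levels: pd.DataFrame) -> pd.DataFrame:
    """Across-sample s.d. and mean level per entry (abundance-variation trend).

    ``fold_sd`` re-expresses the log2 s.d. as a fractional fold change,
    2**sd - 1.
    """
    if levels.shape[1] < 2:
        raise ValueError("need at least two samples")
    sd = levels.std(axis=1, ddof=1)
    mean = levels.mean(axis=1)
    return pd.DataFrame({"sd": sd, "mean_level": mean, "fold_sd": np.power(2.0, sd) - 1.0})
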