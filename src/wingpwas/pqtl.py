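"""Nonparametric cis-pQTL mapping with permutation min-p correction.

For each trait-associated protein entry, homozygous SNPs within +-10 kb of
the gene span with minor allele frequency > 10% are tested against the
entry's per-line levels, one sex at a time, with the Kruskal-Wallis test.
Family-wise correction uses the permutation null of the minimum p-value:
line labels of the whole level matrix are shuffled with one shared stream,
all cis tests are re-run per permutation, and the corrected p-value is the
fraction of permutation minima strictly smaller than the observed minimum
(no smoothing, so a corrected p of 0 is possible).

Effect sizes are standardized mean differences between genotype classes
(Cohen's d with the pooled s.d.), recomputed on the opposite sex and on
per-line wing size to measure attenuation from protein to phenotype.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "snp_maf",
    "select_cis_snps",
    "kw_test",
    "permutation_correct",
    "effect_size",
    "map_pqtls",
    "cross_effects",
]


def snp_maf(genotypes: pd.DataFrame, lines: list[str]) -> pd.Series:
    """Minor allele frequency per SNP over non-missing homozygous lines."""
    codes = genotypes[lines].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        n_ok = (~np.isnan(codes)).sum(axis=1)
        alt = np.nansum(codes == 2, axis=1)
    freq = np.divide(alt, n_ok, out=np.full(len(codes), np.nan), where=n_ok > 0)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.Series(maf, index=genotypes["snp_id"].to_numpy(), name="maf")


def select_cis_snps(
    genotypes: pd.DataFrame,
    gene_spans: pd.DataFrame,
    lines: list[str],
    window: int = 10_000,
    maf_min: float = 0.10,
) -> dict[str, list[str]]:
    """cis-SNP sets per entry: within +-window of the gene span, MAF > maf_min.

    ``gene_spans`` uses BED conventions (0-based half-open); positions in the
    genotype table are 1-based. A SNP at exactly ``window`` bp from the span
    boundary is included; MAF exactly at ``maf_min`` is excluded.
    Entries without a gene annotation are skipped with a warning.
    """
    maf = snp_maf(genotypes, lines)
    ok = maf > maf_min
    spans = gene_spans.set_index("protein")
    out: dict[str, list[str]] = {}
    for entry, row in spans.iterrows():
        start_1b = int(row["start"]) + 1  # BED -> 1-based inclusive
        end_1b = int(row["end"])
        lo, hi = start_1b - window, end_1b + window
        sel = genotypes[
            (genotypes["chrom"] == row["chrom"])
            & (genotypes["pos"] >= lo)
            & (genotypes["pos"] <= hi)
            & ok.loc[genotypes["snp_id"]].to_numpy()
        ]
        out[entry] = sel["snp_id"].tolist()
    return out


def _kw_from_ranks(rank_sums: np.ndarray, counts: np.ndarray, n: int, tie_term: float) -> np.ndarray:
    """Tie-corrected Kruskal-Wallis H from per-group rank sums.

    rank_sums: (..., k) rank totals per group; counts: (k,); n total; tie_term
    = sum(t^3 - t) over tie groups of the ranked vector.
    """
    h = 12.0 / (n * (n + 1)) * (rank_sums**2 / counts).sum(axis=-1) - 3.0 * (n + 1)
    denom = 1.0 - tie_term / (n**3 - n) if n > 2 else 1.0
    if denom <= 0:
        return np.zeros_like(h)
    return h / denom


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float((counts**3 - counts).sum())


def kw_test(values: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-squared p for levels grouped by genotype code.

    Missing codes (NaN) are excluded. Requires >= 2 genotype classes with
    >= 2 observations each; otherwise raises ValueError (callers skip and
    log such SNPs).
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes, dtype=float)
    mask = ~np.isnan(values) & ~np.isnan(codes)
    v, c = values[mask], codes[mask]
    classes, inv = np.unique(c, return_inverse=True)
    counts = np.bincount(inv)
    if len(classes) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 genotype classes with >= 2 observations each")
    ranks = stats.rankdata(v)
    n = len(v)
    rank_sums = np.bincount(inv, weights=ranks)
    h = float(_kw_from_ranks(rank_sums[None, :], counts, n, _tie_term(ranks))[0])
    p = float(stats.chi2.sf(h, len(classes) - 1))
    return h, p


def _snp_groups(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Group index per line and class counts for one SNP, or None if untestable."""
    classes, inv = np.unique(codes, return_inverse=True)
    counts = np.bincount(inv)
    if len(classes) < 2 or (counts < 2).any():
        return None
    return inv, counts


def permutation_correct(
    levels: pd.DataFrame,
    genotypes: pd.DataFrame,
    cis_map: dict[str, list[str]],
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Observed min-p cis scan plus permutation family-wise correction.

    ``levels`` is entries x lines for a single sex (complete values). One
    shared stream of line-label permutations is applied to the whole level
    matrix; for every permutation each entry's cis-SNP Kruskal-Wallis scan is
    re-run and the per-entry minimum p recorded. corrected_p = #(permutation
    minima < observed minimum) / n_perm, strictly.

    Returns a table per testable entry: best_snp, n_cis, min_p, corrected_p.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives poor corrected-p resolution")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lines = list(levels.columns)
    n = len(lines)
    geno = genotypes.set_index("snp_id")
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    for entry, series in levels.iterrows():
        snps = [s for s in cis_map.get(entry, []) if s in geno.index]
        if not snps:
            continue
        v = series.to_numpy(dtype=float)
        if np.isnan(v).any():
            keep = ~np.isnan(v)
        else:
            keep = np.ones(n, dtype=bool)
        groups = []
        for s in snps:
            codes = geno.loc[s, lines].to_numpy(dtype=float)
            m = keep & ~np.isnan(codes)
            if m.sum() < 4 or not m.all():
                # missing data: handled by the general path below
                groups.append(("slow", s, codes))
                continue
            g = _snp_groups(codes)
            if g is None:
                continue
            groups.append(("fast", s, g))
        fast = [(s, g) for kind, s, g in groups if kind == "fast"]
        slow = [(s, c) for kind, s, c in groups if kind == "slow"]
        if not fast and not slow:
            continue

        obs_best, obs_min = None, np.inf
        perm_min = np.full(n_perm, np.inf)
        if fast:
            ranks = stats.rankdata(v)
            tie = _tie_term(ranks)
            perm_ranks = ranks[perm_idx]  # (P, n)
            for s, (inv, counts) in fast:
                k = len(counts)
                ind = np.zeros((n, k))
                ind[np.arange(n), inv] = 1.0
                rs_obs = ranks @ ind
                h_obs = float(_kw_from_ranks(rs_obs[None, :], counts, n, tie)[0])
                p_obs = float(stats.chi2.sf(h_obs, k - 1))
                if p_obs < obs_min:
                    obs_min, obs_best = p_obs, s
                rs = perm_ranks @ ind  # (P, k)
                h = _kw_from_ranks(rs, counts, n, tie)
                perm_min = np.minimum(perm_min, stats.chi2.sf(h, k - 1))
        for s, codes in slow:
            mask = keep & ~np.isnan(codes)
            try:
                _, p_obs = kw_test(v[mask], codes[mask])
            except ValueError:
                continue
            if p_obs < obs_min:
                obs_min, obs_best = p_obs, s
            for t in range(n_perm):
                vp = v[perm_idx[t]]
                try:
                    _, p = kw_test(vp[mask], codes[mask])
                except ValueError:
                    continue
                perm_min[t] = min(perm_min[t], p)
        if obs_best is None:
            continue
        corrected = float((perm_min < obs_min).sum()) / n_perm
        rows.append(
            {
                "entry_id": entry,
                "best_snp": obs_best,
                "n_cis": len(fast) + len(slow),
                "min_p": obs_min,
                "corrected_p": corrected,
            }
        )
    return pd.DataFrame(rows).set_index("entry_id") if rows else pd.DataFrame(
        columns=["best_snp", "n_cis", "min_p", "corrected_p"]
    )


def effect_size(values: np.ndarray, codes: np.ndarray) -> float:
    """Cohen's d between the two homozygous genotype classes.

    d = |mean(class A) - mean(class B)| / pooled s.d. Returns NaN (flagged)
    when the pooled s.d. is zero; raises unless exactly two classes with at
    least one observation each are present.
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes, dtype=float)
    mask = ~np.isnan(values) & ~np.isnan(codes)
    v, c = values[mask], codes[mask]
    classes = np.unique(c)
    if len(classes) != 2:
        raise ValueError(f"effect size needs exactly 2 genotype classes, got {len(classes)}")
    a, b = v[c == classes[0]], v[c == classes[1]]
    na, nb = len(a), len(b)
    sa = a.std(ddof=1) if na > 1 else 0.0
    sb = b.std(ddof=1) if nb > 1 else 0.0
    df = na + nb - 2
    if df <= 0:
        return np.nan
    pooled = np.sqrt(((na - 1) * sa**2 + (nb - 1) * sb**2) / df)
    if pooled == 0:
        return np.nan
    return float(abs(a.mean() - b.mean()) / pooled)


def map_pqtls(
    levels: pd.DataFrame,
    genotypes: pd.DataFrame,
    gene_spans: pd.DataFrame,
    window: int = 10_000,
    maf_min: float = 0.10,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    entry_gene: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full per-sex cis-pQTL scan of an entries x line_sex level matrix.

    ``entry_gene`` maps entry ids to gene-span protein names when they differ
    (defaults to the identity). Returns one row per (entry, sex) with the
    best cis SNP, raw and corrected p, the protein effect size and the
    effect size recomputed on the opposite sex.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cols = list(levels.columns)
    sexes = sorted({c.rsplit("_", 1)[1] for c in cols})
    by_sex = {}
    for sx in sexes:
        sub = levels[[c for c in cols if c.endswith(f"_{sx}")]].copy()
        sub.columns = [c.rsplit("_", 1)[0] for c in sub.columns]
        by_sex[sx] = sub.dropna(axis=0)
    lines = list(next(iter(by_sex.values())).columns)

    if entry_gene is None:
        entry_gene = {e: e for e in levels.index}
    known = set(gene_spans["protein"])
    annotated = {e: g for e, g in entry_gene.items() if g in known}
    dropped = [e for e in levels.index if e not in annotated]
    if dropped:
        warnings.warn(f"{len(dropped)} entr(ies) without gene annotation skipped")
    cis_by_gene = select_cis_snps(genotypes, gene_spans, lines, window=window, maf_min=maf_min)
    cis_map = {e: cis_by_gene.get(g, []) for e, g in annotated.items()}

    geno = genotypes.set_index("snp_id")
    results = []
    for sx in sexes:
        sub = by_sex[sx].loc[[e for e in by_sex[sx].index if cis_map.get(e)]]
        if sub.empty:
            continue
        corr = permutation_correct(sub, genotypes, cis_map, n_perm=n_perm, rng=rng)
        other = [s for s in sexes if s != sx]
        for entry, row in corr.iterrows():
            codes = geno.loc[row["best_snp"], lines].to_numpy(dtype=float)
            d = effect_size(sub.loc[entry].to_numpy(), codes)
            d_opp = np.nan
            if other and entry in by_sex[other[0]].index:
                d_opp = effect_size(by_sex[other[0]].loc[entry].to_numpy(), codes)
            results.append(
                {
                    "entry_id": entry,
                    "sex": sx,
                    "best_snp": row["best_snp"],
                    "n_cis": int(row["n_cis"]),
                    "min_p": row["min_p"],
                    "corrected_p": row["corrected_p"],
                    "effect_size": d,
                    "opposite_sex_effect_size": d_opp,
                    "sig_0.01": row["corrected_p"] < 0.01,
                    "sig_0.05": row["corrected_p"] < 0.05,
                }
            )
    return pd.DataFrame(results)


def cross_effects(
    pqtls: pd.DataFrame,
    absolute_cs: pd.Series,
    genotypes: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Wing-size effect sizes for mapped pQTLs and the attenuation test.

    ``absolute_cs`` is indexed by line_sex. For each pQTL the standardized
    difference of per-line absolute CS (same sex) between genotype classes is
    computed; a two-sided Wilcoxon rank-sum test compares the protein and
    wing-size effect-size samples.
    """
    if pqtls.empty:
        raise ValueError("pQTL list is empty")
    geno = genotypes.set_index("snp_id")
    wing_d = []
    for _, row in pqtls.iterrows():
        sx = row["sex"]
        cs = absolute_cs[[i for i in absolute_cs.index if i.endswith(f"_{sx}")]]
        lines = [i.rsplit("_", 1)[0] for i in cs.index]
        codes = geno.loc[row["best_snp"], lines].to_numpy(dtype=float)
        wing_d.append(effect_size(cs.to_numpy(), codes))
    out = pqtls.copy()
    out["wing_size_effect_size"] = wing_d
    prot = out["effect_size"].dropna().to_numpy()
    wing = out["wing_size_effect_size"].dropna().to_numpy()
    p = float(stats.ranksums(prot, wing).pvalue) if len(prot) and len(wing) else np.nan
    return out, p
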