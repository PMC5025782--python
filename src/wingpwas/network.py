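"""Co-variation modules and the wing-size-associated protein network.

Trait-associated entries are clustered by complete-linkage hierarchical
clustering on the distance 1 - |rho| (pairwise Spearman over all line/sex
samples); cutting the tree at height 1 - rho_cut yields modules whose
members all satisfy |rho| >= rho_cut pairwise (the complete-linkage
guarantee). Confidence-filtered protein-protein interaction edges are then
merged with the co-variation edges into one network. Modules are summarized
by their first principal component, clustered into higher-order module
clusters, and correlated with the size traits.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "spearman_matrix",
    "covariation_modules",
    "merge_interaction_edges",
    "module_pc",
    "module_pcs",
    "higher_order_clustering",
    "module_trait_correlation",
    "rho_equivalent_p",
]


def spearman_matrix(levels: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlation between entry profiles (rows).

    Entries with fewer than ``min_shared`` observed samples are dropped with
    a warning; pairwise-complete observations are used.
    """
    n_obs = levels.notna().sum(axis=1)
    bad = levels.index[n_obs < min_shared]
    if len(bad):
        warnings.warn(f"excluding {len(bad)} entr(ies) with <{min_shared} observed samples")
        levels = levels.drop(index=bad)
    return levels.T.corr(method="spearman", min_periods=min_shared)


def covariation_modules(
    levels: pd.DataFrame, rho_cut: float = 0.4
) -> tuple[pd.Series, np.ndarray, pd.DataFrame]:
    """Cut the complete-linkage tree on 1 - |rho| at height 1 - rho_cut.

    Returns (module labels per entry, scipy linkage matrix, signed Spearman
    correlation matrix). Every within-module pair satisfies |rho| >= rho_cut.
    """
    if levels.shape[0] < 2:
        raise ValueError("need at least 2 entries")
    corr = spearman_matrix(levels)
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize fp noise
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=1.0 - rho_cut, criterion="distance")
    return pd.Series(labels, index=corr.index, name="module"), Z, corr


def merge_interaction_edges(
    modules: pd.Series,
    corr: pd.DataFrame,
    edges: pd.DataFrame | None,
    min_score: float = 0.9,
    rho_cut: float = 0.4,
) -> nx.Graph:
    """Assemble the association network from co-variation and interaction edges.

    Nodes are exactly the entries in ``modules`` (the trait-associated set).
    Co-variation edges connect pairs with |rho| >= rho_cut, weighted by
    |rho| and carrying the signed rho. Interaction edges with confidence
    score >= min_score join the second edge class; edges touching proteins
    outside the network are dropped, and scores given on a 0-1000 scale are
    auto-detected and rescaled. Malformed edge rows are skipped and counted
    in ``G.graph["skipped_edges"]``.
    """
    G = nx.Graph()
    for node, mod in modules.items():
        G.add_node(node, module=int(mod))
    nodes = list(modules.index)
    c = corr.loc[nodes, nodes].to_numpy()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            rho = c[i, j]
            if np.isfinite(rho) and abs(rho) >= rho_cut:
                G.add_edge(nodes[i], nodes[j], kind="covariation", weight=abs(rho), rho=float(rho))

    skipped = 0
    if edges is not None and len(edges):
        scores = pd.to_numeric(edges["score"], errors="coerce")
        finite = scores.dropna()
        scale = 1000.0 if len(finite) and finite.max() > 1.0 else 1.0
        for (_, row), score in zip(edges.iterrows(), scores):
            a, b = row.get("protein_a"), row.get("protein_b")
            if not isinstance(a, str) or not isinstance(b, str) or not np.isfinite(score):
                skipped += 1
                continue
            s = float(score) / scale
            if not (0.0 <= s <= 1.0):
                skipped += 1
                continue
            if s < min_score or a not in G or b not in G or a == b:
                continue
            if G.has_edge(a, b):
                G[a][b]["score"] = s  # annotate existing co-variation edge too
                G[a][b]["interaction"] = True
            else:
                G.add_edge(a, b, kind="interaction", weight=s, score=s, interaction=True)
    G.graph["skipped_edges"] = skipped
    return G


def module_pc(module_levels: pd.DataFrame) -> pd.Series:
    """First principal component scores of one module's member x sample matrix.

    Member profiles are centered (not standardized); the sign is aligned so
    the PC has positive mean correlation with the members. A degenerate
    (constant) module yields NaN scores with ``attrs['degenerate']=True``.
    """
    if module_levels.shape[0] < 2:
        raise ValueError("module PC requires >= 2 members")
    if module_levels.shape[1] < 3:
        raise ValueError("module PC requires >= 3 samples")
    X = module_levels.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    out = pd.Series(np.nan, index=module_levels.columns, name="module_pc")
    if not np.isfinite(Xc).all() or (Xc**2).sum() == 0:
        out.attrs["degenerate"] = True
        return out
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = s[0] * vt[0]
    corrs = [np.corrcoef(scores, row)[0, 1] for row in Xc if row.std() > 0]
    if corrs and np.mean(corrs) < 0:
        scores = -scores
    out[:] = scores
    out.attrs["degenerate"] = False
    return out


def module_pcs(levels: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """PC scores for every multi-member module; rows are module ids."""
    rows, idx = [], []
    for mod in sorted(modules.unique()):
        members = modules.index[modules == mod]
        if len(members) < 2:
            continue
        pc = module_pc(levels.loc[members])
        if pc.attrs.get("degenerate"):
            continue
        rows.append(pc)
        idx.append(mod)
    return pd.DataFrame(rows, index=pd.Index(idx, name="module"))


def higher_order_clustering(pcs: pd.DataFrame, cut_height: float = 0.6) -> pd.Series:
    """Complete-linkage clustering of modules on 1 - |rho| between module PCs.

    ``cut_height`` is on the same 1 - |rho| scale as the module cut (default
    0.6, i.e. |rho| >= 0.4 within a module cluster).
    """
    if pcs.shape[0] == 1:
        return pd.Series([1], index=pcs.index, name="module_cluster")
    corr = pcs.T.corr(method="spearman")
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    return pd.Series(labels, index=pcs.index, name="module_cluster")


def module_trait_correlation(pcs: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Signed and absolute Spearman correlation of each module PC with traits.

    ``traits`` has one row per sample (matching the PC columns) and one
    column per trait (e.g. absolute_cs, relative_cs, iod).
    """
    rows = []
    for mod, pc in pcs.iterrows():
        row: dict[str, float] = {}
        for trait in traits.columns:
            t = traits[trait].reindex(pcs.columns)
            mask = t.notna().to_numpy() & pc.notna().to_numpy()
            rho = float(stats.spearmanr(pc[mask], t[mask]).statistic) if mask.sum() >= 3 else np.nan
            row[f"rho_{trait}"] = rho
            row[f"abs_rho_{trait}"] = abs(rho)
        rows.append(row)
    return pd.DataFrame(rows, index=pcs.index)


def rho_equivalent_p(rho: float, n: int) -> float:
    """Two-sided t-approximation p-value of a Spearman correlation.

    t = rho * sqrt((n - 2) / (1 - rho^2)); used to express a correlation
    cutoff as a significance level (e.g. |rho| = 0.4 at n = 60 ~ p = 0.001).
    """
    if not (-1.0 < rho < 1.0):
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))
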