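"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are TSV. The intensity matrix uses "NA" for missing values; the
genotype table codes homozygous genotypes 0/2 with one column per line; gene
spans are BED (0-based half-open); ground truth serializes to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import StudyBundle

__all__ = [
    "write_intensities",
    "read_intensities",
    "write_design",
    "read_design",
    "write_phenotypes",
    "read_phenotypes",
    "write_genotypes",
    "read_genotypes",
    "write_gene_spans_bed",
    "read_gene_spans_bed",
    "write_edges",
    "read_edges",
    "write_ground_truth",
    "write_bundle",
    "write_levels",
    "read_levels",
    "write_graphml",
]


def write_intensities(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="peptide")


def read_intensities(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="peptide", na_values=["NA"])


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_gene_spans_bed(spans: pd.DataFrame, path) -> None:
    spans[["chrom", "start", "end", "protein"]].to_csv(path, sep="\t", index=False, header=False)


def read_gene_spans_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "protein"])
    return bed[["protein", "chrom", "start", "end"]]


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_levels(levels: pd.DataFrame, path) -> None:
    levels.to_csv(path, sep="\t", na_rep="NA", index_label="entry_id")


def read_levels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="entry_id", na_values=["NA"])


def write_ground_truth(bundle: StudyBundle, path) -> None:
    truth = bundle.truth
    payload = {
        "module_membership": truth.module_membership,
        "size_associated": {k: float(v) for k, v in truth.size_associated.items()},
        "pqtls": truth.pqtls.to_dict(orient="records"),
        "peptide_offsets": {k: float(v) for k, v in truth.peptide_offsets.items()},
        "coding_peptides": {k: str(v) for k, v in truth.coding_peptides.items()},
        "protein_levels": {
            "index": list(truth.protein_levels.index),
            "columns": list(truth.protein_levels.columns),
            "values": np.round(truth.protein_levels.to_numpy(), 6).tolist(),
        },
        "seed": bundle.config.seed,
    }
    Path(path).write_text(json.dumps(payload))


def write_bundle(bundle: StudyBundle, outdir) -> dict[str, Path]:
    """Write every component of a synthetic study bundle into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": outdir / "intensities.tsv",
        "design": outdir / "design.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "gene_spans": outdir / "gene_spans.bed",
        "edges": outdir / "edges.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_intensities(bundle.intensities, paths["intensities"])
    write_design(bundle.design, paths["design"])
    write_phenotypes(bundle.phenotypes, paths["phenotypes"])
    write_genotypes(bundle.genotypes, paths["genotypes"])
    write_gene_spans_bed(bundle.gene_spans, paths["gene_spans"])
    write_edges(bundle.edges, paths["edges"])
    write_ground_truth(bundle, paths["ground_truth"])
    return paths


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)
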