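"""Synthetic study-bundle generator with known ground truth.

Emulates a SWATH-MS proteome survey of wing imaginal discs across inbred,
fully homozygous fly lines: 30 lines x 2 sexes x 2 biological replicates,
peptide-level log2 intensities that are additive in (protein level, peptide
ionization offset), coding-variant peptides that drop out completely in
minor-allele carrier lines, missing-not-at-random dropout at low intensity,
planted co-varying protein modules tied to a size phenotype, and planted
cis-pQTLs of specified standardized effect size.

Every stage draws from an independent substream spawned from one global
seed, so bundles are bit-reproducible and stages can be regenerated alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModuleSpec",
    "PqtlSpec",
    "SimulationConfig",
    "GroundTruth",
    "StudyBundle",
    "generate_genotypes",
    "generate_truth",
    "generate_phenotypes",
    "generate_intensities",
    "generate_bundle",
]

_CHROMS = ("2L", "2R", "3R")
_GENE_SPACING = 50_000
_GENE_LENGTH = 3_000

# Phenotype-scale constants (centroid-size units / distance units).
_CS_MEAN = 270.0
_IOD_MEAN = 20.0
_IOD_SEX_SHIFT = -1.5  # males are smaller-bodied
_IOD_BODY_COEF = 0.8
_IOD_NOISE_SD = 0.1


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-variation module.

    size: number of member proteins.
    within_rho: target pairwise correlation of member line profiles, in (0, 1).
    size_effect: signed slope of the module's latent factor on raw centroid size.
    """

    size: int
    within_rho: float
    size_effect: float


@dataclass(frozen=True)
class PqtlSpec:
    """A planted cis-pQTL: `snp` is moved into the cis window of `protein`.

    cohens_d is the exact standardized mean difference between homozygous
    genotype classes of the noise-free protein line levels, per sex.
    """

    protein: int
    snp: int
    cohens_d: float


@dataclass
class SimulationConfig:
    n_lines: int = 30
    n_sexes: int = 2  # fixed by the study design
    n_replicates: int = 2
    n_proteins: int = 300
    peptides_per_protein: tuple[int, int] = (1, 20)
    n_snps: int = 600
    maf_range: tuple[float, float] = (0.10, 0.50)
    planted_modules: list[ModuleSpec] = field(
        default_factory=lambda: [
            ModuleSpec(size=25, within_rho=0.8, size_effect=4.0),
            ModuleSpec(size=20, within_rho=0.7, size_effect=-4.0),
            ModuleSpec(size=15, within_rho=0.7, size_effect=3.0),
        ]
    )
    planted_pqtls: list[PqtlSpec] = field(
        default_factory=lambda: [
            PqtlSpec(protein=0, snp=0, cohens_d=2.0),
            PqtlSpec(protein=25, snp=1, cohens_d=2.0),
            PqtlSpec(protein=45, snp=2, cohens_d=2.0),
        ]
    )
    coding_dropout_fraction: float = 0.05
    mnar_threshold: float = 9.0
    mnar_scale: float = 1.0
    noise_sd: float = 0.15  # replicate-level log2 s.d.
    line_sd: float = 0.25  # biological (between-line) log2 s.d. per protein
    baseline_mean: float = 14.0  # mean log2 peptide-precursor abundance
    baseline_sd: float = 1.5
    peptide_offset_sd: float = 1.5
    foodbatch_levels: int = 4
    foodbatch_sd: float = 2.0
    inversion_effects: tuple[float, ...] = (-2.0, -1.0)  # CS shift per copy
    sex_dimorphism: tuple[float, float] = (-25.0, 0.3)  # (CS male shift, abundance shift s.d.)
    cs_body_coef: float = 3.0  # slope of the latent body-size factor on raw CS
    cs_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_replicates < 1 or self.n_proteins < 1:
            raise ValueError("counts must be >= 1")
        if self.n_sexes != 2:
            raise ValueError("the study design is two-sex; n_sexes must be 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be a range with lower bound >= 1")
        for m in self.planted_modules:
            if not (0.0 < m.within_rho < 1.0):
                raise ValueError("within_rho must lie in (0, 1)")
            if m.size < 1:
                raise ValueError("module size must be >= 1")
        if sum(m.size for m in self.planted_modules) > self.n_proteins:
            raise ValueError("planted modules exceed the protein count")
        for q in self.planted_pqtls:
            if q.cohens_d < 0:
                raise ValueError("cohens_d must be >= 0")
            if not (0 <= q.protein < self.n_proteins):
                raise ValueError("planted pQTL references a nonexistent protein")
            if not (0 <= q.snp < self.n_snps):
                raise ValueError("planted pQTL references a nonexistent SNP")
        if len({q.snp for q in self.planted_pqtls}) < len(self.planted_pqtls):
            raise ValueError("planted pQTLs must use distinct SNPs")

    @property
    def lines(self) -> list[str]:
        return [f"line{i + 1:02d}" for i in range(self.n_lines)]

    @property
    def proteins(self) -> list[str]:
        return [f"prot{i + 1:04d}" for i in range(self.n_proteins)]


@dataclass
class GroundTruth:
    """Generative state recorded for downstream validation."""

    protein_levels: pd.DataFrame  # proteins x (line_sex) true log2 levels
    peptide_offsets: pd.Series  # peptide -> additive ionization offset (log2)
    peptide_protein: pd.Series  # peptide -> protein id
    module_membership: dict[str, list[str]]  # module id -> member proteins
    size_associated: pd.Series  # protein -> sign (+1/-1) of planted size link
    pqtls: pd.DataFrame  # columns: protein, snp, cohens_d
    module_factors: pd.DataFrame  # module x line latent factors
    body_factor: pd.Series  # line -> latent body-size factor
    coding_peptides: pd.Series  # coding-variant peptide -> tagging snp id
    dropout_provenance: dict[str, pd.DataFrame] | None = None  # masks: mnar, coding

    def validate(self) -> None:
        members = [p for ms in self.module_membership.values() for p in ms]
        if len(members) != len(set(members)):
            raise ValueError("module memberships must be disjoint")
        for _, row in self.pqtls.iterrows():
            if row["protein"] not in self.protein_levels.index:
                raise ValueError(f"pQTL references unknown protein {row['protein']}")


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    config: SimulationConfig
    intensities: pd.DataFrame  # peptides x samples, raw linear scale, NaN missing
    design: pd.DataFrame  # sample_id, line, sex, replicate
    phenotypes: pd.DataFrame  # line/sex rows: raw_cs, iod, foodbatch, inversions
    genotypes: pd.DataFrame  # snp rows: snp_id, chrom, pos, ref, alt, per-line codes
    gene_spans: pd.DataFrame  # protein, chrom, start, end (0-based half-open)
    edges: pd.DataFrame  # protein_a, protein_b, score
    truth: GroundTruth


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("genotypes", "truth", "phenotypes", "intensities", "edges")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def gene_span_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene layout: proteins tile the chromosomes on a fixed grid.

    Coordinates are BED-style 0-based half-open.
    """
    rows = []
    for i, prot in enumerate(config.proteins):
        chrom = _CHROMS[i % len(_CHROMS)]
        start = (i // len(_CHROMS)) * _GENE_SPACING + 20_000
        rows.append((prot, chrom, start, start + _GENE_LENGTH))
    return pd.DataFrame(rows, columns=["protein", "chrom", "start", "end"])


def generate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fully homozygous biallelic genotypes for every line, plus gene spans.

    Returns (genotypes, gene_spans). Genotype codes are 0 (reference
    homozygote) or 2 (alternative homozygote); the alternative allele is the
    minor one by construction. SNPs planted as cis-pQTLs are placed inside
    their target gene; all positions are strictly increasing per chromosome.
    """
    if rng is None:
        rng = _substreams(config.seed)["genotypes"]
    spans = gene_span_table(config)
    n = config.n_snps
    if n == 0:
        cols = ["snp_id", "chrom", "pos", "ref", "alt", *config.lines]
        return pd.DataFrame(columns=cols), spans

    chrom_extent = {
        c: int(spans.loc[spans["chrom"] == c, "end"].max() + 20_000) if (spans["chrom"] == c).any() else 100_000
        for c in _CHROMS
    }
    chroms = np.array([_CHROMS[i] for i in rng.integers(0, len(_CHROMS), size=n)], dtype=object)
    pos = np.array([rng.integers(1, chrom_extent[c]) for c in chroms])
    # planted cis-SNPs sit mid-gene so the +-10 kb window always contains them
    for q in config.planted_pqtls:
        g = spans.iloc[q.protein]
        chroms[q.snp] = g["chrom"]
        pos[q.snp] = int((g["start"] + g["end"]) // 2) + 1  # 1-based
    # enforce strictly increasing positions within each chromosome by
    # resampling collisions deterministically
    for c in _CHROMS:
        idx = np.flatnonzero(chroms == c)
        seen = set()
        for i in idx:
            while pos[i] in seen:
                pos[i] += 1
            seen.add(int(pos[i]))

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n)]
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    codes = np.zeros((n, config.n_lines), dtype=int)
    for j in range(n):
        k = int(round(mafs[j] * config.n_lines))
        k = max(1, min(k, config.n_lines // 2))
        carriers = rng.choice(config.n_lines, size=k, replace=False)
        codes[j, carriers] = 2

    out = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:05d}" for j in range(n)],
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
        }
    )
    for i, line in enumerate(config.lines):
        out[line] = codes[:, i]
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return out, spans


def _module_assignments(config: SimulationConfig) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    start = 0
    for m, spec in enumerate(config.planted_modules):
        out[f"module{m + 1}"] = config.proteins[start : start + spec.size]
        start += spec.size
    return out


def generate_truth(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw latent factors, true protein profiles, peptide map and pQTL shifts.

    Module members load on a shared per-line factor so that the expected
    pairwise correlation of their line profiles equals ``within_rho``; planted
    pQTL shifts are calibrated so the noise-free standardized difference
    between genotype classes equals the configured Cohen's d exactly.
    """
    if rng is None:
        rng = _substreams(config.seed)["truth"]
    lines = config.lines
    proteins = config.proteins
    modules = _module_assignments(config)

    # module factors are drawn exactly uncorrelated across lines (QR of a
    # centered Gaussian draw): planted modules represent distinct latent
    # processes, so their between-module correlation is 0 by construction
    n_mod = len(modules)
    if n_mod and n_mod < config.n_lines:
        raw = rng.standard_normal((config.n_lines, n_mod))
        raw -= raw.mean(axis=0)
        q, r = np.linalg.qr(raw)
        fac = (q * np.sign(np.diag(r))) * np.sqrt(config.n_lines - 1)
    else:
        fac = rng.standard_normal((config.n_lines, n_mod))
    factors = pd.DataFrame(fac.T, index=list(modules), columns=lines)
    body = pd.Series(rng.standard_normal(config.n_lines), index=lines, name="body")

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_proteins)
    sex_shift = rng.normal(0.0, config.sex_dimorphism[1], size=config.n_proteins)
    # co-regulated module members respond to sex as a unit: one shared shift
    # per module, so the planted within-module correlation holds over the
    # pooled line/sex samples used downstream
    module_sex_shift = rng.normal(0.0, config.sex_dimorphism[1], size=max(len(modules), 1))
    noise = rng.standard_normal((config.n_proteins, config.n_lines))

    line_part = np.empty((config.n_proteins, config.n_lines))
    sign = pd.Series(0.0, index=proteins, name="sign")
    member_of = {p: m for m, ms in modules.items() for p in ms}
    for i, prot in enumerate(proteins):
        if prot in member_of:
            m = member_of[prot]
            mi = int(m[len("module") :]) - 1
            spec = config.planted_modules[mi]
            rho = spec.within_rho
            line_part[i] = config.line_sd * (
                np.sqrt(rho) * factors.loc[m].to_numpy() + np.sqrt(1.0 - rho) * noise[i]
            )
            sex_shift[i] = module_sex_shift[mi]
            sign[prot] = float(np.sign(spec.size_effect))
        else:
            line_part[i] = config.line_sd * noise[i]

    # planted pQTL shifts: move minor-allele carrier lines so that the
    # standardized class difference equals d exactly (identically in both
    # sexes, since the sex shift is constant within a protein)
    pq_rows = []
    geno_lines = genotypes[lines].to_numpy() if len(genotypes) else np.empty((0, len(lines)))
    for q in config.planted_pqtls:
        snp_row = genotypes.index[genotypes["snp_id"] == f"snp{q.snp + 1:05d}"]
        if len(snp_row) == 0:
            continue
        codes = geno_lines[snp_row[0]]
        minor = codes == 2
        vals = line_part[q.protein]
        n1, n0 = int(minor.sum()), int((~minor).sum())
        s1 = vals[minor].std(ddof=1) if n1 > 1 else 0.0
        s0 = vals[~minor].std(ddof=1) if n0 > 1 else 0.0
        pooled = np.sqrt(((n1 - 1) * s1**2 + (n0 - 1) * s0**2) / max(n1 + n0 - 2, 1))
        if pooled == 0:
            pooled = config.line_sd
        shift = q.cohens_d * pooled - (vals[minor].mean() - vals[~minor].mean())
        line_part[q.protein, minor] += shift
        pq_rows.append((proteins[q.protein], f"snp{q.snp + 1:05d}", q.cohens_d))

    cols = [f"{ln}_{sx}" for ln in lines for sx in ("F", "M")]
    levels = np.empty((config.n_proteins, len(cols)))
    for j, col in enumerate(cols):
        ln, sx = col.rsplit("_", 1)
        li = lines.index(ln)
        levels[:, j] = baseline + line_part[:, li] + (sex_shift if sx == "M" else 0.0)
    protein_levels = pd.DataFrame(levels, index=proteins, columns=cols)

    # peptide map with additive ionization offsets
    lo, hi = config.peptides_per_protein
    pep_counts = rng.integers(lo, hi + 1, size=config.n_proteins)
    pep_ids, pep_prot = [], []
    for i, prot in enumerate(proteins):
        for k in range(pep_counts[i]):
            pep_ids.append(f"pep_{prot}_{k + 1:02d}")
            pep_prot.append(prot)
    offsets = pd.Series(
        rng.normal(0.0, config.peptide_offset_sd, size=len(pep_ids)), index=pep_ids, name="offset"
    )
    peptide_protein = pd.Series(pep_prot, index=pep_ids, name="protein")

    # coding-variant peptides: only from multi-peptide proteins, each tagged
    # by one SNP whose minor-allele lines are the carriers
    multi = peptide_protein[peptide_protein.map(peptide_protein.value_counts()) > 1]
    n_coding = int(round(config.coding_dropout_fraction * len(pep_ids)))
    n_coding = min(n_coding, len(multi))
    coding = pd.Series(dtype=object)
    if n_coding > 0 and len(genotypes) > 0:
        chosen = rng.choice(multi.index.to_numpy(), size=n_coding, replace=False)
        snp_ids = genotypes["snp_id"].to_numpy()
        tags = rng.choice(snp_ids, size=n_coding, replace=len(snp_ids) < n_coding)
        coding = pd.Series(tags, index=chosen, name="snp_id")

    truth = GroundTruth(
        protein_levels=protein_levels,
        peptide_offsets=offsets,
        peptide_protein=peptide_protein,
        module_membership=modules,
        size_associated=sign[sign != 0],
        pqtls=pd.DataFrame(pq_rows, columns=["protein", "snp", "cohens_d"]),
        module_factors=factors,
        body_factor=body,
        coding_peptides=coding,
    )
    truth.validate()
    return truth


def generate_phenotypes(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per line/sex morphometrics generated from the additive size model.

    raw CS = intercept + sex + foodbatch + inversions + body-size component
    + module (protein-mediated) components + noise; IOD tracks the latent
    body-size factor so relative size can be body-adjusted downstream.
    """
    if rng is None:
        rng = _substreams(config.seed)["phenotypes"]
    lines = config.lines
    fb_effects = rng.normal(0.0, config.foodbatch_sd, size=config.foodbatch_levels)
    fb_effects -= fb_effects.mean()
    inv_counts = rng.choice([0, 1, 2], p=[0.6, 0.3, 0.1], size=(config.n_lines, len(config.inversion_effects)))

    rows = []
    for li, ln in enumerate(lines):
        batch = li % config.foodbatch_levels
        gi = float(np.dot(inv_counts[li], config.inversion_effects))
        mod = sum(
            spec.size_effect * truth.module_factors.iloc[m, li]
            for m, spec in enumerate(config.planted_modules)
        )
        for sx in ("F", "M"):
            male = 1.0 if sx == "M" else 0.0
            cs = (
                _CS_MEAN
                + config.sex_dimorphism[0] * male
                + fb_effects[batch]
                + gi
                + config.cs_body_coef * truth.body_factor.iloc[li]
                + mod
                + rng.normal(0.0, config.cs_noise_sd)
            )
            iod = (
                _IOD_MEAN
                + _IOD_SEX_SHIFT * male
                + _IOD_BODY_COEF * truth.body_factor.iloc[li]
                + rng.normal(0.0, _IOD_NOISE_SD)
            )
            row = {"line": ln, "sex": sx, "raw_cs": cs, "iod": iod, "foodbatch": batch + 1}
            for k in range(len(config.inversion_effects)):
                row[f"inversion_{k + 1}"] = int(inv_counts[li, k])
            rows.append(row)
    return pd.DataFrame(rows)


def generate_intensities(
    config: SimulationConfig,
    truth: GroundTruth,
    genotypes: pd.DataFrame,
    rng: np.random.Generator | None = None,
    apply_mnar: bool = True,
    apply_coding_dropout: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw peptide x sample intensity matrix and its sample design table.

    log2 intensity(p, s) = true protein level(line, sex of s) + peptide
    offset(p) + replicate noise. Coding-variant peptides are entirely missing
    in all samples of carrier lines and fully present elsewhere; MNAR dropout
    removes low-intensity observations with logistic probability. Returned
    intensities are on the raw linear scale (2**log2), NaN for missing.
    """
    if rng is None:
        rng = _substreams(config.seed)["intensities"]
    design = pd.DataFrame(
        [
            {"sample_id": f"{ln}_{sx}{r + 1}", "line": ln, "sex": sx, "replicate": r + 1}
            for ln in config.lines
            for sx in ("F", "M")
            for r in range(config.n_replicates)
        ]
    )
    peptides = truth.peptide_offsets.index
    prot_idx = truth.protein_levels.index.get_indexer(truth.peptide_protein.to_numpy())
    col_idx = truth.protein_levels.columns.get_indexer(
        [f"{ln}_{sx}" for ln, sx in zip(design["line"], design["sex"])]
    )
    base = truth.protein_levels.to_numpy()[np.ix_(prot_idx, col_idx)]
    log2 = base + truth.peptide_offsets.to_numpy()[:, None]
    if config.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, config.noise_sd, size=log2.shape)

    mnar_mask = np.zeros(log2.shape, dtype=bool)
    if apply_mnar:
        p_drop = 1.0 / (1.0 + np.exp((log2 - config.mnar_threshold) / config.mnar_scale))
        mnar_mask = rng.random(log2.shape) < p_drop

    coding_mask = np.zeros(log2.shape, dtype=bool)
    if apply_coding_dropout and len(truth.coding_peptides) > 0 and len(genotypes) > 0:
        geno = genotypes.set_index("snp_id")
        sample_lines = design["line"].to_numpy()
        for pep, snp in truth.coding_peptides.items():
            carriers = set(
                ln for ln in config.lines if geno.loc[snp, ln] == 2
            )
            i = peptides.get_loc(pep)
            coding_mask[i] = np.array([ln in carriers for ln in sample_lines])

    values = np.power(2.0, log2)
    values[mnar_mask | coding_mask] = np.nan
    matrix = pd.DataFrame(values, index=peptides, columns=design["sample_id"].to_numpy())
    truth.dropout_provenance = {
        "mnar": pd.DataFrame(mnar_mask, index=peptides, columns=matrix.columns),
        "coding": pd.DataFrame(coding_mask, index=peptides, columns=matrix.columns),
    }
    return matrix, design


def _generate_edges(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Interaction edge list: high-confidence edges inside planted modules,
    plus low-confidence background noise edges."""
    rows = []
    for members in truth.module_membership.values():
        for i in range(len(members) - 1):
            rows.append((members[i], members[i + 1], float(rng.uniform(0.9, 0.999))))
    prots = config.proteins
    n_bg = min(4 * config.n_proteins, 2000)
    for _ in range(n_bg):
        a, b = rng.choice(len(prots), size=2, replace=False)
        rows.append((prots[a], prots[b], float(rng.uniform(0.15, 0.89))))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])


def generate_bundle(config: SimulationConfig | None = None, **overrides) -> StudyBundle:
    """Generate a full synthetic study bundle from one seed."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    rngs = _substreams(config.seed)
    genotypes, spans = generate_genotypes(config, rngs["genotypes"])
    truth = generate_truth(config, genotypes, rngs["truth"])
    phenotypes = generate_phenotypes(config, truth, rngs["phenotypes"])
    intensities, design = generate_intensities(config, truth, genotypes, rngs["intensities"])
    edges = _generate_edges(config, truth, rngs["edges"])
    return StudyBundle(
        config=config,
        intensities=intensities,
        design=design,
        phenotypes=phenotypes,
        genotypes=genotypes,
        gene_spans=spans,
        edges=edges,
        truth=truth,
    )
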