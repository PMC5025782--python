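# Methods

`wingpwas` re-implements, as a tested pipeline on synthetic data, a
proteome-wide association study (PWAS) of a quantitative size phenotype:
wing imaginal disc proteomes of highly inbred *Drosophila* lines, quantified
by data-independent-acquisition (SWATH-type) mass spectrometry, associated
with adult wing centroid size, organized into co-variation modules, and
mapped against cis genetic variants.

## The measurement model

The entry point is a peptide × sample matrix of raw intensities with an
explicit missing mask. The pipeline assumes the standard additive model on
the log2 scale: the observed intensity of peptide *p* in sample *s* is

    log2 I(p, s) = protein level(line(s), sex(s)) + peptide offset(p) + ε,

where the peptide offset captures ionization efficiency (an "MS feature"),
the protein level is the "biological feature" shared by all of an entry's
peptides, and ε is replicate-level technical noise. Two missingness
mechanisms are distinct in kind:

* **Coding-variant dropout.** Inbred lines are homozygous, so a peptide
  overlapping a coding polymorphism is entirely absent in carrier lines and
  fully present elsewhere — an all-or-nothing pattern per (peptide, line).
  The protein is still quantified in carriers from its other peptides.
* **Missing-not-at-random (MNAR) low-intensity dropout.** Signals near the
  detection limit are unreliable and are treated as missing. The simulator
  models this with a logistic dropout probability in log2 intensity
  (`mnar_threshold`, `mnar_scale`); the real mechanism is only known to be
  intensity-dependent, so these two parameters are stated simulator choices,
  not estimates.

## Pipeline stages

1. **Peptide QC** (`peptides`). log2 transform; per-sample median centering
   to a common target defined as the median of the per-sample medians (the
   centering convention is recorded in `DataFrame.attrs`); removal of
   peptides missing in strictly more than 20% of samples (retained iff
   missing count ≤ floor(0.2·n); over 120 samples this keeps peptides
   observed in ≥96); pairwise Spearman reproducibility with pairs labelled
   replicate (same line and sex) or non-replicate, average ranks on ties,
   pairs with <3 shared observations flagged and excluded from medians. A
   sample exclusion list supports dropping failed acquisitions.
2. **Protein roll-up** (`proteins`). Peptides are grouped into *entries* by
   their annotation signature: a unique protein, numbered entries for
   annotated variants of one protein with distinct peptide sets, or one
   combined entry for isoforms sharing an identical peptide set. Each entry
   is fit by least squares with two additive factors, peptide and biological
   sample (line × sex), on the observed cells; replicate scatter estimates
   the error variance and an F-test scores the biological term. The entry
   level per line/sex is the mean of the fitted cell values over constituent
   peptides, so peptide offsets cancel from every between-sample difference
   (the model's reason for existing: it tolerates the structured missingness
   above, where a naive peptide mean would not). Dummy coding is used
   internally; fitted cell values, and hence levels up to a constant, are
   invariant to the coding choice. Biological samples observed for no
   peptide are flagged unquantifiable and left missing, not imputed.
3. **Phenotype derivation** (`phenotype`). Raw centroid size (CS) is the
   root-summed-squared distance of 14 wing landmarks from their centroid.
   *Absolute CS* removes fitted foodbatch and inversion (0/1/2 copy-coded)
   effects but retains sex; fitted contributions are centered before
   subtraction so the grand mean is preserved (the adjustment is only
   identifiable up to a constant). *Relative CS* is the residual of
   CS ~ IOD + sex + foodbatch, i.e. wing size relative to body size, with
   interocular distance (IOD) as the body proxy. Lines are classified
   big/small by the sign of the line-mean relative CS (sexes averaged; ties
   to small) — a single call per line needs the sexes combined, and the
   sign of the mean is the simplest symmetric rule.
4. **Association scan** (`pwas`). Per entry: relative CS = sex + level + ε,
   and absolute CS = level + ε (a simple regression, since the sex
   dimorphism is deliberately retained in that trait). Two-sided t-tests on
   the protein slope, complete pairs per entry with n recorded, constant
   entries flagged and excluded from correction, Benjamini–Hochberg step-up
   across entries with the 5% FDR default. A sex × protein interaction
   check accompanies the relative model.
5. **Dimension reduction** (`dimred`). Centered, unscaled PCA and
   single-response PLS (NIPALS as in scikit-learn) on complete-case entries
   only. Trait variance explained is the incremental R² of the trait on the
   leading scores; matrix variance uses the rank-one reconstruction per
   component. Components are sign-fixed to correlate positively with the
   trait. Unit-variance scaling is available by flag but off by default —
   log2 levels are already on one scale.
6. **Co-variation network** (`network`). Among trait-associated entries:
   complete-linkage hierarchical clustering on 1 − |ρ| (Spearman over the 60
   pooled line/sex samples), tree cut at height 0.6 so every within-module
   pair has |ρ| ≥ 0.4 — a cut chosen as the |ρ| whose two-sided t-test
   p-value at n = 60 is ≈ 0.001. Interaction edges with confidence score
   ≥ 0.9 (boundary inclusive — the "highest confidence" preset means score
   at or above 0.9; 0–1000-scaled scores auto-rescaled) are merged as a
   second edge class; edges touching non-network proteins are dropped.
   Modules are summarized by the first PC of their centered member profiles
   (sign-aligned to positive mean member correlation), clustered at a
   second complete-linkage cut (default height 0.6, a package default, on
   the same 1 − |ρ| scale), and correlated (signed and absolute Spearman)
   with absolute CS, relative CS and IOD.
7. **cis-pQTL mapping** (`pqtl`). For each entry: homozygous SNPs within
   ±10 kb of the gene span (BED input converted to 1-based inclusive;
   boundary SNPs included) with MAF strictly >10% over non-missing analyzed
   lines. Kruskal–Wallis per sex with tie correction; classes under two
   lines are skipped. Family-wise correction by the permutation null of the
   minimum p: one shared stream of within-sex line-label permutations is
   applied to the whole level matrix (preserving cross-entry
   comparability), every cis test re-run per permutation, and
   corrected p = #(permutation minima < observed minimum)/n_perm with
   strict inequality and no smoothing, so 0 is attainable. Defaults
   n_perm = 10,000; thresholds 0.01 and 0.05 are both flagged. Effect size
   is Cohen's d with the *pooled* s.d. (the source procedure says only
   "the s.d."; the pooled choice is recorded in output metadata and
   switchable), recomputed on the opposite sex and on per-line absolute CS;
   a two-sided Wilcoxon rank-sum test compares protein and wing-size
   effect-size samples to quantify attenuation toward the phenotype.
8. **Per-cell conversion** (`cells`). Trichome count in a fixed
   10⁴ μm² square gives single-cell area (10⁴/count), total cell number
   (wing area / cell area) and relative volume (area^{3/2}). Whole-proteome
   normalization divides by total protein, so a constant-per-cell protein
   looks depleted in big cells; multiplying the linear-scale level by
   relative volume undoes this (the two-cell worked identity: Y/2 × 2X and
   Y × X both give XY). Volumes are mean-normalized before conversion (a
   pure rescaling) unless disabled.

## The synthetic-data generator

`simulate.generate_bundle` emulates the study design: 30 lines × 2 sexes ×
2 biological replicates (120 samples), fully homozygous biallelic SNPs with
per-SNP MAF drawn in (0.10, 0.50], genes tiled deterministically over three
chromosome arms, protein entries of 1–20 peptides with Gaussian ionization
offsets (s.d. 1.5 log2), baseline abundance N(14, 1.5²) log2, between-line
biological s.d. 0.25 log2 per protein (≈19% fold change, matching the
low-variability regime of the tissue), replicate noise 0.15 log2 (chosen so
replicate Spearman ≈ 0.99 against non-replicate ≈ 0.97), four foodbatches,
two inversions with per-copy CS shifts, male CS shift −25 centroid-size
units, and a latent body-size factor driving both IOD and CS.

Planted structure, recorded in `GroundTruth`:

* **Modules.** Each module has a latent per-line factor; members load
  √ρ on it so their pairwise correlation targets `within_rho`. Factors are
  drawn exactly uncorrelated across lines (QR of a centered Gaussian draw):
  modules represent distinct latent processes, and over only 30 lines
  independently drawn factors would correlate by chance (|r| up to ~0.5),
  which is between-module structure the ground truth does not intend.
  Members share one module-level sex-response shift — co-regulated proteins
  respond to sex as a unit — so the correlation target also holds over the
  pooled line/sex samples that downstream clustering uses. Module factors
  enter raw CS with the configured signed slope, making the
  protein–phenotype association correlational (shared latent cause), not
  mechanistic, as in an observational study.
* **cis-pQTLs.** A planted (protein, SNP, d) triple relocates the SNP into
  the protein's cis window and shifts minor-allele carrier lines so the
  noise-free standardized class difference equals d exactly in both sexes.
* **Dropout provenance.** Coding-variant peptides (a configured fraction,
  only from multi-peptide proteins) are tagged with one SNP each; MNAR and
  coding masks are kept separately.

One global seed expands into fixed-order substreams (genotypes, truth,
phenotypes, intensities, edges), so bundles are bit-reproducible and stages
can be regenerated independently.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: linkage disequilibrium (SNPs are
independent), retention-time or spectral-level artifacts, batch effects in
the MS acquisition, correlated measurement error between peptides of one
protein, non-additive peptide behavior (interference, saturation), and any
real biological pathway structure behind the modules.

## Numerical choices and degenerate inputs

* All least-squares fits use SVD-based `lstsq`; rank-deficient designs take
  the minimum-norm solution, and estimable quantities (fitted cells, level
  differences) are checked against normal-equations oracles at 1e-9.
* Spearman ties use average ranks everywhere; the Kruskal–Wallis statistic
  carries the standard tie correction and reduces exactly to the squared
  standardized rank-sum statistic for two groups.
* BH q-values follow the step-up running-minimum form, capped at 1; NaN
  p-values (flagged entries) propagate without counting toward m.
* Permutation correction uses strict inequality per the source formula;
  with n_perm < 100 a resolution warning is raised.
* Constant entries, constant IOD, empty cis windows, sub-minimal class
  sizes and degenerate (constant) modules are flagged or skipped rather
  than producing numbers.

## Problem sizes

Simulated studies in the test-suite and the acceptance script use 300
proteins (~3,000 peptides) for the full-pipeline bundle and 8–60 proteins
for focused experiments; these sizes give stable estimates of every
reported quantity while keeping a complete run in minutes on one core. The
module-recovery experiment plants three 20-member modules at within-module
ρ = 0.9 with sex-neutral abundance so the planted between-module
correlation is zero; at pooled-sample complete linkage with the 0.4 cut,
recovery is then exact. At within ρ near 0.7 the minimum pairwise *sample*
correlation among 190 member pairs regularly dips below the cut, so
complete linkage — by design — splits such modules; perfect recovery is a
property of well-separated planted structure, not of the threshold.

## Known limitations

* The roll-up assumes every peptide of an entry tracks one abundance
  profile; proteoforms that genuinely diverge would be averaged.
* Associations are marginal per-entry regressions without kinship or
  relatedness adjustment (lines are treated as exchangeable).
* The permutation scheme shuffles lines within sex; it preserves the
  genotype LD structure (trivial here) but not any line-level covariates
  beyond sex.
* With 28 lines the pQTL scan only has power for large effects; this
  matches the source study's own regime (all reported effects were large,
  d > 0.8).
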