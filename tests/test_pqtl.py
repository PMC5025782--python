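"""cis-window selection, Kruskal-Wallis identities, permutation min-p
correction against exhaustive enumeration, and effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wingpwas import pqtl
from wingpwas.simulate import ModuleSpec, PqtlSpec, SimulationConfig, generate_bundle


def _geno(lines, rows):
    """rows: (snp_id, chrom, pos, codes)."""
    out = pd.DataFrame(
        [(r[0], r[1], r[2], "A", "T") for r in rows],
        columns=["snp_id", "chrom", "pos", "ref", "alt"],
    )
    for i, ln in enumerate(lines):
        out[ln] = [r[3][i] for r in rows]
    return out


class TestCisSelection:
    def test_window_boundary_at_10kb(self):
        lines = [f"l{i}" for i in range(10)]
        codes = [0] * 5 + [2] * 5
        # gene span BED [30000, 33000) -> 1-based [30001, 33000]
        spans = pd.DataFrame([("g1", "2L", 30_000, 33_000)], columns=["protein", "chrom", "start", "end"])
        rows = [
            ("in_edge", "2L", 20_001, codes),   # exactly 10 kb upstream of 30001
            ("out_edge", "2L", 20_000, codes),  # 10,001 bp upstream
            ("in_down", "2L", 43_000, codes),   # exactly 10 kb downstream of 33000
            ("out_down", "2L", 43_001, codes),
            ("wrong_chrom", "2R", 31_000, codes),
        ]
        cis = pqtl.select_cis_snps(_geno(lines, rows), spans, lines)
        assert cis["g1"] == ["in_edge", "in_down"]

    def test_maf_strictly_above_10_percent(self):
        lines = [f"l{i}" for i in range(28)]
        spans = pd.DataFrame([("g1", "2L", 0, 3_000)], columns=["protein", "chrom", "start", "end"])
        three = [2] * 3 + [0] * 25  # 3/28 = 0.107 > 0.10
        two = [2] * 2 + [0] * 26  # 0.071
        rows = [("snp3", "2L", 100, three), ("snp2", "2L", 200, two)]
        cis = pqtl.select_cis_snps(_geno(lines, rows), spans, lines)
        assert cis["g1"] == ["snp3"]

    def test_empty_window_gives_empty_set(self):
        lines = ["l0", "l1", "l2", "l3"]
        spans = pd.DataFrame([("g1", "3R", 10**7, 10**7 + 100)], columns=["protein", "chrom", "start", "end"])
        rows = [("snp1", "2L", 100, [0, 0, 2, 2])]
        cis = pqtl.select_cis_snps(_geno(lines, rows), spans, lines)
        assert cis["g1"] == []


class TestKruskalWallis:
    def test_identical_distributions_give_h_near_zero(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        c = np.array([0, 0, 0, 2, 2, 2])
        h, p = pqtl.kw_test(v, c)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_matches_hand_rank_arithmetic(self):
        # 14 vs 14 perfectly separated: rank sums 105 and 301
        v = np.concatenate([np.arange(14.0), np.arange(14.0) + 100.0])
        c = np.array([0] * 14 + [2] * 14)
        h, _ = pqtl.kw_test(v, c)
        n = 28
        h_hand = 12.0 / (n * (n + 1)) * (105.0**2 / 14 + 301.0**2 / 14) - 3 * (n + 1)
        assert h == pytest.approx(h_hand, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_including_ties(self, seed):
        r = np.random.default_rng(seed)
        v = np.round(r.standard_normal(30), 1)  # rounding forces ties
        c = r.choice([0, 2, 4], size=30)
        while min((c == g).sum() for g in np.unique(c)) < 2:
            c = r.choice([0, 2, 4], size=30)
        h, p = pqtl.kw_test(v, c)
        ref = stats.kruskal(*[v[c == g] for g in np.unique(c)])
        assert h == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_two_group_rank_sum_chi2_identity(self, rng):
        """For two groups the KW statistic equals the squared standardized
        Mann-Whitney U (tie-corrected, no continuity correction)."""
        v = rng.standard_normal(20)
        c = np.array([0] * 9 + [2] * 11)
        h, p = pqtl.kw_test(v, c)
        # independent z from the rank-sum statistic
        ranks = stats.rankdata(v)
        n1, n2 = 9, 11
        w = ranks[c == 0].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        sigma2 = n1 * n2 * (n1 + n2 + 1) / 12.0
        z = (w - mu) / np.sqrt(sigma2)
        assert h == pytest.approx(z**2, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(z**2, 1), abs=1e-9)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            pqtl.kw_test(np.arange(5.0), np.array([0, 0, 0, 0, 2]))


class TestPermutationCorrection:
    def _toy(self):
        lines = [f"l{i}" for i in range(6)]
        rows = [
            ("s1", "2L", 100, [0, 0, 0, 2, 2, 2]),
            ("s2", "2L", 200, [0, 0, 2, 2, 0, 2]),
            ("s3", "2L", 300, [2, 0, 2, 0, 2, 0]),
        ]
        geno = _geno(lines, rows)
        levels = pd.DataFrame(
            [[0.1, 0.4, 0.2, 1.9, 2.2, 2.4]], index=["e1"], columns=lines
        )
        cis = {"e1": ["s1", "s2", "s3"]}
        return levels, geno, cis

    def test_sampled_corrected_p_matches_exhaustive_enumeration(self):
        """6-line toy: all 720 label permutations are enumerable; the sampled
        corrected p at 10,000 draws must sit within 3 s.e. of the exact value."""
        levels, geno, cis = self._toy()
        v = levels.loc["e1"].to_numpy()
        snp_codes = [geno.set_index("snp_id").loc[s, levels.columns].to_numpy(dtype=float) for s in cis["e1"]]

        def min_p(values):
            ps = []
            for codes in snp_codes:
                groups = [values[codes == g] for g in np.unique(codes)]
                ps.append(stats.kruskal(*groups).pvalue)
            return min(ps)

        obs = min_p(v)
        exact_minima = [min_p(np.asarray(perm)) for perm in itertools.permutations(v)]
        exact = np.mean([m < obs for m in exact_minima])
        res = pqtl.permutation_correct(levels, geno, cis, n_perm=10_000, rng=7)
        sampled = res.loc["e1", "corrected_p"]
        se = np.sqrt(exact * (1 - exact) / 10_000) if 0 < exact < 1 else 1e-4
        assert abs(sampled - exact) <= max(3 * se, 0.005)

    def test_extreme_observed_p_gives_corrected_zero(self):
        levels, geno, cis = self._toy()
        res = pqtl.permutation_correct(levels, geno, cis, n_perm=2_000, rng=3)
        # s1 splits the levels perfectly: no permutation can beat it often
        assert res.loc["e1", "corrected_p"] < 0.2
        assert res.loc["e1", "best_snp"] == "s1"

    def test_corrected_p_monotone_in_observed_min_p(self):
        """Entries sharing one cis set and permutation stream must have
        corrected p ordered like their observed minimum p."""
        lines = [f"l{i}" for i in range(12)]
        r = np.random.default_rng(11)
        codes = np.array([0] * 6 + [2] * 6)
        geno = _geno(lines, [("s1", "2L", 100, list(codes))])
        base = r.standard_normal(12)
        levels = pd.DataFrame(
            [base + codes * s for s in (0.0, 0.3, 0.8)],
            index=["weak", "mid", "strong"],
            columns=lines,
        )
        cis = {e: ["s1"] for e in levels.index}
        res = pqtl.permutation_correct(levels, geno, cis, n_perm=3_000, rng=5)
        ordered = res.sort_values("min_p")
        assert (ordered["corrected_p"].diff().dropna() >= 0).all()

    def test_null_corrected_p_approximately_uniform(self):
        """A truly null entry's corrected p has mean ~0.5 across seeds."""
        lines = [f"l{i}" for i in range(28)]
        codes_a = [0] * 14 + [2] * 14
        codes_b = ([0, 2] * 14)[:28]
        geno = _geno(lines, [("s1", "2L", 100, codes_a), ("s2", "2L", 200, codes_b)])
        cis = {"e1": ["s1", "s2"]}
        vals = []
        for seed in range(50):
            r = np.random.default_rng(900 + seed)
            levels = pd.DataFrame([r.standard_normal(28)], index=["e1"], columns=lines)
            res = pqtl.permutation_correct(levels, geno, cis, n_perm=400, rng=r)
            vals.append(res.loc["e1", "corrected_p"])
        assert 0.40 <= np.mean(vals) <= 0.60


class TestEffectSize:
    def test_closed_forms(self):
        v = np.array([0.0, 1.0, 0.0, 1.0])  # identical class means
        c = np.array([0, 0, 2, 2])
        assert pqtl.effect_size(v, c) == pytest.approx(0.0)
        v2 = np.array([-1.0, 1.0, 0.0, 2.0])  # means 0 and 1, pooled sd sqrt(2)
        assert pqtl.effect_size(v2, c) == pytest.approx(1.0 / np.sqrt(2.0))

    def test_affine_invariance(self, rng):
        v = rng.standard_normal(20)
        c = np.array([0] * 8 + [2] * 12)
        d = pqtl.effect_size(v, c)
        assert pqtl.effect_size(3.5 * v + 11.0, c) == pytest.approx(d, abs=1e-12)

    def test_zero_pooled_sd_flagged(self):
        v = np.array([1.0, 1.0, 2.0, 2.0])
        c = np.array([0, 0, 2, 2])
        assert np.isnan(pqtl.effect_size(v, c))


def _pqtl_bundle(seed, d=2.0, protein=0):
    return generate_bundle(
        SimulationConfig(
            seed=seed,
            n_lines=28,
            n_proteins=8,
            n_snps=40,
            peptides_per_protein=(3, 5),
            planted_modules=[],
            planted_pqtls=[PqtlSpec(protein, 0, d)],
            coding_dropout_fraction=0.0,
        )
    )


def test_planted_pqtl_recovered_in_both_sexes():
    b = _pqtl_bundle(seed=31)
    levels = b.truth.protein_levels  # noise-free levels isolate the mapping stage
    res = pqtl.map_pqtls(levels, b.genotypes, b.gene_spans, n_perm=2_000, rng=1)
    hit = res[res["entry_id"] == "prot0001"]
    assert len(hit) == 2
    assert (hit["corrected_p"] < 0.05).all()
    assert (hit["effect_size"] > 1.0).all()
    # equal generative effect in both sexes: opposite-sex d close to own d
    np.testing.assert_allclose(
        hit["effect_size"].to_numpy(), hit["opposite_sex_effect_size"].to_numpy(), rtol=1e-6
    )


def test_cross_effects_wing_size_attenuation():
    """A pQTL with no generative path to wing size shows small wing-size
    effect sizes, and identical effect-size lists give Wilcoxon p = 1."""
    wing_ds = []
    for seed in (41, 42, 43, 44, 45):
        b = _pqtl_bundle(seed=seed, protein=5)  # protein outside any module
        levels = b.truth.protein_levels
        res = pqtl.map_pqtls(levels, b.genotypes, b.gene_spans, n_perm=500, rng=2)
        hit = res[res["entry_id"] == "prot0006"]
        ph = b.phenotypes
        idx = pd.Index(ph["line"] + "_" + ph["sex"])
        from wingpwas import phenotype

        abs_cs = pd.Series(phenotype.absolute_cs(ph).to_numpy(), index=idx)
        out, p = pqtl.cross_effects(hit, abs_cs, b.genotypes)
        wing_ds.extend(out["wing_size_effect_size"].tolist())
    assert np.median(wing_ds) < 0.8  # below the 'large' convention
    same = pd.DataFrame(
        {
            "sex": ["F", "F"],
            "best_snp": ["s1", "s1"],
            "effect_size": [1.0, 2.0],
            "wing_size_effect_size": [np.nan, np.nan],
        }
    )
    assert stats.ranksums([1.0, 2.0], [1.0, 2.0]).pvalue == pytest.approx(1.0)
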