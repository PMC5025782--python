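"""Entry classification and model-based roll-up against explicit
normal-equations oracles and generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from wingpwas import proteins
from wingpwas.simulate import SimulationConfig, generate_bundle


def _design(samples, lines, sexes, reps):
    return pd.DataFrame({"sample_id": samples, "line": lines, "sex": sexes, "replicate": reps})


class TestClassifyEntries:
    def test_disjoint_proteins_are_unique_entries(self):
        mapping = {"p1": ("A",), "p2": ("A",), "p3": ("B",), "p4": ("C",)}
        t = proteins.classify_entries(mapping)
        assert (t["entry_class"] == "unique").all()
        assert sorted(t["entry_id"]) == ["A", "B", "C"]

    def test_isoforms_sharing_peptides_form_one_combined_entry(self):
        mapping = {"p1": ("X-PA", "X-PB"), "p2": ("X-PA", "X-PB")}
        t = proteins.classify_entries(mapping)
        assert len(t) == 1
        assert t["entry_class"].iloc[0] == "isoform-group"
        assert t["entry_id"].iloc[0] == "X-PA+X-PB"

    def test_variants_with_distinct_peptide_sets_get_numbered_entries(self):
        mapping = {"p1": ("Y-PA",), "p2": ("Y-PA",), "p3": ("Y-PB",)}
        t = proteins.classify_entries(mapping)
        assert len(t) == 2
        assert set(t["entry_class"]) == {"numbered-variant"}
        assert set(t["entry_id"]) == {"Y#1", "Y#2"}

    def test_unmapped_peptide_is_an_error(self):
        with pytest.raises(ValueError, match="zero proteins"):
            proteins.classify_entries({"p1": ()})

    def test_every_peptide_lands_in_exactly_one_entry(self):
        mapping = {"p1": ("A",), "p2": ("A", "B"), "p3": ("B",), "p4": ("A", "B")}
        t = proteins.classify_entries(mapping)
        all_peps = [p for peps in t["peptides"] for p in peps]
        assert sorted(all_peps) == ["p1", "p2", "p3", "p4"]


def _toy_unbalanced():
    """3 peptides x 4 biological samples, duplicate replicates, holes."""
    samples = [f"{b}_r{r}" for b in ("l1_F", "l1_M", "l2_F", "l2_M") for r in (1, 2)]
    design = _design(
        samples,
        [s.split("_")[0] for s in samples],
        [s.split("_")[1] for s in samples],
        [int(s[-1]) for s in samples],
    )
    rng = np.random.default_rng(0)
    alpha = np.array([0.0, 1.3, -0.7])
    beta = np.array([5.0, 4.2, 6.1, 5.5])
    vals = np.empty((3, 8))
    for i in range(3):
        for j in range(8):
            vals[i, j] = alpha[i] + beta[j // 2] + rng.normal(0, 0.1)
    m = pd.DataFrame(vals, index=["pep1", "pep2", "pep3"], columns=samples)
    m.iloc[0, 2] = np.nan
    m.iloc[2, 5] = np.nan
    m.iloc[1, 7] = np.nan
    return m, design


def _oracle_fit(m, design):
    """Independent normal-equations solve of the two-way additive model."""
    bio = {s: f"{l}_{x}" for s, l, x in zip(design.sample_id, design.line, design.sex)}
    bios = sorted({bio[c] for c in m.columns})
    peps = list(m.index)
    rows, y = [], []
    for i, p in enumerate(peps):
        for c in m.columns:
            v = m.loc[p, c]
            if np.isnan(v):
                continue
            row = np.zeros(1 + len(peps) - 1 + len(bios) - 1)
            row[0] = 1.0
            if i > 0:
                row[i] = 1.0
            b = bios.index(bio[c])
            if b > 0:
                row[len(peps) - 1 + b] = 1.0
            rows.append(row)
            y.append(v)
    X = np.array(rows)
    y = np.array(y)
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    alpha = np.concatenate([[0.0], coef[1 : len(peps)]])
    beta = np.concatenate([[0.0], coef[len(peps) :]])
    fitted = coef[0] + alpha[:, None] + beta[None, :]
    return pd.DataFrame(fitted, index=peps, columns=bios)


def test_rollup_matches_normal_equations_oracle():
    m, design = _toy_unbalanced()
    fit = proteins.fit_entry_model(m, design)
    oracle = _oracle_fit(m, design)
    np.testing.assert_allclose(
        fit.fitted[oracle.columns].to_numpy(), oracle.to_numpy(), atol=1e-9
    )
    levels = proteins.entry_levels(fit)
    np.testing.assert_allclose(
        levels[oracle.columns].to_numpy(), oracle.mean(axis=0).to_numpy(), atol=1e-9
    )


def test_noise_free_additive_data_recovered_exactly():
    samples = ["l1_F1", "l1_F2", "l2_F1", "l2_F2"]
    design = _design(samples, ["l1", "l1", "l2", "l2"], ["F"] * 4, [1, 2, 1, 2])
    alpha = np.array([0.0, 2.0])
    beta = {"l1_F": 3.0, "l2_F": 7.0}
    m = pd.DataFrame(
        [[alpha[i] + beta[f"l{1 + j // 2}_F"] for j in range(4)] for i in range(2)],
        index=["pepA", "pepB"],
        columns=samples,
    )
    fit = proteins.fit_entry_model(m, design)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)
    lv = proteins.entry_levels(fit)
    assert lv["l2_F"] - lv["l1_F"] == pytest.approx(4.0, abs=1e-12)
    assert fit.p_bio < 1e-12 or fit.p_bio == 0.0


def test_single_peptide_equal_replicates_returns_observations():
    samples = ["l1_F1", "l1_F2", "l2_F1", "l2_F2"]
    design = _design(samples, ["l1", "l1", "l2", "l2"], ["F"] * 4, [1, 2, 1, 2])
    m = pd.DataFrame([[5.0, 5.0, 9.0, 9.0]], index=["pep"], columns=samples)
    lv = proteins.entry_levels(proteins.fit_entry_model(m, design))
    assert lv["l1_F"] == pytest.approx(5.0)
    assert lv["l2_F"] == pytest.approx(9.0)


def test_rollup_invariant_to_constant_peptide_shift():
    m, design = _toy_unbalanced()
    lv1 = proteins.entry_levels(proteins.fit_entry_model(m, design))
    shifted = m.copy()
    shifted.loc["pep2"] += 11.0  # absorbed into the peptide effect
    lv2 = proteins.entry_levels(proteins.fit_entry_model(shifted, design))
    d1 = lv1 - lv1.iloc[0]
    d2 = lv2 - lv2.iloc[0]
    np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)


def test_unobserved_biosample_flagged_unquantifiable():
    samples = ["l1_F1", "l1_F2", "l2_F1", "l2_F2"]
    design = _design(samples, ["l1", "l1", "l2", "l2"], ["F"] * 4, [1, 2, 1, 2])
    m = pd.DataFrame([[5.0, 6.0, np.nan, np.nan]], index=["pep"], columns=samples)
    fit = proteins.fit_entry_model(m, design)
    assert fit.unquantifiable == ["l2_F"]
    assert np.isnan(proteins.entry_levels(fit)["l2_F"])


class TestSexLine:
    def _levels(self, values, lines=("l1", "l2", "l3"), sexes=("F", "M")):
        cols = [f"{ln}_{sx}" for ln in lines for sx in sexes]
        return pd.DataFrame([values], index=["e"], columns=cols)

    def test_pure_sex_shift_detected_only_for_sex(self):
        lv = self._levels([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        res = proteins.test_sex_line(lv)
        assert res["p_sex"].iloc[0] < 1e-10
        assert not res["sig_line"].iloc[0]

    def test_constant_levels_flag_nothing(self):
        lv = self._levels([2.0] * 6)
        res = proteins.test_sex_line(lv)
        assert not res["sig_sex"].iloc[0]
        assert not res["sig_line"].iloc[0]

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        cols = [f"l{i}_{sx}" for i in range(10) for sx in ("F", "M")]
        lv = pd.DataFrame(rng.standard_normal((800, 20)), columns=cols)
        res = proteins.test_sex_line(lv)
        for col in ("sig_sex", "sig_line"):
            rate = res[col].mean()
            # binomial 3 s.e. band around 5%
            assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 800), (col, rate)


def test_dispersion_closed_forms():
    lv = pd.DataFrame(
        {"a_F": [1.0, 2.0], "a_M": [3.0, 2.0], "b_F": [1.0, 2.0], "b_M": [3.0, 2.0]},
        index=["varying", "constant"],
    )
    disp = proteins.entry_dispersion(lv)
    assert disp.loc["constant", "sd"] == pytest.approx(0.0)
    two_point = proteins.entry_dispersion(
        pd.DataFrame({"x_F": [1.0], "x_M": [3.0]}, index=["e"])
    )
    assert two_point.loc["e", "sd"] == pytest.approx(np.sqrt(2.0))


def test_planted_line_sd_recovered(quantified, bundle):
    """Median across-sample s.d. of recovered entries approximates the
    planted biological spread (line s.d. + sex dimorphism)."""
    levels, _ = quantified
    disp = proteins.entry_dispersion(levels)
    truth_sd = bundle.truth.protein_levels.std(axis=1, ddof=1)
    assert disp["sd"].median() == pytest.approx(truth_sd.median(), rel=0.10)


def test_noise_free_bundle_recovery_is_exact():
    cfg = SimulationConfig(
        seed=21, n_proteins=25, peptides_per_protein=(2, 4), noise_sd=0.0,
        planted_modules=[], planted_pqtls=[], coding_dropout_fraction=0.0,
        mnar_threshold=-np.inf,
    )
    b = generate_bundle(cfg)
    log2 = np.log2(b.intensities)  # no centering: small matrix, no noise
    mapping = {p: (b.truth.peptide_protein[p],) for p in log2.index}
    entries = proteins.classify_entries(mapping)
    levels, _ = proteins.quantify(log2, b.design, entries)
    for e in levels.index:
        x = levels.loc[e]
        y = b.truth.protein_levels.loc[e, x.index]
        if y.std() > 0:
            assert np.corrcoef(x, y)[0, 1] > 1.0 - 1e-9


def test_noisy_recovery_correlation_above_099():
    cfg = SimulationConfig(
        seed=22, n_proteins=25, peptides_per_protein=(4, 4), noise_sd=0.1,
        planted_modules=[], planted_pqtls=[], coding_dropout_fraction=0.0,
        mnar_threshold=-np.inf,
    )
    b = generate_bundle(cfg)
    log2 = np.log2(b.intensities)
    mapping = {p: (b.truth.peptide_protein[p],) for p in log2.index}
    levels, _ = proteins.quantify(log2, b.design, proteins.classify_entries(mapping))
    rs = []
    for e in levels.index:
        x = levels.loc[e]
        y = b.truth.protein_levels.loc[e, x.index]
        rs.append(np.corrcoef(x, y)[0, 1])
    assert np.median(rs) > 0.99
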