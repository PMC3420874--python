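"""NSAF computation, replicate rule, distribution classes, purity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_psms
from vesiquant.quantitation import (abundance_ratio, category_summary,
                                    count_matrix, diff_nsaf, ln_stats, nsaf,
                                    purity_estimate, quantify,
                                    summarize_fraction)
from vesiquant.reference import prohormone_abundances


def _random_counts(rng, n_prot=12):
    cols = pd.MultiIndex.from_product([["soluble", "membrane"], [1, 2, 3, 4]],
                                      names=["fraction", "replicate"])
    counts = pd.DataFrame(rng.integers(0, 40, size=(n_prot, 8)),
                          index=[f"P{i}" for i in range(n_prot)], columns=cols)
    mw = {f"P{i}": float(rng.uniform(10_000, 90_000)) for i in range(n_prot)}
    return counts, mw


class TestCountMatrix:
    def test_counts_sum_over_slices(self):
        psms = make_psms([{"proteins": "A", "slice": s} for s in (1, 2, 3)])
        counts = count_matrix(psms, ["A"])
        assert counts.loc["A", ("soluble", 1)] == 3
        assert counts.to_numpy().sum() == 3

    def test_shared_peptide_credits_every_retained_protein(self):
        psms = make_psms([{"proteins": "A;B"}])
        counts = count_matrix(psms, ["A", "B"])
        assert counts.loc["A", ("soluble", 1)] == 1
        assert counts.loc["B", ("soluble", 1)] == 1

    def test_psm_without_retained_protein_is_dropped(self, caplog):
        psms = make_psms([{"proteins": "X"}, {"proteins": "A"}])
        with caplog.at_level("WARNING"):
            counts = count_matrix(psms, ["A"])
        assert counts.to_numpy().sum() == 1
        assert "no retained protein" in caplog.text

    def test_matches_direct_recount(self, small_sim):
        from vesiquant.identification import apply_thresholds
        accepted = apply_thresholds(small_sim.psms).accepted
        retained = sorted({p for e in accepted["proteins"]
                           for p in e.split(";")})
        counts = count_matrix(accepted, retained)
        # independent recount of a handful of cells
        for pid in retained[:5]:
            for fraction in ("soluble", "membrane"):
                for rep in (1, 4):
                    manual = sum(
                        pid in row["proteins"].split(";")
                        for _, row in accepted.iterrows()
                        if row["fraction"] == fraction
                        and row["replicate"] == rep)
                    assert counts.loc[pid, (fraction, rep)] == manual


class TestNsaf:
    def test_single_protein_gets_nsaf_one(self):
        counts, _ = _random_counts(np.random.default_rng(0), n_prot=1)
        counts.iloc[0] = 5
        values = nsaf(counts, {"P0": 30_000.0})
        assert (values.to_numpy() == 1.0).all()

    def test_equal_counts_split_by_molecular_weight(self):
        cols = pd.MultiIndex.from_product([["soluble"], [1]],
                                          names=["fraction", "replicate"])
        counts = pd.DataFrame([[6], [6]], index=["A", "B"], columns=cols)
        values = nsaf(counts, {"A": 10_000.0, "B": 20_000.0})
        assert values.loc["A"].iloc[0] == pytest.approx(2 / 3)
        assert values.loc["B"].iloc[0] == pytest.approx(1 / 3)

    def test_matches_spreadsheet_style_recompute(self, rng):
        counts, mw = _random_counts(rng)
        values = nsaf(counts, mw)
        for col in counts.columns:
            saf = {p: counts.loc[p, col] / mw[p] for p in counts.index}
            total = sum(saf.values())
            for p in counts.index:
                assert values.loc[p, col] == pytest.approx(saf[p] / total)

    def test_sums_to_one_per_sample(self, rng):
        counts, mw = _random_counts(rng, n_prot=30)
        sums = nsaf(counts, mw).sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_scale_invariance(self, rng):
        counts, mw = _random_counts(rng)
        doubled = counts * 7
        pd.testing.assert_frame_equal(nsaf(counts, mw), nsaf(doubled, mw))

    def test_nonpositive_mw_rejected(self, rng):
        counts, mw = _random_counts(rng, n_prot=2)
        mw["P0"] = 0.0
        with pytest.raises(ValueError):
            nsaf(counts, mw)


class TestReplicateRule:
    def _one_fraction(self, row):
        cols = pd.Index([1, 2, 3, 4], name="replicate")
        counts = pd.DataFrame([[1 if v > 0 else 0 for v in row]],
                              index=["A"], columns=cols)
        values = pd.DataFrame([row], index=["A"], columns=cols, dtype=float)
        return counts, values

    def test_two_of_four_is_not_quantitated(self):
        counts, values = self._one_fraction([0.1, 0.2, 0.0, 0.0])
        s = summarize_fraction(counts, values)
        assert not s.quantitated.loc["A"]
        assert s.n_obs.loc["A"] == 2

    def test_full_observation_with_equal_values(self):
        counts, values = self._one_fraction([0.3, 0.3, 0.3, 0.3])
        s = summarize_fraction(counts, values)
        assert s.mean.loc["A"] == pytest.approx(0.3)
        assert s.sd.loc["A"] == 0.0

    def test_missing_replicate_contributes_zero_to_sd(self):
        a, b, c = 0.10, 0.14, 0.12
        counts, values = self._one_fraction([a, b, c, 0.0])
        s = summarize_fraction(counts, values)
        assert s.quantitated.loc["A"]
        assert s.mean.loc["A"] == pytest.approx(np.mean([a, b, c]))
        assert s.sd.loc["A"] == pytest.approx(np.std([a, b, c, 0.0], ddof=1))


class TestDiffNsaf:
    @pytest.mark.parametrize(
        ("s", "m", "qs", "qm", "expect_diff", "expect_class"),
        [
            (0.002, 0.001, True, True, 1.0, "green"),
            (0.001, 0.002, True, True, -1.0, "red"),
            (0.002, 0.002, True, True, 0.0, "yellow"),
            (0.0021, 0.0020, True, True, 0.1, "yellow"),
            (0.0, 0.003, False, True, -3.0, "red"),
            (0.003, 0.0, True, False, 3.0, "green"),
            (0.0, 0.0, False, False, None, "grey"),
        ],
    )
    def test_classes(self, s, m, qs, qm, expect_diff, expect_class):
        diff, cls = diff_nsaf(s, m, qs, qm, epsilon=0.2)
        assert cls == expect_class
        if expect_diff is not None:
            assert diff == pytest.approx(expect_diff)

    def test_quantitated_but_zero_in_both_is_grey(self):
        diff, cls = diff_nsaf(0.0, 0.0, True, True)
        assert (diff, cls) == (0.0, "grey")


class TestLnStats:
    def test_lognormal_sample_passes_normality(self):
        rng = np.random.default_rng(42)
        sol = rng.lognormal(-6, 1, 200)
        mem = rng.lognormal(-6, 1, 200)
        report = ln_stats(sol, mem, np.concatenate([sol, mem]))
        assert report.soluble.dagostino_p > 0.01
        assert report.soluble.shapiro_p > 0.01
        assert report.membrane.dagostino_p > 0.01

    def test_t_test_false_positive_rate_is_calibrated(self):
        """Identical ln-normal soluble and membrane distributions should
        reject at ~ the nominal 5% level (within 3 binomial SEs)."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_runs = 200
        for _ in range(n_runs):
            sol = rng.lognormal(-6, 1, 200)
            mem = rng.lognormal(-6, 1, 200)
            if ln_stats(sol, mem, sol).t_p < 0.05:
                rejections += 1
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_runs)
        assert rejections / n_runs <= bound

    def test_constant_data_flagged_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            report = ln_stats([0.1] * 10, [0.2] * 10, [0.1] * 10)
        assert report.soluble.degenerate
        assert math.isnan(report.soluble.shapiro_p)

    def test_too_few_values_reported_undefined(self):
        report = ln_stats([0.1, 0.2], [0.3], [0.1])
        assert math.isnan(report.membrane.shapiro_p)
        assert math.isnan(report.t_p)

    def test_nonpositive_values_excluded(self):
        report = ln_stats([0.0, 0.1, 0.2, 0.3], [0.1, 0.2, 0.4], [0.1] * 4)
        assert report.soluble.n == 3


def _quant_from_counts(counts, mw, **kw):
    rows = []
    for pid in counts.index:
        for (fraction, rep), c in counts.loc[pid].items():
            rows += [{"proteins": pid, "fraction": fraction,
                      "replicate": rep}] * int(c)
    return quantify(make_psms(rows), list(counts.index), mw, **kw)


class TestCategorySummary:
    def test_single_category_sums_to_one(self, rng):
        counts, mw = _random_counts(rng, n_prot=6)
        counts[counts == 0] = 1  # every protein observed everywhere
        quant = _quant_from_counts(counts, mw)
        cats = category_summary(quant, {p: "Everything" for p in counts.index})
        assert cats["mean_sum_nsaf"].tolist() == pytest.approx([1.0, 1.0])
        assert cats["sem"].tolist() == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_uncategorized_fall_into_miscellaneous(self, rng, caplog):
        counts, mw = _random_counts(rng, n_prot=4)
        counts[counts == 0] = 1
        quant = _quant_from_counts(counts, mw)
        with caplog.at_level("WARNING"):
            cats = category_summary(quant, {})
        assert set(cats["category"]) == {"Miscellaneous"}

    def test_sums_match_direct_recount(self, rng):
        counts, mw = _random_counts(rng, n_prot=10)
        quant = _quant_from_counts(counts, mw)
        mapping = {p: ("X" if i < 5 else "Y")
                   for i, p in enumerate(counts.index)}
        cats = category_summary(quant, mapping).set_index(
            ["category", "fraction"])
        for fraction in ("soluble", "membrane"):
            quantitated = quant.summary[
                quant.summary[f"quantitated_{fraction}"]].index
            for cat in ("X", "Y"):
                members = [p for p in quantitated if mapping[p] == cat]
                per_rep = quant.nsaf[fraction].loc[members].sum(axis=0)
                assert cats.loc[(cat, fraction), "mean_sum_nsaf"] == \
                    pytest.approx(per_rep.mean())


class TestAbundanceRatio:
    def test_published_prohormone_ratios(self):
        table = prohormone_abundances()["mean_nsaf_x1000"].to_dict()
        assert abundance_ratio(table, "PC2", "PC1_3") == \
            pytest.approx(13.8 / 4.42)
        assert abundance_ratio(table, "CPE", "PC1_3") == \
            pytest.approx(26.7 / 4.42)

    def test_identical_proteins_ratio_one(self):
        assert abundance_ratio({"A": 0.5}, "A", "A") == 1.0

    def test_zero_denominator_is_nan(self, caplog):
        with caplog.at_level("WARNING"):
            assert math.isnan(abundance_ratio({"A": 1.0, "B": 0.0}, "A", "B"))


class TestPurity:
    def test_marker_equal_to_anchor_gives_cga_fraction(self):
        report = purity_estimate({"CGA": 0.1, "M": 0.1}, {"M": "lysosome"},
                                 "CGA")
        assert report.contamination["contamination_pct"].iloc[0] == \
            pytest.approx(46.0)
        assert report.purity_pct == pytest.approx(54.0)

    def test_no_markers_means_full_purity(self):
        report = purity_estimate({"CGA": 0.1}, {}, "CGA")
        assert report.purity_pct == 100.0

    def test_inverse_reproduces_relative_abundance(self):
        cga = 0.08
        marker = cga * 0.3 / 46.0
        report = purity_estimate({"CGA": cga, "M": marker},
                                 {"M": "lysosome"}, "CGA")
        assert report.contamination["contamination_pct"].iloc[0] == \
            pytest.approx(0.3)

    def test_missing_anchor_is_an_error(self):
        with pytest.raises(ValueError):
            purity_estimate({"M": 0.1}, {"M": "lysosome"}, "CGA")

    def test_purity_floored_at_zero(self):
        report = purity_estimate({"CGA": 0.01, "M": 0.1}, {"M": "er"}, "CGA")
        assert report.purity_pct == 0.0


def test_length_correction_equalizes_equal_molar_proteins():
    """Two proteins at equal molar abundance but 2x length difference end
    up with near-equal mean NSAF: counts scale with peptide count (~length)
    and the MW division removes that factor again."""
    from vesiquant.records import ProteinRecord
    from vesiquant.synthetic import (SyntheticConfig, SyntheticTruth,
                                     generate_psms)
    from vesiquant.identification import apply_thresholds

    unit_a = "ACDEFG" + "K"
    unit_b = "LMNQST" + "K"
    proteins = [ProteinRecord(id="SHORT", sequence=unit_a * 20),
                ProteinRecord(id="LONG", sequence=unit_b * 40)]
    truth = SyntheticTruth(pd.DataFrame({
        "protein_id": ["SHORT", "LONG"], "molar_abundance": [1.0, 1.0],
        "theta_soluble": [0.5, 0.5], "marker": "", "cluster": [0, 1]}))
    cfg = SyntheticConfig(n_proteins=2, n_isoform_clusters=2, depth=100_000,
                          decoy_ratio=0.0, database_excess=1, seed=8)
    psms = generate_psms(proteins, truth, cfg)
    accepted = apply_thresholds(psms).accepted
    quant = quantify(accepted, ["SHORT", "LONG"],
                     {p.id: p.mw for p in proteins})
    ratio = (quant.summary.loc["SHORT", "mean_total"]
             / quant.summary.loc["LONG", "mean_total"])
    assert ratio == pytest.approx(1.0, rel=0.10)
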