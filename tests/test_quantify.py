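import numpy as np
import pandas as pd
import pytest

import switchquant as sq
from switchquant import quantify


def _dte_row(tx, cohort, lfc, de):
    return {
        "transcript_id": tx, "gene_id": "g", "cohort": cohort,
        "log2fc": lfc, "p": 0.001 if de else 0.9,
        "adj_p": 0.001 if de else 0.9,
        "de_flag": de,
        "expr_direction": ("up" if lfc > 0 else "down") if de else "none",
    }


def _switch(cohort="T"):
    return pd.DataFrame(
        [{"gene_id": "g", "cohort": cohort, "cancer_tx": "c", "normal_tx": "n",
          "dIF_cancer": 0.3, "dIF_normal": -0.3}]
    )


class TestClassification:
    @pytest.mark.parametrize(
        "lfc_c,de_c,lfc_n,de_n,expected",
        [
            (1.2, True, -0.8, True, "concordant"),
            (0.5, False, -1.0, True, "cancer_not_de"),
            (1.0, True, -0.5, False, "normal_not_de"),
            (-0.4, True, -2.0, True, "both_down"),
            (2.0, True, 0.5, True, "both_up"),
            (-1.0, True, 1.0, True, "reverse"),
            (0.5, False, -0.5, False, "both_not_de"),
        ],
    )
    def test_truth_table(self, lfc_c, de_c, lfc_n, de_n, expected):
        dte = pd.DataFrame([
            _dte_row("c", "T", lfc_c, de_c),
            _dte_row("n", "T", lfc_n, de_n),
        ])
        sw = _switch().iloc[0]
        assert sq.classify_switch(sw, dte) == expected
        table = sq.classify_switches(_switch(), dte)
        assert table["concordance_class"].iloc[0] == expected

    def test_classification_is_a_partition(self):
        rng = np.random.default_rng(31)
        rows, switches = [], []
        for i in range(40):
            de_c, de_n = rng.random() < 0.7, rng.random() < 0.7
            lfc_c, lfc_n = rng.normal(), rng.normal()
            rows += [_dte_row(f"c{i}", "T", lfc_c, de_c),
                     _dte_row(f"n{i}", "T", lfc_n, de_n)]
            switches.append(
                {"gene_id": f"g{i}", "cohort": "T", "cancer_tx": f"c{i}",
                 "normal_tx": f"n{i}", "dIF_cancer": 0.2, "dIF_normal": -0.2}
            )
        out = sq.classify_switches(pd.DataFrame(switches), pd.DataFrame(rows))
        assert out["concordance_class"].isin(quantify.CONCORDANCE_CLASSES).all()
        counts = out["concordance_class"].value_counts()
        assert counts.sum() == len(out)

    def test_missing_dte_row_names_transcript(self):
        dte = pd.DataFrame([_dte_row("c", "T", 1.0, True)])
        with pytest.raises(ValueError, match="n"):
            sq.classify_switch(_switch().iloc[0], dte)


class TestFrequencies:
    def _tpm_samples(self):
        samples = pd.DataFrame(
            {"condition": ["cancer"] * 3 + ["normal"] * 3, "cohort": "T"},
            index=pd.Index(["c1", "c2", "c3", "n1", "n2", "n3"],
                           name="sample_id"),
        )
        tpm = pd.DataFrame(
            {
                "c1": [5.0, 1.0], "c2": [4.0, 2.0], "c3": [3.0, 6.0],
                "n1": [1.0, 5.0], "n2": [2.0, 4.0], "n3": [6.0, 3.0],
            },
            index=["c", "n"],
        )
        return sq.ExpressionMatrix(tpm, kind="tpm"), samples

    def test_direct_count(self):
        tpm, samples = self._tpm_samples()
        out = sq.switch_frequencies(_switch(), tpm, samples)
        assert out["f_cancer"].iloc[0] == pytest.approx(2 / 3)
        assert out["f_normal"].iloc[0] == pytest.approx(2 / 3)
        assert out["combined_freq"].iloc[0] == pytest.approx(4 / 9)
        assert out["legacy_score"].iloc[0] == pytest.approx(1 / 3)

    def test_degenerate_one_zero(self):
        samples = pd.DataFrame(
            {"condition": ["cancer", "normal"], "cohort": "T"},
            index=pd.Index(["c1", "n1"], name="sample_id"),
        )
        tpm = sq.ExpressionMatrix(
            pd.DataFrame({"c1": [5.0, 1.0], "n1": [5.0, 1.0]},
                         index=["c", "n"]),
            kind="tpm",
        )
        out = sq.switch_frequencies(_switch(), tpm, samples)
        # cancer tx always higher: f_cancer=1, f_normal=0
        assert out["f_cancer"].iloc[0] == 1.0
        assert out["f_normal"].iloc[0] == 0.0
        assert out["combined_freq"].iloc[0] == 0.0
        assert out["legacy_score"].iloc[0] == 0.0

    def test_legacy_degeneracy_vs_combined(self):
        """(1, 0) and (0.5, 0.5) tie on the legacy score but not combined."""
        legacy = lambda fc, fn: fc + fn - 1
        combined = lambda fc, fn: fc * fn
        assert legacy(1.0, 0.0) == legacy(0.5, 0.5)
        assert combined(1.0, 0.0) == 0.0
        assert combined(0.5, 0.5) == 0.25

    def test_tie_counts_toward_neither(self):
        samples = pd.DataFrame(
            {"condition": ["cancer", "normal"], "cohort": "T"},
            index=pd.Index(["c1", "n1"], name="sample_id"),
        )
        tpm = sq.ExpressionMatrix(
            pd.DataFrame({"c1": [0.0, 0.0], "n1": [0.0, 0.0]},
                         index=["c", "n"]),
            kind="tpm",
        )
        out = sq.switch_frequencies(_switch(), tpm, samples)
        assert out["f_cancer"].iloc[0] == 0.0
        assert out["f_normal"].iloc[0] == 0.0

    def test_tpm_and_usage_equivalent_when_gene_expressed(self):
        """Usage normalization preserves within-gene expression order."""
        spec = sq.ScenarioSpec(n_genes=20, seed=37, dispersion=5.0)
        spec.planted = sq.plant_switches(spec, 4, delta_if=0.3)
        counts, tpm, ann, samples, truth = sq.generate_cohort(spec)
        usage = sq.compute_usage(tpm, ann)
        gene_expressed = (
            tpm.values.groupby(ann.to_numpy()).transform("sum") > 0
        ).all(axis=1)
        sw = pd.DataFrame(
            {
                "gene_id": truth["gene_id"],
                "cohort": "SIM",
                "cancer_tx": truth["cancer_tx"],
                "normal_tx": truth["normal_tx"],
            }
        )
        ok = sw["cancer_tx"].map(gene_expressed) & sw["normal_tx"].map(
            gene_expressed
        )
        sw = sw[ok]
        a = sq.switch_frequencies(sw, tpm, samples)
        b = sq.switch_frequencies(sw, usage, samples)
        np.testing.assert_array_equal(a["f_cancer"], b["f_cancer"])
        np.testing.assert_array_equal(a["f_normal"], b["f_normal"])


class TestFrequencyCurve:
    def test_constant_combined(self):
        sw = pd.DataFrame(
            {"f_cancer": [1.0, 1.0], "f_normal": [1.0, 1.0],
             "combined_freq": [1.0, 1.0]}
        )
        curve = sq.frequency_curve(sw)
        assert (curve["prop_combined"] == 1.0).all()

    def test_single_switch_evaluation(self):
        sw = pd.DataFrame(
            {"f_cancer": [0.6], "f_normal": [0.8], "combined_freq": [0.48]}
        )
        curve = sq.frequency_curve(sw).set_index("threshold")
        assert curve.loc[0.70, "prop_max_frequency"] == 1.0
        assert curve.loc[0.90, "prop_max_frequency"] == 0.0

    def test_matches_brute_force_and_is_monotone(self):
        rng = np.random.default_rng(41)
        sw = pd.DataFrame(
            {"f_cancer": rng.uniform(size=30), "f_normal": rng.uniform(size=30)}
        )
        sw["combined_freq"] = sw["f_cancer"] * sw["f_normal"]
        curve = sq.frequency_curve(sw)
        fmax = np.maximum(sw["f_cancer"], sw["f_normal"]).to_numpy()
        for _, row in curve.iloc[::7].iterrows():
            assert row["prop_max_frequency"] == pytest.approx(
                (fmax >= row["threshold"]).mean()
            )
        assert (np.diff(curve["prop_max_frequency"]) <= 0).all()
        assert (np.diff(curve["prop_combined"]) <= 0).all()

    def test_empty_input(self):
        assert len(sq.frequency_curve(pd.DataFrame(
            columns=["f_cancer", "f_normal", "combined_freq"]))) == 0


class TestStratification:
    def _results(self, tpm_values, dif, lfc):
        n = len(tpm_values)
        return pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "cohort": "T",
                "gene_id": [f"g{i}" for i in range(n)],
                "role": "cancer",
                "dIF": dif,
                "log2fc": lfc,
            }
        )

    def _tpm(self, values, samples):
        df = pd.DataFrame(
            np.tile(np.asarray(values)[:, None], (1, len(samples))),
            index=[f"t{i}" for i in range(len(values))],
            columns=samples.index,
        )
        return sq.ExpressionMatrix(df, kind="tpm")

    def _samples(self):
        return pd.DataFrame(
            {"condition": ["normal", "normal", "cancer", "cancer"],
             "cohort": "T"},
            index=pd.Index(list("abcd"), name="sample_id"),
        )

    def test_all_high_skips_comparison(self):
        samples = self._samples()
        res = self._results([5.0] * 6, np.linspace(0, 1, 6),
                            np.linspace(-1, 1, 6))
        tpm = self._tpm([5.0] * 6, samples)
        out = quantify.stratify_by_expression(res, tpm, samples, 1.0)
        assert len(out) == 0

    def test_threshold_zero_all_high(self):
        samples = self._samples()
        res = self._results([0.5] * 6, np.linspace(0, 1, 6),
                            np.linspace(-1, 1, 6))
        tpm = self._tpm([0.5] * 6, samples)
        out = quantify.stratify_by_expression(res, tpm, samples, 0.0)
        assert len(out) == 0  # low group empty again

    def test_groups_split_and_compared(self):
        samples = self._samples()
        values = [0.1, 0.2, 0.3, 5.0, 6.0, 7.0]
        res = self._results(values, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                            [-1, -2, -3, 1, 2, 3])
        tpm = self._tpm(values, samples)
        out = quantify.stratify_by_expression(res, tpm, samples, 1.0)
        assert set(out["metric"]) == {"dIF", "log2fc"}
        row = out[out["metric"] == "dIF"].iloc[0]
        assert row["n_low"] == 3 and row["n_high"] == 3
        assert row["median_diff_high_minus_low"] == pytest.approx(0.5 - 0.2)


class TestCorrelation:
    def test_perfect_monotone(self):
        samples = pd.DataFrame(
            {"condition": ["normal", "cancer"], "cohort": "T"},
            index=pd.Index(["a", "b"], name="sample_id"),
        )
        n = 10
        tpm = sq.ExpressionMatrix(
            pd.DataFrame(
                {"a": np.arange(1.0, n + 1), "b": np.arange(1.0, n + 1)},
                index=[f"t{i}" for i in range(n)],
            ),
            kind="tpm",
        )
        res = pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(n)],
                "cohort": "T",
                "role": "cancer",
                "dIF": np.arange(n, dtype=float),
                "log2fc": np.arange(n, dtype=float),
            }
        )
        out = quantify.expression_effect_correlation(res, tpm, samples)
        np.testing.assert_allclose(out["spearman_rho"], 1.0)

    def test_matches_rank_then_pearson(self):
        from scipy.stats import pearsonr, rankdata

        rng = np.random.default_rng(43)
        x, y = rng.normal(size=50), rng.normal(size=50)
        from switchquant.stats import spearman

        assert spearman(x, y) == pytest.approx(
            pearsonr(rankdata(x), rankdata(y)).statistic
        )

    def test_independent_pairs_near_zero(self):
        from switchquant.stats import spearman

        rng = np.random.default_rng(47)
        hits = 0
        for _ in range(40):
            rho = spearman(rng.normal(size=1000), rng.normal(size=1000))
            hits += abs(rho) < 0.1
        assert hits >= 38

    def test_constant_input_reported_missing(self):
        from switchquant.stats import spearman

        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestCohortComparisons:
    def test_paired_all_equal_p_one(self):
        sw = pd.DataFrame(
            {
                "cohort": ["T"] * 5,
                "dIF_cancer": [0.3] * 5,
                "dIF_normal": [-0.3] * 5,
                "concordance_class": ["concordant"] * 5,
                "log2fc_cancer": [1.0] * 5,
                "log2fc_normal": [-1.0] * 5,
            }
        )
        res = pd.DataFrame(
            {
                "cohort": ["T"] * 4,
                "role": ["cancer", "cancer", "normal", "normal"],
                "dIF": [0.3, 0.3, -0.3, -0.3],
                "log2fc": [1.0, 1.0, -1.0, -1.0],
                "transcript_id": list("abcd"),
            }
        )
        out = quantify.cohort_comparisons(sw, res)
        paired = out[out["test"] == "signed_rank_abs_dif_cancer_vs_normal"]
        assert (paired["p"] == 1.0).all()

    def test_planted_both_down_normal_decreases_more(self):
        """Power check: plants where the normal transcript falls further
        should reject on the one-sided signed-rank test."""
        rng = np.random.default_rng(53)
        n = 60
        sw = pd.DataFrame(
            {
                "cohort": "T",
                "dIF_cancer": rng.uniform(0.1, 0.4, n),
                "dIF_normal": -rng.uniform(0.1, 0.4, n),
                "concordance_class": "both_down",
                "log2fc_cancer": rng.normal(-0.5, 0.2, n),
                "log2fc_normal": rng.normal(-2.0, 0.2, n),
            }
        )
        res = pd.DataFrame(
            {
                "cohort": "T",
                "role": ["cancer"] * n + ["normal"] * n,
                "dIF": np.r_[sw["dIF_cancer"], sw["dIF_normal"]],
                "log2fc": np.r_[sw["log2fc_cancer"], sw["log2fc_normal"]],
                "transcript_id": [f"t{i}" for i in range(2 * n)],
            }
        )
        out = quantify.cohort_comparisons(sw, res)
        one_sided = out[out["test"] == "signed_rank_normal_lfc_less_than_cancer"]
        assert (one_sided["p"] < 0.05).all()


class TestSummaries:
    def test_class_counts_sum_to_total(self):
        rng = np.random.default_rng(59)
        sw = pd.DataFrame(
            {
                "cohort": rng.choice(["A", "B"], 30),
                "concordance_class": rng.choice(
                    ["concordant", "both_down", "cancer_not_de"], 30
                ),
            }
        )
        summary = quantify.class_summary(sw)
        pooled = summary[summary["cohort"] == "pooled"]
        assert pooled["n"].sum() == 30
        assert pooled["percent"].sum() == pytest.approx(100.0)

    def test_role_summary_counts_each_transcript_once(self):
        dte = pd.DataFrame([
            _dte_row("c1", "T", 1.0, True),
            _dte_row("n1", "T", -1.0, True),
            _dte_row("n2", "T", 0.5, False),
        ])
        sw = pd.DataFrame(
            [
                {"gene_id": "g", "cohort": "T", "cancer_tx": "c1",
                 "normal_tx": "n1"},
                {"gene_id": "g", "cohort": "T", "cancer_tx": "c1",
                 "normal_tx": "n2"},
            ]
        )
        out = quantify.transcript_role_summary(sw, dte)
        cancer_total = out[out["role"] == "cancer"]["n_transcripts"].iloc[0]
        assert cancer_total == 1  # c1 in two switches, counted once
        normal_not_de = out[
            (out["role"] == "normal") & (out["category"] == "not_de")
        ]["n"].iloc[0]
        assert normal_not_de == 1
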