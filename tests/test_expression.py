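"""Normalization, NB differential test, ZGA cascade and repeat condensing."""

import numpy as np
import pandas as pd
import pytest

from k9dyn.expression import (
    ExpressionMatrix,
    ZgaThresholds,
    bh_adjust,
    classify_degree,
    classify_zga,
    condense_repeat_family,
    nb_de_test,
    signal_expression_correlation,
    size_factors_median_ratio,
)

STAGES = ("oocyte", "PN5", "E2C", "L2C", "4C")


def _matrix(stage_means: dict[str, np.ndarray], reps=2, condition="fertilized",
            n_anchor=11):
    """Noise-free matrix with the given per-stage mean counts.

    Appends ``n_anchor`` constant housekeeping genes so the median-of-
    ratios size factors are exactly 1 and normalized counts equal the
    raw means being asserted on.
    """
    n = len(next(iter(stage_means.values())))
    genes = [f"g{i}" for i in range(n)] + [f"anchor{i}" for i in range(n_anchor)]
    samples = [(s, condition, r + 1) for s in STAGES for r in range(reps)]
    cols = [
        np.concatenate([np.asarray(stage_means[s], float), np.full(n_anchor, 20.0)])
        for s, _c, _r in samples
    ]
    return ExpressionMatrix(genes, np.full(len(genes), 1000), samples,
                            np.column_stack(cols))


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        counts = np.tile([[10.0], [20.0], [30.0]], (1, 3))
        sf = size_factors_median_ratio(counts)
        assert np.allclose(sf, sf[0])

    def test_doubled_sample_has_double_factor(self):
        a = np.array([10.0, 20.0, 100.0])
        counts = np.column_stack([a, 2 * a])
        sf = size_factors_median_ratio(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_matches_definition_brute_force(self, rng):
        counts = rng.negative_binomial(5, 0.3, size=(200, 4)).astype(float) + 1
        sf = size_factors_median_ratio(counts)
        # brute force straight from the definition
        ref = np.exp(np.mean(np.log(counts), axis=1))
        expected = [np.median(counts[:, j] / ref) for j in range(4)]
        assert np.allclose(sf, expected)

    def test_no_allpositive_gene_errors(self):
        with pytest.raises(ValueError, match="reference"):
            size_factors_median_ratio(np.array([[0.0, 5.0], [5.0, 0.0]]))


class TestNbDeTest:
    def test_identical_groups_null(self, rng):
        counts = rng.poisson(50, size=(100, 6)).astype(float)
        res = nb_de_test(counts[:, :3], counts[:, 3:], np.ones(3), np.ones(3))
        assert np.abs(res["log2fc"]).max() < 1.0
        assert (res["q"] > 0.01).mean() > 0.95

    def test_allzero_gene_degenerate(self):
        counts = np.zeros((1, 4))
        res = nb_de_test(counts[:, :2], counts[:, 2:], np.ones(2), np.ones(2))
        assert res.loc[0, "p"] == 1.0 and res.loc[0, "log2fc"] == 0.0

    def test_power_on_planted_eightfold(self, rng):
        """Planted 8-fold genes at dispersion 0.05 and n=3 are detected
        at q < 0.01 with power >= 0.9."""
        n = 400
        mu_a, mu_b = 50.0, 400.0
        size = 1 / 0.05
        a = rng.negative_binomial(size, size / (size + mu_a), size=(n, 3)).astype(float)
        b = rng.negative_binomial(size, size / (size + mu_b), size=(n, 3)).astype(float)
        res = nb_de_test(a, b, np.ones(3), np.ones(3))
        assert (res["q"] < 0.01).mean() >= 0.9

    def test_type_i_control_under_null(self, rng):
        size = 1 / 0.05
        counts = rng.negative_binomial(
            size, size / (size + 100.0), size=(1000, 6)
        ).astype(float)
        res = nb_de_test(counts[:, :3], counts[:, 3:], np.ones(3), np.ones(3))
        assert (res["q"] < 0.01).mean() <= 0.02


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_edge_cases(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected)

    def test_monotone_in_sorted_order(self, rng):
        q = bh_adjust(rng.uniform(size=100))
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1.0).all()


class TestZgaCascade:
    def _base_means(self, n):
        return {s: np.full(n, 5.0) for s in STAGES}

    def test_cascade_examples(self):
        """One gene per gate combination, exercised through the cascade."""
        means = {s: np.array([60.0, 5.0, 5.0, 5.0, 5.0]) for s in STAGES}
        # gene0: maternal (oocyte 60 > 50)
        # gene1: minor (PN5 150)
        # gene2: major (PN5 80, E2C 90 below gate; L2C 500)
        # gene3: MGA (4C 500)
        # gene4: none
        means["oocyte"] = np.array([60.0, 5.0, 5.0, 5.0, 5.0])
        means["PN5"] = np.array([500.0, 150.0, 80.0, 5.0, 5.0])
        means["E2C"] = np.array([500.0, 150.0, 90.0, 5.0, 5.0])
        means["L2C"] = np.array([500.0, 150.0, 500.0, 60.0, 5.0])
        means["4C"] = np.array([500.0, 150.0, 500.0, 500.0, 5.0])
        calls = classify_zga(_matrix(means))
        assert list(calls["zga_class"].iloc[:5]) == [
            "maternal", "minor_ZGA", "major_ZGA", "MGA", "none",
        ]

    def test_thresholds_are_strict(self):
        """Values exactly at a gate do not pass (printed thresholds are
        strict inequalities)."""
        means = self._base_means(2)
        means["oocyte"] = np.array([50.0, 5.0])       # exactly 50: not maternal
        means["PN5"] = np.array([500.0, 100.0])       # exactly 100: fails gate
        means["E2C"] = np.array([500.0, 100.0])
        calls = classify_zga(_matrix(means))
        assert calls["zga_class"].iloc[0] == "minor_ZGA"  # 50 is not > 50
        assert calls["zga_class"].iloc[1] == "none"       # 100 is not > 100

    def test_classes_mutually_exclusive_and_order_dependent(self):
        """A gene passing both the E2C and L2C gates is minor, not major;
        feeding stages in a permuted order changes the call."""
        means = self._base_means(1)
        for s in ("PN5", "E2C", "L2C", "4C"):
            means[s] = np.array([400.0])
        calls = classify_zga(_matrix(means))
        assert calls["zga_class"].iloc[0] == "minor_ZGA"

    def test_missing_stage_errors(self):
        means = {s: np.array([5.0]) for s in ("oocyte", "PN5", "E2C", "L2C")}
        genes = ["g0"]
        samples = [(s, "fertilized", 1) for s in means]
        m = ExpressionMatrix(genes, [1000], samples,
                             np.column_stack(list(means.values())))
        with pytest.raises(KeyError, match="4C"):
            classify_zga(m)


class TestDegree:
    @pytest.mark.parametrize(
        "fert,scnt,expected",
        [(50.0, 5.0, "restricted"), (50.0, 40.0, "full"), (50.0, 15.0, "partial")],
    )
    def test_gate_arithmetic(self, fert, scnt, expected):
        means_f = {s: np.array([5.0]) for s in STAGES}
        means_f["E2C"] = np.array([fert])
        means_f["PN5"] = np.array([fert])
        means_s = {s: np.array([5.0]) for s in STAGES}
        means_s["E2C"] = np.array([scnt])
        mf, ms = _matrix(means_f), _matrix(means_s, condition="SCNT")
        calls = pd.DataFrame({"gene": ["g0"], "zga_class": ["minor_ZGA"]}).set_index("gene")
        out = classify_degree(calls, mf, ms)
        assert out["degree"].iloc[0] == expected
        assert out["fold_change_fert_scnt"].iloc[0] == pytest.approx(
            (fert + 1) / (scnt + 1)
        )

    def test_unclassified_not_applicable(self):
        mf = _matrix({s: np.array([5.0]) for s in STAGES})
        calls = pd.DataFrame({"gene": ["g0"], "zga_class": ["none"]}).set_index("gene")
        out = classify_degree(calls, mf, mf)
        assert out["degree"].iloc[0] == "not_applicable"


class TestRepeatCondense:
    def test_mean_methylation(self):
        assert condense_repeat_family([0.2, 0.4, 0.6], "mean_methylation") == pytest.approx(0.4)
        assert condense_repeat_family([0.7], "mean_methylation") == pytest.approx(0.7)

    def test_sum_expression_rpkm(self):
        # 30 reads over 3 kb at 1e6 library -> RPKM 10
        v = condense_repeat_family(
            [5, 10, 15], "sum_expression", lengths=[1000, 1000, 1000], library_size=1e6
        )
        assert v == pytest.approx(10.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            condense_repeat_family([], "mean_methylation")


class TestCorrelation:
    def test_endpoints(self):
        x = np.arange(10.0)
        assert signal_expression_correlation(x, x) == pytest.approx(1.0)
        assert signal_expression_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_definition(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r = signal_expression_correlation(x, y)
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expected)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            signal_expression_correlation(np.ones(5), np.arange(5.0))
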