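import math

import numpy as np
import pandas as pd
import pytest

from bhlhkit import expression_analysis as ea
from bhlhkit import synthetic_data as sd


def matrix(values, samples, tissue_of, stage_order=None, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return ea.ExpressionMatrix(
        rpkm=pd.DataFrame(values, index=genes, columns=samples),
        tissue_of=tissue_of,
        stage_order=stage_order,
    )


TWO_TISSUE = {"s1": "root", "s2": "root", "s3": "leaf", "s4": "leaf"}


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [(0, 0), (1, 1), (3, 2)])
    def test_analytic_values(self, value, expected):
        m = matrix([[value]], ["s1"], {"s1": "root"})
        assert ea.log_transform(m).iloc[0, 0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ea.log_transform(pd.DataFrame([[-1.0]]))


class TestExpressedGenes:
    def test_all_zero_excluded(self):
        m = matrix([[0, 0, 0, 0]], list(TWO_TISSUE), TWO_TISSUE)
        assert ea.expressed_genes(m) == set()

    def test_boundary_is_strict(self):
        m = matrix([[2.0, 0, 0, 0], [2.01, 0, 0, 0]], list(TWO_TISSUE), TWO_TISSUE)
        assert ea.expressed_genes(m) == {"g1"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.uniform(0, 10, (30, 4)), list(TWO_TISSUE), TWO_TISSUE)
        sets = [ea.expressed_genes(m, t) for t in (1.0, 2.0, 5.0, 9.0)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger


class TestTissueSpecific:
    def test_forced_call(self):
        m = matrix([[10, 10, 1, 1]], list(TWO_TISSUE), TWO_TISSUE)
        assert ea.tissue_specific(m) == [("g0", "root")]

    def test_uniform_gene_not_called(self):
        m = matrix([[5, 5, 5, 5]], list(TWO_TISSUE), TWO_TISSUE)
        assert ea.tissue_specific(m) == []

    def test_floor_blocks_low_expression(self):
        m = matrix([[1.5, 1.5, 0.1, 0.1]], list(TWO_TISSUE), TWO_TISSUE)
        assert ea.tissue_specific(m) == []

    def test_scaling_invariance_of_fold_rule(self):
        """With the floor disabled, scaling all RPKM by a constant never
        removes a fold-rule call."""
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 20, (25, 4))
        m1 = matrix(vals, list(TWO_TISSUE), TWO_TISSUE)
        m2 = matrix(vals * 7.3, list(TWO_TISSUE), TWO_TISSUE)
        calls1 = ea.tissue_specific(m1, floor=0.0)
        calls2 = ea.tissue_specific(m2, floor=0.0)
        assert calls1 == calls2

    def test_requires_two_tissues(self):
        m = matrix([[1, 2]], ["s1", "s2"], {"s1": "root", "s2": "root"})
        with pytest.raises(ValueError):
            ea.tissue_specific(m)


STAGES = {"p1": "S1", "p2": "S2", "p3": "S3", "p4": "S4"}


class TestStageTrend:
    def trend_matrix(self, rows):
        return matrix(
            rows, list(STAGES), STAGES, stage_order=["S1", "S2", "S3", "S4"]
        )

    def test_doubling_series_increasing(self):
        m = self.trend_matrix([[1, 2, 4, 8]])
        assert ea.stage_trend(m)["g0"] == "increasing"

    def test_halving_series_decreasing(self):
        m = self.trend_matrix([[8, 4, 2, 1]])
        assert ea.stage_trend(m)["g0"] == "decreasing"

    def test_oscillation_is_none(self):
        m = self.trend_matrix([[1, 5, 1, 5]])
        assert ea.stage_trend(m)["g0"] == "none"

    def test_unexpressed_gene_is_none(self):
        m = self.trend_matrix([[0.1, 0.2, 0.4, 0.8]])
        assert ea.stage_trend(m)["g0"] == "none"

    def test_monotone_but_small_fold_is_none(self):
        m = self.trend_matrix([[3.0, 3.2, 3.5, 4.0]])
        assert ea.stage_trend(m)["g0"] == "none"

    def test_needs_three_stages(self):
        m = matrix([[1, 2]], ["p1", "p2"], {"p1": "S1", "p2": "S2"},
                   stage_order=["S1", "S2"])
        with pytest.raises(ValueError):
            ea.stage_trend(m)


class TestCorrelation:
    SAMPLES = ["s1", "s2", "s3", "s4"]
    GROUPS = {s: "t" for s in SAMPLES}

    def test_identical_profiles(self):
        ma = matrix([[1, 2, 4, 8]], self.SAMPLES, self.GROUPS, genes=["a1"])
        mb = matrix([[1, 2, 4, 8]], self.SAMPLES, self.GROUPS, genes=["b1"])
        r = ea.ortholog_expression_correlation([("a1", "b1")], ma, mb)
        assert r[("a1", "b1")] == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ma = matrix([2.0 ** x - 1], self.SAMPLES, self.GROUPS, genes=["a1"])
        mb = matrix([2.0 ** x[::-1] - 1], self.SAMPLES, self.GROUPS, genes=["b1"])
        r = ea.ortholog_expression_correlation([("a1", "b1")], ma, mb)
        assert r[("a1", "b1")] == pytest.approx(-1.0)

    def test_constant_profile_undefined(self):
        ma = matrix([[3, 3, 3, 3]], self.SAMPLES, self.GROUPS, genes=["a1"])
        mb = matrix([[1, 2, 3, 4]], self.SAMPLES, self.GROUPS, genes=["b1"])
        r = ea.ortholog_expression_correlation([("a1", "b1")], ma, mb)
        assert math.isnan(r[("a1", "b1")])

    def test_shared_signal_with_noise(self):
        """Planted orthologue pairs sharing a profile plus sigma=0.1 noise
        correlate strongly."""
        rng = np.random.default_rng(8)
        base = rng.uniform(1, 50, size=(15, 10))
        noise = lambda: np.exp(rng.normal(0, 0.1, size=base.shape))
        samples = [f"s{i}" for i in range(10)]
        groups = {s: "t" for s in samples}
        ga = [f"a{i}" for i in range(15)]
        gb = [f"b{i}" for i in range(15)]
        ma = matrix(base * noise(), samples, groups, genes=ga)
        mb = matrix(base * noise(), samples, groups, genes=gb)
        r = ea.ortholog_expression_correlation(list(zip(ga, gb)), ma, mb)
        assert np.mean(list(r.values())) > 0.9

    def test_no_shared_samples_rejected(self):
        ma = matrix([[1]], ["s1"], {"s1": "t"}, genes=["a1"])
        mb = matrix([[1]], ["s9"], {"s9": "t"}, genes=["b1"])
        with pytest.raises(ValueError):
            ea.ortholog_expression_correlation([("a1", "b1")], ma, mb)


def ct_table(rows, calibrator="root"):
    return ea.CtTable(
        rows=pd.DataFrame(rows, columns=["sample", "gene", "ct", "is_reference"]),
        calibrator=calibrator,
    )


class TestDdct:
    def test_calibrator_is_one(self):
        ct = ct_table(
            [
                ("root", "actin", 20.0, True),
                ("root", "target", 25.0, False),
            ]
        )
        assert ea.ddct(ct, "target", "root") == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "target_ct,expected",
        [(26.0, 0.5), (25.0, 1.0), (23.0, 4.0)],  # ddCt = +1, 0, -2
    )
    def test_analytic_values(self, target_ct, expected):
        ct = ct_table(
            [
                ("root", "actin", 20.0, True),
                ("root", "target", 25.0, False),
                ("leaf", "actin", 20.0, True),
                ("leaf", "target", target_ct, False),
            ]
        )
        assert ea.ddct(ct, "target", "leaf") == pytest.approx(expected)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            ct_table([("root", "target", 25.0, False)])


class TestTTest:
    def test_identical_groups(self):
        t, p = ea.two_sample_ttest([1, 1, 1], [1, 1, 1])
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups_significant(self):
        t, p = ea.two_sample_ttest([0.0, 0.001], [1.0, 0.999])
        assert p < 0.05
        # closed-form check for the equal-variance statistic
        from scipy import stats

        ref = stats.ttest_ind([0.0, 0.001], [1.0, 0.999], equal_var=True)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_degenerate_zero_variance_unequal_means(self):
        t, p = ea.two_sample_ttest([0, 0], [1, 1])
        assert math.isinf(t) and p == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            ea.two_sample_ttest([1], [1, 2])


class TestPlantedRecovery:
    def test_expressed_specific_and_trends_recovered(self, expression_bundle):
        m = expression_bundle.matrix
        assert ea.expressed_genes(m) == expression_bundle.truth_expressed
        assert dict(ea.tissue_specific(m)) == expression_bundle.truth_specific
        trends = {g: v for g, v in ea.stage_trend(m).items() if v != "none"}
        assert trends == expression_bundle.truth_trends
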