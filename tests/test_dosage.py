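"""RPKM, X:A dosage ratios, component expression, gene age, overlaps."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from scdc.annotation import ChromClass
from scdc.dosage import (
    component_expression_summary,
    mean_age,
    overlap_test,
    remove_and_recompute,
    rpkm,
    rpkm_matrix,
    xa_expression_ratio,
)
from scdc.enrichment import class_counts, enrich_class


class TestRpkm:
    @pytest.mark.parametrize(
        "reads,length,total,expected",
        [
            (1000, 1000, 10**6, 1000.0),
            (0, 500, 10**7, 0.0),
            (250, 2000, 5 * 10**6, 25.0),
        ],
    )
    def test_examples(self, reads, length, total, expected):
        assert rpkm(reads, length, total) == pytest.approx(expected)

    def test_linearity_in_reads(self):
        assert rpkm(300, 1000, 10**6) == pytest.approx(3 * rpkm(100, 1000, 10**6))

    def test_inverse_in_length(self):
        assert rpkm(100, 2000, 10**6) == pytest.approx(rpkm(100, 1000, 10**6) / 2)

    def test_inverse_in_library_size(self):
        assert rpkm(100, 1000, 2 * 10**6) == pytest.approx(
            rpkm(100, 1000, 10**6) / 2
        )

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm(10, 1000, 0)

    def test_matrix_matches_scalar(self):
        counts = pd.DataFrame(
            {"s1": [100, 200], "s2": [50, 0]}, index=["g1", "g2"]
        )
        lengths = {"g1": 1000, "g2": 4000}
        sizes = {"s1": 10**6, "s2": 2 * 10**6}
        mat = rpkm_matrix(counts, lengths, sizes)
        for g in counts.index:
            for s in counts.columns:
                assert mat.loc[g, s] == pytest.approx(
                    rpkm(counts.loc[g, s], lengths[g], sizes[s])
                )


class TestXaRatio:
    def test_identical_distributions_ratio_one(self):
        rng = np.random.default_rng(31)
        vals = rng.gamma(2, 10, size=400) + 1
        expr = {f"g{i}": float(v) for i, v in enumerate(vals)}
        classes = {
            f"g{i}": ChromClass.X if i % 2 else ChromClass.AUTOSOME
            for i in range(400)
        }
        # interleave so both classes see the same distribution
        res = xa_expression_ratio(expr, classes, min_rpkm=0.0)
        assert res["ratio_a_over_x"] == pytest.approx(1.0, abs=0.3)
        assert res["wilcoxon_p"] > 0.05

    def test_halved_x_expression_recovered(self):
        rng = np.random.default_rng(32)
        expr = {}
        classes = {}
        for i in range(600):
            v = float(rng.lognormal(3, 0.5))
            if i % 3 == 0:
                expr[f"g{i}"] = v / 2  # X without compensation
                classes[f"g{i}"] = ChromClass.X
            else:
                expr[f"g{i}"] = v
                classes[f"g{i}"] = ChromClass.AUTOSOME
        res = xa_expression_ratio(expr, classes, min_rpkm=0.0)
        assert res["ratio_a_over_x"] == pytest.approx(2.0, rel=0.25)
        assert res["wilcoxon_p"] < 0.001

    def test_median_matches_sort_and_pick_oracle(self):
        expr = {"a": 1.0, "b": 5.0, "c": 9.0, "d": 2.0, "e": 8.0}
        classes = {
            "a": ChromClass.AUTOSOME,
            "b": ChromClass.AUTOSOME,
            "c": ChromClass.AUTOSOME,
            "d": ChromClass.X,
            "e": ChromClass.X,
        }
        res = xa_expression_ratio(expr, classes, min_rpkm=0.0)
        assert res["median_autosome"] == 5.0  # middle of sorted [1,5,9]
        assert res["median_x"] == 5.0  # mean of [2,8]

    def test_housekeeping_filter_requires_tau(self):
        with pytest.raises(ValueError, match="tau"):
            xa_expression_ratio({"g": 2.0}, {"g": ChromClass.X}, max_tau=0.4)

    def test_empty_class_names_filter(self):
        expr = {"g1": 5.0}
        classes = {"g1": ChromClass.AUTOSOME}
        with pytest.raises(ValueError, match="min_rpkm"):
            xa_expression_ratio(expr, classes, min_rpkm=1.0)


class TestComponentExpression:
    def test_replicate_mean_and_sem(self):
        table = pd.DataFrame(
            {"r1": [10.0], "r2": [12.0], "r3": [14.0]}, index=["mle_gene"]
        )
        out = component_expression_summary(table, {"MLE": "mle_gene"})
        row = out.iloc[0]
        assert row["mean_rpkm"] == pytest.approx(12.0)
        assert row["sem_rpkm"] == pytest.approx(2.0 / math.sqrt(3))

    def test_constant_replicates_zero_sem(self):
        table = pd.DataFrame({"r1": [7.0], "r2": [7.0]}, index=["g"])
        out = component_expression_summary(table, {"MOF": "g"})
        assert out.iloc[0]["sem_rpkm"] == 0.0

    def test_single_replicate_flagged(self):
        table = pd.DataFrame({"r1": [7.0]}, index=["g"])
        out = component_expression_summary(table, {"MSL2": "g"})
        row = out.iloc[0]
        assert row["sem_rpkm"] == 0.0 and not row["sem_defined"]

    def test_missing_component_reported_absent(self):
        table = pd.DataFrame({"r1": [7.0]}, index=["g"])
        out = component_expression_summary(table, {"MLE": "absent_gene"})
        assert not out.iloc[0]["present"]


class TestMeanAge:
    def test_uniform_oldest_class(self):
        assert mean_age(["a", "b"], {"a": 6, "b": 6})[0] == 6.0

    def test_arithmetic_mean(self):
        mean, cov = mean_age(["a", "b", "c"], {"a": 6, "b": 6, "c": 5})
        assert mean == pytest.approx(5.667, abs=1e-3)
        assert cov == 1.0

    def test_unknown_genes_excluded_with_coverage(self):
        mean, cov = mean_age(["a", "b", "c", "d"], {"a": 4, "b": 2})
        assert mean == pytest.approx(3.0)
        assert cov == pytest.approx(0.5)

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            mean_age(["a"], {"b": 3})


class TestOverlapTest:
    def test_disjoint_sets(self):
        universe = [f"g{i}" for i in range(50)]
        res = overlap_test(universe[:10], universe[10:20], universe)
        assert res.n_overlap == 0
        assert res.hypergeometric_p == pytest.approx(1.0)

    def test_identical_sets_minimal_p(self):
        universe = [f"g{i}" for i in range(30)]
        res = overlap_test(universe[:6], universe[:6], universe)
        assert res.n_overlap == 6
        # P(X >= 6) = C(6,6)*C(24,0)/C(30,6)
        assert res.hypergeometric_p == pytest.approx(
            1 / comb(30, 6, exact=True)
        )

    def test_matches_exact_enumeration(self):
        # universe 20, |a|=5, |b|=5, overlap 3
        universe = [f"g{i}" for i in range(20)]
        a = universe[:5]
        b = universe[2:7]
        res = overlap_test(a, b, universe)
        assert res.n_overlap == 3
        exact = sum(
            comb(5, k, exact=True) * comb(15, 5 - k, exact=True)
            for k in range(3, 6)
        ) / comb(20, 5, exact=True)
        assert res.hypergeometric_p == pytest.approx(exact)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(33)
        universe = list(range(40))
        a = set(range(12))
        b = set(range(8, 22))
        res = overlap_test(
            [str(g) for g in a], [str(g) for g in b],
            [str(g) for g in universe],
        )
        draws = 100_000
        hits = 0
        arr = np.array(universe)
        for _ in range(draws):
            samp = set(rng.choice(arr, size=len(b), replace=False).tolist())
            hits += len(a & samp) >= res.n_overlap
        mc = hits / draws
        se = math.sqrt(mc * (1 - mc) / draws)
        assert abs(res.hypergeometric_p - mc) <= 3 * se + 1e-12

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(["a"], ["b"], ["b"])


class TestRemoveAndRecompute:
    @staticmethod
    def _fixture():
        rng = np.random.default_rng(34)
        n = 300
        records = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "call": rng.choice(["MBG", "FBG", "UBG"], size=n, p=[0.2, 0.2, 0.6]),
            }
        )
        classes = {
            f"g{i}": ChromClass.X if rng.uniform() < 0.2 else ChromClass.AUTOSOME
            for i in range(n)
        }
        return records, classes

    def test_empty_removal_is_identity(self):
        records, classes = self._fixture()
        counts, res = remove_and_recompute(records, classes, [])
        base = class_counts(records, classes)
        assert counts.counts == base.counts
        assert res.p_value == enrich_class(base, "MBG").p_value

    def test_removing_all_x_mbg_zeroes_percentage(self):
        records, classes = self._fixture()
        x_mbg = [
            g
            for g, c in zip(records["gene_id"], records["call"])
            if c == "MBG" and classes[g] is ChromClass.X
        ]
        counts, _ = remove_and_recompute(records, classes, x_mbg)
        assert counts.pct_x("MBG") == 0

    def test_equals_from_scratch_run_on_reduced_universe(self):
        records, classes = self._fixture()
        removal = records["gene_id"].iloc[::7].tolist()
        counts, res = remove_and_recompute(records, classes, removal)
        reduced = records[~records["gene_id"].isin(removal)]
        fresh = class_counts(reduced, classes)
        assert counts.counts == fresh.counts
        assert res.oe_ratio == pytest.approx(
            enrich_class(fresh, "MBG").oe_ratio
        )

    def test_disjoint_removal_preserves_observed_x(self):
        records, classes = self._fixture()
        non_mbg = records.loc[records["call"] != "MBG", "gene_id"].tolist()[:40]
        base = class_counts(records, classes)
        counts, res = remove_and_recompute(records, classes, non_mbg)
        assert res.observed_x == base.count_x("MBG")
        assert counts.counts["MBG"] == base.counts["MBG"]
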