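"""Regression, rank tests against enumeration, zonal/asymmetry/proximity
analyses and driver convergence summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonmosaic.spatial import (
    age_burden_regression,
    asymmetry_analysis,
    driver_summary,
    group_test,
    proximity_analysis,
    zonal_comparison,
)


class TestRegression:
    def test_noiseless_line_recovers_slope_exactly(self):
        df = pd.DataFrame({"age": [50.0, 55, 62, 70, 80], "tissue": "normal"})
        df["burden"] = 16.0 * df["age"]
        res = age_burden_regression(df)
        assert res.slope == pytest.approx(16.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_burden_zero_slope(self):
        df = pd.DataFrame({"age": [50.0, 60, 70], "burden": [5.0, 5, 5]})
        res = age_burden_regression(df)
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_constant_age_rejected(self):
        df = pd.DataFrame({"age": [60.0, 60, 60], "burden": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            age_burden_regression(df)

    def test_ci_coverage_of_generating_slope(self, rng):
        hits = 0
        for _ in range(100):
            age = rng.uniform(50, 80, 60)
            burden = rng.poisson(np.maximum(43.4 * age, 1))
            df = pd.DataFrame({"age": age, "burden": burden})
            res = age_burden_regression(df)
            hits += res.slope_ci[0] <= 43.4 <= res.slope_ci[1]
        assert hits >= 90


def mw_enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments (permutation distribution of U)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    m = len(y)
    mid = n * m / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )
        if abs(u - mid) >= abs(obs - mid) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestGroupTests:
    def test_exact_mannwhitney_small_example(self):
        res = group_test([[1, 2], [3, 4]], kind="mannwhitney")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1 / 3)

    @given(
        x=st.lists(st.integers(0, 20), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 20), min_size=2, max_size=6),
    )
    @settings(max_examples=40, deadline=None)
    def test_mannwhitney_matches_enumeration(self, x, y):
        x, y = np.array(x, float), np.array(y, float)
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if ties:
            return  # exact enumeration guarantee only holds without ties
        ours = group_test([x, y], kind="mannwhitney").p_value
        assert ours == pytest.approx(mw_enumeration_p(x, y), abs=1e-9)

    def test_identical_groups_kruskal_null(self):
        res = group_test([[1.0, 1, 1], [1.0, 1, 1]], kind="kruskal")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chisq_closed_form_diagonal_table(self):
        res = group_test([[10, 0], [0, 10]], kind="chisq")
        assert res.statistic == pytest.approx(20.0)

    def test_type_one_error_calibration(self, rng):
        reps = 2000
        rej = {"mannwhitney": 0, "kruskal": 0, "chisq": 0}
        for _ in range(reps):
            x, y, z = rng.normal(size=(3, 30))
            rej["mannwhitney"] += group_test([x, y], kind="mannwhitney").p_value <= 0.05
            rej["kruskal"] += group_test([x, y, z], kind="kruskal").p_value <= 0.05
            tab = np.array(
                [
                    [int((x > 0).sum()), int((x <= 0).sum())],
                    [int((y > 0).sum()), int((y <= 0).sum())],
                ]
            )
            rej["chisq"] += group_test(tab, kind="chisq").p_value <= 0.05
        for kind, n_rej in rej.items():
            assert abs(n_rej / reps - 0.05) <= 0.015, kind


class TestZonal:
    def test_ordered_medians_reported(self, rng):
        rows = []
        for zone, shift in (("PZ", 40), ("CZ", 20), ("TZ", 0)):
            for v in rng.normal(100 + shift, 5, 12):
                rows.append(dict(zone=zone, burden=v))
        res = zonal_comparison(pd.DataFrame(rows))
        assert list(res.group_summary) == ["PZ", "CZ", "TZ"]
        assert res.p_value < 0.01

    def test_identical_zones_nonsignificant(self):
        df = pd.DataFrame(
            dict(zone=["PZ"] * 5 + ["TZ"] * 5, burden=[7.0] * 10)
        )
        assert zonal_comparison(df).p_value > 0.9

    def test_single_zone_rejected(self):
        df = pd.DataFrame(dict(zone=["PZ"] * 5, burden=range(5)))
        with pytest.raises(ValueError):
            zonal_comparison(df)


class TestAsymmetry:
    @staticmethod
    def sided_frame(rng, right_boost=1.0, n=10):
        rows = []
        for side, sign in (("L", -1), ("R", 1)):
            boost = right_boost if sign > 0 else 1.0
            for i in range(n):
                rows.append(
                    dict(
                        x=sign * (1 + i % 3), y=(i % 5) - 2, z=1 + i % 4,
                        burden=rng.normal(100 * boost, 10),
                        telomere_length=rng.normal(6, 0.5),
                        ps_count=rng.poisson(30 * boost),
                        total_count=200,
                    )
                )
        return pd.DataFrame(rows)

    def test_right_enriched_burden_detected(self, rng):
        hits = 0
        for _ in range(100):
            df = self.sided_frame(rng, right_boost=1.5)
            res = asymmetry_analysis(df, "lateral")
            right_higher = (
                res["burden"].group_summary["right"]
                > res["burden"].group_summary["left"]
            )
            hits += right_higher and res["burden"].p_value < 0.05
        assert hits >= 80

    def test_null_pvalues_roughly_uniform(self, rng):
        from scipy.stats import kstest

        ps = [
            asymmetry_analysis(self.sided_frame(rng), "lateral")["burden"].p_value
            for _ in range(500)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_pooled_ps_proportion_chisq(self):
        df = pd.DataFrame(
            [
                dict(x=-1, y=0, z=1, ps_count=30, total_count=200),
                dict(x=-2, y=0, z=1, ps_count=0, total_count=0),
                dict(x=1, y=0, z=1, ps_count=60, total_count=200),
                dict(x=2, y=0, z=1, ps_count=0, total_count=0),
            ]
        )
        res = asymmetry_analysis(df, "lateral", fields=())
        assert res["ps_proportion"].p_value < 0.05

    def test_one_sided_data_rejected(self):
        df = pd.DataFrame(dict(x=[1, 2], y=[0, 0], z=[1, 1], burden=[1.0, 2.0]))
        with pytest.raises(ValueError):
            asymmetry_analysis(df, "lateral")


class TestProximity:
    @staticmethod
    def trio_frame(vals):
        rows = []
        for i, (n1, n2) in enumerate(vals):
            rows.append(dict(case_id=f"c{i}", role="N1", burden=n1))
            rows.append(dict(case_id=f"c{i}", role="N2", burden=n2))
        return pd.DataFrame(rows)

    def test_identical_pairs_p_one(self):
        df = self.trio_frame([(5, 5), (9, 9), (7, 7)])
        assert proximity_analysis(df).p_value == pytest.approx(1.0)

    def test_type_one_error_controlled(self, rng):
        rej = 0
        reps = 200
        for _ in range(reps):
            vals = rng.normal(100, 10, size=(20, 2))
            rej += proximity_analysis(self.trio_frame(vals), seed=1).p_value <= 0.05
        assert rej / reps <= 0.08

    def test_power_against_thirty_percent_shift(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            n2 = rng.normal(100, 15, 20)
            n1 = n2 * 1.3 + rng.normal(0, 5, 20)
            vals = np.column_stack([n1, n2])
            hits += proximity_analysis(self.trio_frame(vals), seed=1).p_value < 0.05
        assert hits / reps >= 0.7

    def test_missing_pair_member_rejected(self):
        df = pd.DataFrame([dict(case_id="c0", role="N1", burden=5.0)])
        with pytest.raises(ValueError):
            proximity_analysis(df)


class TestDriverSummary:
    @staticmethod
    def tables(gene_rows):
        samples = pd.DataFrame(
            [
                dict(case_id="C1", sample_id=f"s{i}", tissue=t)
                for i, t in enumerate(["normal"] * 5 + ["BPH"] * 3)
            ]
        )
        variants = pd.DataFrame(
            [
                dict(
                    case_id="C1", sample_id=sid, variant_id=f"v{j}",
                    chrom="1", pos=j + 1, alt_count=8, total_depth=20,
                    gene=g, effect="missense",
                )
                for j, (sid, g) in enumerate(gene_rows)
            ]
        )
        return variants, samples

    def test_empty_driver_list_counts_zero(self):
        variants, samples = self.tables([("s0", "FOXA1")])
        out = driver_summary(variants, samples, driver_genes=(), pathway_genes=())
        assert all(v["n_driver_mutations"] == 0 for v in out["per_tissue"].values())

    def test_singleton_pathway_hits_in_disjoint_samples_flag_convergence(self):
        genes = ["KRAS", "HRAS", "NRAS", "BRAF", "EGFR"]
        variants, samples = self.tables(
            [(f"s{i}", g) for i, g in enumerate(genes)]
        )
        out = driver_summary(variants, samples)
        assert out["convergence"]["C1"]["convergent"]
        assert out["convergence"]["C1"]["n_genes"] == 5

    def test_mean_per_sample_counts(self):
        variants, samples = self.tables([("s0", "FOXA1"), ("s1", "TP53")])
        out = driver_summary(variants, samples)
        assert out["per_tissue"]["normal"]["n_driver_mutations"] == 2
        assert out["per_tissue"]["normal"]["mean_per_sample"] == pytest.approx(0.4)

    def test_missing_annotation_rejected(self):
        variants, samples = self.tables([("s0", "FOXA1")])
        with pytest.raises(ValueError):
            driver_summary(variants.drop(columns=["effect"]), samples)
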