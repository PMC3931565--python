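"""Heterosis scores, cross classes and the associated classical tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yeastvigor.heterosis import (
    HeterosisModel,
    bestparent_heterosis,
    classify_cross,
    divergence_correlation,
    heterosis_scores,
    heterosis_summary,
    midparent_heterosis,
    oneway_anova_F,
    significance_stars,
    welch_t,
)
from yeastvigor.io import DivergenceMatrix

finite = st.floats(min_value=-10, max_value=10, allow_nan=False)


class TestScores:
    def test_hybrid_at_midparent_scores_zero(self):
        assert midparent_heterosis(0.5, 0.4, 0.6) == pytest.approx(0.0)

    def test_midparent_arithmetic(self):
        assert midparent_heterosis(0.55, 0.4, 0.6) == pytest.approx(0.05)

    def test_bestparent_positive_when_hybrid_beats_best(self):
        assert bestparent_heterosis(0.65, 0.4, 0.6) == pytest.approx(0.05)

    def test_bestparent_zero_at_best_parent(self):
        assert bestparent_heterosis(0.6, 0.4, 0.6) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=200)
    @given(fh=finite, f1=finite, f2=finite)
    def test_mph_at_least_bph_and_parent_symmetric(self, fh, f1, f2):
        mph = midparent_heterosis(fh, f1, f2)
        bph = bestparent_heterosis(fh, f1, f2)
        assert mph >= bph - 1e-12
        assert mph == pytest.approx(midparent_heterosis(fh, f2, f1))
        assert bph == pytest.approx(bestparent_heterosis(fh, f2, f1))
        if f1 == f2:
            assert mph == pytest.approx(bph)

    @settings(derandomize=True, max_examples=100)
    @given(fh=finite, f1=finite, f2=finite, shift=finite)
    def test_scores_invariant_under_environment_shift(self, fh, f1, f2, shift):
        assert midparent_heterosis(fh + shift, f1 + shift, f2 + shift) == (
            pytest.approx(midparent_heterosis(fh, f1, f2), abs=1e-9)
        )
        assert bestparent_heterosis(fh + shift, f1 + shift, f2 + shift) == (
            pytest.approx(bestparent_heterosis(fh, f1, f2), abs=1e-9)
        )


class TestCrossClass:
    @pytest.mark.parametrize(
        "o1,o2,expected",
        [
            ("domesticated", "domesticated", "DxD"),
            ("wild", "domesticated", "mixed"),
            ("domesticated", "wild", "mixed"),
            ("wild", "wild", "WxW"),
        ],
    )
    def test_classification(self, o1, o2, expected):
        assert classify_cross(o1, o2) == expected

    def test_unknown_origin_rejected(self):
        with pytest.raises(ValueError, match="origin"):
            classify_cross("domesticated", "feral")

    def test_full_design_class_sizes(self):
        # 13 domesticated + 9 wild strains crossed in all pairs
        origins = ["domesticated"] * 13 + ["wild"] * 9
        classes = [
            classify_cross(a, b) for a, b in itertools.combinations(origins, 2)
        ]
        counts = pd.Series(classes).value_counts()
        assert len(classes) == 231
        assert counts["DxD"] == 78
        assert counts["mixed"] == 117
        assert counts["WxW"] == 36


class TestSummary:
    def _scores(self, values, cls="DxD"):
        return pd.DataFrame(
            {
                "hybrid": [f"h{i}" for i in range(len(values))],
                "environment": "e",
                "mph": values,
                "bph": [v - 0.01 for v in values],
                "cross_class": cls,
            }
        )

    def test_uniform_positive_scores(self):
        s = heterosis_summary(self._scores([0.1, 0.1, 0.1]))
        assert s.loc[0, "mean_mph"] == pytest.approx(0.1)
        assert s.loc[0, "prop_mph_positive"] == 1.0

    def test_balanced_scores(self):
        s = heterosis_summary(self._scores([0.1, -0.1]))
        assert s.loc[0, "mean_mph"] == pytest.approx(0.0)
        assert s.loc[0, "prop_mph_positive"] == 0.5

    def test_exact_zero_counts_as_non_positive_and_reported(self):
        s = heterosis_summary(self._scores([0.0, 0.2]))
        assert s.loc[0, "prop_mph_positive"] == 0.5
        assert s.loc[0, "prop_mph_zero"] == 0.5


class TestClassicalTests:
    def test_anova_hand_computed_example(self):
        res = oneway_anova_F([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)

    def test_anova_equal_group_means_give_zero_F(self):
        res = oneway_anova_F([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.statistic == pytest.approx(0.0)

    def test_anova_empty_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova_F([1.0, 2.0], [])

    def test_welch_identical_samples(self):
        res = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_shift_closed_form(self):
        # equal variances, equal n: t = d / sqrt(2 s^2 / n), df = 2n - 2
        res = welch_t([11, 12, 13, 14], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(10.0 / np.sqrt(5.0 / 6.0))
        assert res.df == pytest.approx(6.0)

    def test_welch_degenerate_constants(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_stars(self):
        assert significance_stars(0.2) == ""
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"


class TestDivergenceCorrelation:
    def _matrix(self):
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], dtype=float
        )
        return DivergenceMatrix(labels, d)

    def test_metric_proportional_to_divergence_gives_unit_r(self):
        div = self._matrix()
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")]
        df = pd.DataFrame(
            {
                "parent1": [p[0] for p in pairs],
                "parent2": [p[1] for p in pairs],
                "mph": [2.0 * div.distance(*p) for p in pairs],
            }
        )
        res = divergence_correlation(df, div)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value < 0.001

    def test_zero_variance_flagged(self):
        div = self._matrix()
        df = pd.DataFrame(
            {"parent1": ["a", "a", "b"], "parent2": ["b", "c", "c"],
             "mph": [1.0, 1.0, 1.0]}
        )
        res = divergence_correlation(df, div)
        assert np.isnan(res.statistic)

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame(
            {"parent1": ["a"], "parent2": ["b"], "mph": [1.0]}
        )
        with pytest.raises(ValueError, match="3"):
            divergence_correlation(df, self._matrix())

    def test_null_correlation_near_zero_on_average(self):
        # independent metric: mean r over replicates must vanish
        rng = np.random.default_rng(0)
        labels = [f"s{i}" for i in range(13)]
        pairs = list(itertools.combinations(labels, 2))  # 78 hybrids
        d = np.zeros((13, 13))
        iu = np.triu_indices(13, 1)
        d[iu] = rng.uniform(1, 10, iu[0].size)
        div = DivergenceMatrix(labels, d + d.T)
        rs = []
        for _ in range(500):
            df = pd.DataFrame(
                {
                    "parent1": [p[0] for p in pairs],
                    "parent2": [p[1] for p in pairs],
                    "mph": rng.normal(size=len(pairs)),
                }
            )
            rs.append(divergence_correlation(df, div).statistic)
        assert abs(np.mean(rs)) < 0.05


class TestHeterosisModel:
    def _inputs(self):
        metadata = pd.DataFrame(
            {"strain": ["p1", "p2", "p3"],
             "origin": ["domesticated", "domesticated", "wild"]}
        )
        crosses = pd.DataFrame(
            {"hybrid": ["h12", "h13"], "parent1": ["p1", "p1"],
             "parent2": ["p2", "p3"]}
        )
        rows = []
        fit = {
            ("p1", "e1"): 0.4, ("p2", "e1"): 0.6, ("p3", "e1"): 0.5,
            ("h12", "e1"): 0.55, ("h13", "e1"): 0.42,
            ("p1", "e2"): 0.3, ("p2", "e2"): 0.5, ("h12", "e2"): 0.45,
            ("h13", "e2"): 0.35,  # p3 missing in e2
        }
        for (s, e), v in fit.items():
            for rep in (1, 2):
                rows.append((s, e, rep, v))
        fitness = pd.DataFrame(
            rows, columns=["strain", "environment", "replicate", "mgr"]
        )
        return fitness, metadata, crosses

    def test_scores_match_hand_computation(self):
        fitness, metadata, crosses = self._inputs()
        res = HeterosisModel(fitness, metadata, crosses).fit()
        s = res.scores.set_index(["hybrid", "environment"])
        assert s.loc[("h12", "e1"), "mph"] == pytest.approx(0.05)
        assert s.loc[("h12", "e1"), "bph"] == pytest.approx(-0.05)
        assert s.loc[("h12", "e1"), "cross_class"] == "DxD"
        assert s.loc[("h13", "e1"), "mph"] == pytest.approx(0.42 - 0.45)
        assert s.loc[("h13", "e1"), "cross_class"] == "mixed"

    def test_hybrid_with_missing_parent_excluded_from_environment(self):
        fitness, metadata, crosses = self._inputs()
        res = HeterosisModel(fitness, metadata, crosses).fit()
        assert ("h13", "e2") not in set(
            zip(res.scores["hybrid"], res.scores["environment"])
        )
        assert ("h12", "e2") in set(
            zip(res.scores["hybrid"], res.scores["environment"])
        )

    def test_qc_failures_dropped(self):
        fitness, metadata, crosses = self._inputs()
        fitness["qc_pass"] = True
        # poison one replicate but mark it qc-failing: result unchanged
        poisoned = fitness.copy()
        poisoned.loc[len(poisoned)] = ["h12", "e1", 3, 99.0, False]
        r1 = HeterosisModel(fitness, metadata, crosses).fit()
        r2 = HeterosisModel(poisoned, metadata, crosses).fit()
        pd.testing.assert_frame_equal(r1.scores, r2.scores)

    def test_summary_mentions_classes(self):
        fitness, metadata, crosses = self._inputs()
        text = HeterosisModel(fitness, metadata, crosses).fit().summary()
        assert "DxD" in text and "Heterosis" in text


class TestSyntheticLoadedSimulation:
    def test_complementation_gradient_across_classes(self):
        # domesticated-clade-only mutation load (h = 0): class means must
        # order DxD > mixed > WxW with WxW at zero
        from yeastvigor.simulate import SimulationParams, simulate_fitness_table

        mm = []
        for seed in range(5):
            sim = simulate_fitness_table(SimulationParams(), seed=seed)
            res = HeterosisModel(
                sim["fitness"], sim["metadata"], sim["crosses"]
            ).fit()
            mm.append(res.class_summary().set_index("cross_class")["mean_mph"])
        mean = pd.concat(mm, axis=1).mean(axis=1)
        assert mean["DxD"] > mean["mixed"] > mean["WxW"]
        assert abs(mean["WxW"]) < 0.005


class TestCorrelationGridOptions:
    def _fitted(self):
        from yeastvigor.simulate import SimulationParams, simulate_fitness_table

        sim = simulate_fitness_table(
            SimulationParams(n_dom=5, n_wild=4, n_env=3), seed=8
        )
        return HeterosisModel(
            sim["fitness"], sim["metadata"], sim["crosses"],
            divergence=sim["divergence"],
        ).fit()

    def test_bh_adjustment_column_is_monotone_in_p(self):
        res = self._fitted()
        grid = res.divergence_correlations(adjust="bh")
        ok = grid.dropna(subset=["p", "p_bh"]).sort_values("p")
        assert (ok["p_bh"] >= ok["p"] - 1e-12).all()
        assert ok["p_bh"].is_monotonic_increasing

    def test_per_hybrid_unit_summary(self):
        res = self._fitted()
        cells = res.class_summary(unit="cells")
        hybrids = res.class_summary(unit="hybrids")
        # per-hybrid rows pool environments: one row per hybrid
        assert hybrids["n"].sum() == res.scores["hybrid"].nunique()
        assert cells["n"].sum() == len(res.scores)
        with pytest.raises(ValueError, match="pool"):
            res.class_summary(per_environment=True, unit="hybrids")
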