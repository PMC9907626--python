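import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsicolor import (
    StudyDesign,
    SummaryStats,
    ValidationError,
    account_missing,
    anova_from_summary,
    anova_oneway,
    boxplot_summary,
    correlate,
    enumerate_design,
    parse_ranking,
    percent_nonlinearity,
    run_replication,
    tukey_grouping,
)

# Reference summary statistics used as worked-example inputs throughout:
# per-product mean/SD of the dL* and da* effects (2nd repetition, imager,
# operator 2), n = 9 models per product.
DL_SUMMARIES = {
    "A": SummaryStats(0.27, 0.69, 9),
    "B": SummaryStats(3.95, 1.04, 9),
    "C": SummaryStats(1.46, 0.77, 9),
}
DA_SUMMARIES = {
    "A": SummaryStats(-0.24, 0.84, 9),
    "B": SummaryStats(-2.13, 1.17, 9),
    "C": SummaryStats(-1.34, 0.80, 9),
}


class TestDesignAccounting:
    def test_validation_study_counts(self):
        counts = enumerate_design(StudyDesign())
        assert counts.hsi_images == 216
        assert counts.spectra == 108
        assert counts.independent_tests == 12

    def test_minimal_design(self):
        design = StudyDesign(
            n_models=1, products=("X", "Y"), n_repetitions=1,
            operators=("Op.1",), instruments=("HSI",),
        )
        counts = enumerate_design(design)
        assert counts.hsi_images == 4  # 1 model x 2 products x 2 time points
        assert counts.independent_tests == 2

    def test_duplicate_products_rejected(self):
        with pytest.raises(ValidationError):
            StudyDesign(products=("A", "A", "B"))


def full_acquisition(design):
    return [
        (m, p, r, o, tp)
        for m in range(design.n_models)
        for p in design.products
        for r in range(design.n_repetitions)
        for o in design.operators
        for tp in design.time_points
    ]


class TestAccountMissing:
    def test_complete_dataset_pairs(self):
        design = StudyDesign()
        report = account_missing(full_acquisition(design), design)
        assert report["n_images"] == 216
        assert report["n_pairs"] == 108

    def test_three_removals_from_distinct_sessions(self):
        design = StudyDesign()
        acquired = full_acquisition(design)
        removed = [k for k in acquired if k[0] == 0 and k[2] == 0
                   and k[3] == "Op.1" and k[4] == "T0"][:3]
        assert len(removed) == 3
        kept = [k for k in acquired if k not in removed]
        report = account_missing(kept, design)
        assert report["n_images"] == 213
        assert report["n_pairs"] == 105
        assert len(report["incomplete_sessions"]) == 3

    def test_removing_both_images_of_one_session_costs_one_pair(self):
        design = StudyDesign()
        acquired = full_acquisition(design)
        session = acquired[0][:4]
        kept = [k for k in acquired if k[:4] != session]
        assert account_missing(kept, design)["n_pairs"] == 107

    def test_duplicate_keys_rejected(self):
        design = StudyDesign()
        acquired = full_acquisition(design)
        with pytest.raises(ValidationError):
            account_missing(acquired + [acquired[0]], design)


class TestAnova:
    def test_identical_constant_groups(self):
        groups = {"A": [2.0] * 5, "B": [2.0] * 5, "C": [2.0] * 5}
        res = anova_oneway(groups)
        assert res.F == 0.0 and res.p == 1.0

    def test_reference_summary_example(self):
        res = anova_from_summary(DL_SUMMARIES)
        assert res.F == pytest.approx(44.3, abs=0.1)
        assert res.p < 1e-7

    def test_summary_route_matches_raw_route_exactly(self, rng):
        for _ in range(20):
            groups = {
                name: rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), size=n)
                for name, n in zip("ABCD", rng.integers(3, 12, 4))
            }
            raw = anova_oneway(groups)
            summaries = {
                k: SummaryStats(float(np.mean(v)), float(np.std(v, ddof=1)), len(v))
                for k, v in groups.items()
            }
            summ = anova_from_summary(summaries)
            assert summ.F == pytest.approx(raw.F, abs=1e-10)
            assert summ.p == pytest.approx(raw.p, rel=1e-9)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway({"A": [1.0], "B": [1.0, 2.0]})


class TestTukeyGrouping:
    def test_three_well_separated_groups(self):
        res = tukey_grouping({
            "A": SummaryStats(1.16, 0.3, 9),
            "B": SummaryStats(-1.2, 0.3, 9),
            "C": SummaryStats(-2.2, 0.3, 9),
        })
        assert res.ranking_string == "C,B,A"
        assert res.n_groups == 3 and not res.overlapping

    def test_no_significant_pairs_single_token(self, rng):
        res = tukey_grouping({
            "A": SummaryStats(0.10, 1.5, 9),
            "B": SummaryStats(-0.15, 1.5, 9),
            "C": SummaryStats(0.02, 1.5, 9),
        })
        assert res.n_groups == 1
        assert "," not in res.ranking_string
        assert sorted(res.ranking_string) == ["A", "B", "C"]

    def test_reference_dL_example_two_groups(self):
        res = tukey_grouping(DL_SUMMARIES, alpha=0.01)
        assert res.ranking_string == "AC,B"
        assert res.n_groups == 2 and not res.overlapping

    def test_reference_da_example_two_overlapping_letters(self):
        res = tukey_grouping(DA_SUMMARIES, alpha=0.01)
        assert res.n_groups == 2
        assert res.overlapping
        assert res.groups[0] == ("B", "C") and res.groups[1] == ("C", "A")

    def test_matches_statsmodels_pairwise_oracle(self, rng):
        """Pairwise significance decisions equal statsmodels' Tukey HSD on
        random raw-data instances."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        for trial in range(15):
            k = int(rng.integers(3, 5))
            names = [chr(65 + i) for i in range(k)]
            groups = {
                name: rng.normal(rng.uniform(-1.5, 1.5), 1.0, size=9)
                for name in names
            }
            alpha = (0.01, 0.05)[trial % 2]
            res = tukey_grouping(groups, alpha=alpha, gate_on_anova=False)
            data = np.concatenate(list(groups.values()))
            labels = np.repeat(names, [len(v) for v in groups.values()])
            sm = pairwise_tukeyhsd(data, labels, alpha=alpha)
            for (g1, g2), reject in zip(
                itertools.combinations(sorted(names), 2),
                sm.reject,
            ):
                key = (g1, g2) if (g1, g2) in res.pairwise_p else (g2, g1)
                assert (res.pairwise_p[key] < alpha) == bool(reject), (
                    f"trial {trial}: pair {g1}-{g2}"
                )

    def test_ranking_string_round_trips_to_partition(self):
        res = tukey_grouping(DL_SUMMARIES)
        assert parse_ranking(res.ranking_string) == [("A", "C"), ("B",)]
        res3 = tukey_grouping({
            "A": SummaryStats(3.0, 0.2, 9),
            "B": SummaryStats(-3.0, 0.2, 9),
            "C": SummaryStats(0.0, 0.2, 9),
        })
        assert parse_ranking(res3.ranking_string) == [tuple(g) for g in res3.groups]

    def test_anova_gate_forces_single_group(self):
        summaries = {
            "A": SummaryStats(0.0, 1.0, 3),
            "B": SummaryStats(0.4, 1.0, 3),
            "C": SummaryStats(0.8, 1.0, 3),
        }
        gated = tukey_grouping(summaries, alpha=0.01)
        assert gated.anova_gated and gated.n_groups == 1


class TestCorrelate:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        res = correlate(x, x + 0.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.mean_abs_diff == 0.0
        assert res.percent_nl == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelation(self):
        x = np.arange(8.0)
        assert correlate(x, -x).pearson_r == pytest.approx(-1.0)

    def test_five_point_hand_example(self):
        x = np.arange(5.0)
        y = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        res = correlate(x, y)
        assert res.slope == pytest.approx(1.2)
        assert res.intercept == pytest.approx(-0.2)
        assert res.percent_nl == pytest.approx(16.0)
        assert res.delta_plus == pytest.approx(0.4)
        assert res.delta_minus == pytest.approx(-0.4)

    def test_too_few_or_degenerate_pairs_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50))
    def test_percent_nl_scale_invariance(self, scale):
        x = np.arange(5.0)
        y = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
        base = correlate(x, y).percent_nl
        scaled = correlate(scale * x, scale * y).percent_nl
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_maximum_signal_rejected(self):
        with pytest.raises(ValidationError):
            percent_nonlinearity(
                np.arange(4.0), np.arange(4.0), 1.0, 0.0, maximum_signal=0.0
            )


class TestBoxplotSummary:
    def test_median_of_one_to_nine(self):
        assert boxplot_summary(np.arange(1.0, 10.0)).Q2 == 5.0

    def test_constant_sample(self):
        res = boxplot_summary([3.0] * 7)
        assert res.Q1 == res.Q2 == res.Q3 == 3.0
        assert res.outliers == ()
        assert res.whisker_low == res.whisker_high == 3.0

    def test_extreme_point_flagged_outlier(self):
        res = boxplot_summary([0.0, 0.0, 0.0, 0.0, 100.0])
        assert res.outliers == (100.0,)
        assert res.whisker_high == 0.0

    def test_quartile_ordering_invariant(self, rng):
        for _ in range(10):
            res = boxplot_summary(rng.normal(size=rng.integers(1, 40)))
            assert res.Q1 <= res.Q2 <= res.Q3
            assert res.whisker_low <= res.Q1 and res.whisker_high >= res.Q3


def synthetic_effects_frame(rng, means=None):
    """Effect records with a realistic variance hierarchy: a per-model
    product response shared across repetitions (SD 0.7), a per-repetition
    drift (SD 0.3), and small per-operator measurement noise (SD 0.05)."""
    means = means or {"A": (0.3, -0.25, 1.1), "B": (3.9, -2.1, -1.2),
                      "C": (1.5, -1.5, -2.2)}
    rows = []
    for prod, mu in means.items():
        for m in range(9):
            model_dev = rng.normal(0.0, 0.7, 3)
            for rep in (1, 2):
                rep_dev = rng.normal(0.0, 0.3, 3)
                for op in ("Op.1", "Op.2"):
                    d = np.asarray(mu) + model_dev + rep_dev \
                        + rng.normal(0.0, 0.05, 3)
                    rows.append({
                        "model": f"M{m}", "product": prod, "repetition": rep,
                        "operator": op, "instrument": "HSI",
                        "dL": d[0], "da": d[1], "db": d[2],
                        "dE": float(np.linalg.norm(d)),
                    })
    return pd.DataFrame(rows)


class TestRunReplication:
    def test_injected_ordering_recovered_in_every_subset(self, rng):
        report = run_replication(synthetic_effects_frame(rng))
        dl = report.groupings[report.groupings.parameter == "dL"]
        assert len(dl) == 4
        for ranking in dl.ranking:
            assert ranking.replace(",", "") == "ACB"

    def test_duplicated_records_do_not_change_output(self, rng):
        effects = synthetic_effects_frame(rng)
        base = run_replication(effects).groupings
        doubled = run_replication(
            pd.concat([effects, effects], ignore_index=True)
        ).groupings
        pd.testing.assert_frame_equal(base, doubled)

    def test_operator_and_repetition_correlations_present(self, rng):
        report = run_replication(synthetic_effects_frame(rng))
        for corr in (report.operator_correlations, report.repetition_correlations):
            assert set(corr) == {"dL", "da", "db"}
            assert corr["dL"].pearson_r > 0.9  # strong product effect dominates

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            run_replication(pd.DataFrame({"model": [], "product": []}))

    def test_summary_text_mentions_each_subset(self, rng):
        text = run_replication(synthetic_effects_frame(rng)).summary_text()
        assert "rep1 Op.1" in text and "rep2 Op.2" in text
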