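"""Paired experiment engine and its statistical summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mccv.comparison as comparison
from mccv.comparison import (
    ExperimentConfig,
    PairedResults,
    run_experiment,
    sd_by_arm,
    summarize,
)
from mccv.exceptions import InvalidArgumentError
from mccv.synthetic_data import GeneratorConfig


def make_paired(mccv_vals, cv_vals, method="lda", metric="accuracy"):
    mccv_vals = np.asarray(mccv_vals, dtype=float)
    cv_vals = np.asarray(cv_vals, dtype=float)
    cfg = ExperimentConfig(
        data=GeneratorConfig(n_samples=60, seed=0),
        n_outer_sims=len(mccv_vals),
        methods=(method,),
        metric_names=(metric,),
    )
    return PairedResults(
        cfg,
        {(method, metric): {"mccv": mccv_vals, "cv": cv_vals}},
        {(method, metric): np.arange(len(mccv_vals))},
    )


@pytest.fixture(scope="module")
def tiny_run():
    cfg = ExperimentConfig(
        data=GeneratorConfig(n_samples=60, seed=3),
        n_outer_sims=3,
        k=5,
        t=1,
        methods=("lda",),
        metric_names=("accuracy",),
        seed=11,
    )
    return cfg, run_experiment(cfg)


class TestRunExperiment:
    def test_shape_contract(self, tiny_run):
        _, paired = tiny_run
        m, c = paired.arms("lda", "accuracy")
        assert len(m) == len(c) == 3

    def test_both_arms_same_split_count_by_default(self, tiny_run):
        cfg, _ = tiny_run
        assert cfg.effective_s_mccv == 5  # C(5,1)

    def test_determinism(self, tiny_run):
        cfg, paired = tiny_run
        again = run_experiment(cfg)
        for key in paired.arm_values:
            for arm in ("mccv", "cv"):
                assert np.array_equal(
                    paired.arm_values[key][arm], again.arm_values[key][arm]
                )

    def test_tidy_output_schema(self, tiny_run):
        _, paired = tiny_run
        tidy = paired.to_tidy()
        assert list(tidy.columns) == ["sim", "method", "metric", "arm", "mean_value"]
        assert set(tidy["arm"]) == {"mccv", "cv"}
        assert len(tidy) == 6  # 3 sims x 2 arms

    def test_oracle_classifier_gives_d_zero(self, monkeypatch):
        """A stub predicting y_true exactly yields mean accuracy 1.0 in both arms."""
        from mccv.classifiers import PredictionResult

        def oracle(spec, table, train, test, seed=None):
            return PredictionResult(table.y[test], table.y[test], {})

        monkeypatch.setattr(comparison.classifiers, "fit_predict", oracle)
        cfg = ExperimentConfig(
            data=GeneratorConfig(n_samples=40, seed=1),
            n_outer_sims=3,
            k=4,
            t=1,
            methods=("lda",),
            metric_names=("accuracy",),
            seed=2,
        )
        paired = run_experiment(cfg)
        m, c = paired.arms("lda", "accuracy")
        assert np.all(m == 1.0) and np.all(c == 1.0)
        assert summarize(paired)["d"].iloc[0] == 0.0

    def test_both_arms_share_one_data_realization_per_sim(self, monkeypatch):
        from mccv.classifiers import PredictionResult

        seen = []

        def spy(spec, table, train, test, seed=None):
            seen.append(table)
            return PredictionResult(table.y[test], table.y[test], {})

        monkeypatch.setattr(comparison.classifiers, "fit_predict", spy)
        cfg = ExperimentConfig(
            data=GeneratorConfig(n_samples=40, seed=1),
            n_outer_sims=2,
            k=4,
            t=1,
            methods=("lda", "glm"),
            metric_names=("accuracy",),
            seed=9,
        )
        run_experiment(cfg)
        # 2 sims x 2 methods x (4 CV + 4 MCCV) splits
        assert len(seen) == 32
        per_sim = [seen[:16], seen[16:]]
        for group in per_sim:
            assert all(t is group[0] for t in group)
        assert per_sim[0][0] is not per_sim[1][0]

    def test_default_k10_t2_gives_45_splits_per_arm(self):
        cfg = ExperimentConfig(data=GeneratorConfig(n_samples=100, seed=0))
        assert cfg.effective_s_mccv == 45

    def test_unknown_method_rejected_up_front(self):
        with pytest.raises(Exception):
            ExperimentConfig(
                data=GeneratorConfig(n_samples=100, seed=0), methods=("nope",)
            )

    def test_too_few_sims_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ExperimentConfig(data=GeneratorConfig(n_samples=100, seed=0), n_outer_sims=1)


class TestSummarize:
    def test_identical_arms_give_zero_d_and_p_one(self):
        arms = np.array([0.6, 0.7, 0.8, 0.65])
        rep = summarize(make_paired(arms, arms)).iloc[0]
        assert rep["d"] == 0.0
        assert rep["t_stat"] == 0.0 and rep["t_p"] == 1.0
        assert "all_differences_zero" in rep["flags"]

    def test_constant_shift_flagged_as_degenerate(self):
        rep = summarize(
            make_paired([0.6, 0.7, 0.8], [0.5, 0.6, 0.7])
        ).iloc[0]
        assert rep["d"] == pytest.approx(0.1)
        assert np.isinf(rep["t_stat"]) and rep["t_stat"] > 0
        assert "constant_difference" in rep["flags"]

    def test_paired_t_matches_closed_form(self):
        rng = np.random.default_rng(123)
        a, b = rng.uniform(0.5, 0.9, 100), rng.uniform(0.5, 0.9, 100)
        rep = summarize(make_paired(a, b)).iloc[0]
        diff = a - b
        t_expected = diff.mean() * np.sqrt(100) / diff.std(ddof=1)
        p_expected = 2 * stats.t.sf(abs(t_expected), 99)
        assert rep["t_stat"] == pytest.approx(t_expected, abs=1e-10)
        assert rep["t_p"] == pytest.approx(p_expected, abs=1e-10)

    def test_assumption_checks_match_scipy(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0.7, 0.02, 50), rng.normal(0.69, 0.02, 50)
        rep = summarize(make_paired(a, b)).iloc[0]
        diff = a - b
        assert rep["shapiro_p"] == pytest.approx(stats.shapiro(diff).pvalue)
        assert rep["dagostino_p"] == pytest.approx(stats.normaltest(diff).pvalue)
        assert rep["wilcoxon_p"] == pytest.approx(stats.wilcoxon(diff).pvalue)
        assert rep["levene_p"] == pytest.approx(
            stats.levene(a, b, center="mean").pvalue
        )

    def test_d_equals_mean_arm_difference(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        rep = summarize(make_paired(a, b)).iloc[0]
        assert rep["d"] == pytest.approx(a.mean() - b.mean(), abs=1e-12)
        assert rep["mccv_mean"] == pytest.approx(a.mean())
        assert rep["cv_mean"] == pytest.approx(b.mean())

    def test_type_i_error_calibrated_on_null_pairs(self):
        """Paired t rejects ~5% of null pairs (both arms same distribution)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            a = rng.normal(0.7, 0.05, 20)
            b = rng.normal(0.7, 0.05, 20)
            p = stats.ttest_rel(a, b).pvalue
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rejections / n_reps - 0.05) < 3 * se

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            summarize(make_paired([0.5, 0.6], [0.5, 0.6]))


class TestSdByArm:
    def test_constant_arm_zero(self):
        out = sd_by_arm([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert out["mccv"] == 0.0

    def test_two_point_closed_form(self):
        assert sd_by_arm([0.0, 1.0], [0.0, 1.0])["mccv"] == pytest.approx(
            np.sqrt(0.5)
        )

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(44)
        v = rng.uniform(0, 1, 100)
        mean = sum(v) / 100
        two_pass = np.sqrt(sum((x - mean) ** 2 for x in v) / 99)
        assert sd_by_arm(v, v)["mccv"] == pytest.approx(two_pass, abs=1e-12)

    def test_short_arm_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sd_by_arm([0.5], [0.5])
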