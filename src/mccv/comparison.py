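"""The paired MCCV-versus-CV experiment and its statistical summary.

For each outer simulation one data realization is obtained (a freshly
generated table, or a random subsample of a supplied pool).  Both
resampling arms — the exhaustive leave-t-out CV rounds of one balanced
fold partition, and an equal number of independent MCCV draws — evaluate
every classifier on the identical realization, so within a simulation the
two arms differ only in how the data are split.  The per-simulation mean
metric in each arm forms one paired observation; across simulations the
pairs feed

* d: mean paired difference (MCCV − CV), positive d favouring MCCV,
* a two-sided paired t-test and the Wilcoxon signed-rank fallback,
* normality checks on the differences (Shapiro–Wilk, D'Agostino), and
* a mean-centred Levene test of equal variance between the arms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from . import classifiers, metrics
from .exceptions import DegenerateSplitError, InvalidArgumentError
from .resampling import enumerate_cv_rounds, make_folds, mccv_splits
from .rng import (
    PURPOSE_CLASSIFIER,
    PURPOSE_DATA,
    PURPOSE_FOLDS,
    PURPOSE_MCCV,
    PURPOSE_SUBSAMPLE,
    child_rng,
    child_seed,
)
from .synthetic_data import FeatureTable, GeneratorConfig, generate

logger = logging.getLogger(__name__)

ARMS = ("mccv", "cv")


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one paired comparison experiment.

    ``data`` is either a GeneratorConfig (fresh table per simulation) or a
    FeatureTable pool to subsample ``subsample_size`` rows from, without
    replacement, per simulation.  ``s_mccv`` defaults to C(k, t) so both
    arms evaluate the same number of splits.
    """

    data: GeneratorConfig | FeatureTable
    n_outer_sims: int = 100
    k: int = 10
    t: int = 2
    s_mccv: int | None = None
    subsample_size: int | None = None
    # registry names, or ClassifierSpec instances for custom grids
    methods: tuple = ("lda", "glm", "bayes", "knn")
    metric_names: tuple[str, ...] = ("accuracy", "f1")
    seed: int = 0
    max_dropped_fraction: float = 0.1

    def __post_init__(self):
        if self.n_outer_sims < 2:
            raise InvalidArgumentError("n_outer_sims must be >= 2 (paired tests)")
        if not 1 <= self.t <= self.k - 1:
            raise InvalidArgumentError("t must satisfy 1 <= t <= k-1")
        if self.s_mccv is not None and self.s_mccv < 1:
            raise InvalidArgumentError("s_mccv must be >= 1")
        for m in self.metric_names:
            if m not in metrics.METRICS:
                raise InvalidArgumentError(f"unknown metric {m!r}")
        for m in self.methods:
            if isinstance(m, str):
                classifiers.get_method(m)  # fail fast on unknown names
        if isinstance(self.data, FeatureTable) and self.subsample_size is not None:
            if not 0 < self.subsample_size <= self.data.n_samples:
                raise InvalidArgumentError("subsample_size out of range")

    @property
    def effective_s_mccv(self) -> int:
        return self.s_mccv if self.s_mccv is not None else comb(self.k, self.t)

    def method_items(self) -> list[tuple[str, "classifiers.ClassifierSpec"]]:
        """(name, resolved spec) pairs for every configured method."""
        return [
            (m, classifiers.get_method(m)) if isinstance(m, str) else (m.name, m)
            for m in self.methods
        ]


@dataclass
class PairedResults:
    """Per (method, metric): aligned per-simulation mean metric vectors for both arms."""

    config: ExperimentConfig
    arm_values: dict  # (method, metric) -> {"mccv": np.ndarray, "cv": np.ndarray}
    sim_indices: dict  # (method, metric) -> np.ndarray of retained simulation ids
    n_dropped_splits: int = 0
    n_invalid_sims: int = 0

    def arms(self, method: str, metric: str) -> tuple[np.ndarray, np.ndarray]:
        v = self.arm_values[(method, metric)]
        return v["mccv"], v["cv"]

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for (method, metric), v in self.arm_values.items():
            sims = self.sim_indices[(method, metric)]
            for arm in ARMS:
                for sim, val in zip(sims, v[arm]):
                    rows.append(
                        {"sim": int(sim), "method": method, "metric": metric,
                         "arm": arm, "mean_value": float(val)}
                    )
        return pd.DataFrame(rows, columns=["sim", "method", "metric", "arm", "mean_value"])


def _realize_data(config: ExperimentConfig, sim: int) -> FeatureTable:
    if isinstance(config.data, GeneratorConfig):
        gc = config.data
        specs = gc.resolved_specs()  # held fixed across simulations of one design
        sim_cfg = GeneratorConfig(
            n_samples=gc.n_samples,
            n_features=gc.n_features,
            beta0=gc.beta0,
            beta1=gc.beta1,
            seed=child_seed(config.seed, PURPOSE_DATA, sim),
            feature_specs=specs,
        )
        return generate(sim_cfg)
    pool = config.data
    size = config.subsample_size or pool.n_samples
    rng = child_rng(config.seed, PURPOSE_SUBSAMPLE, sim)
    rows = rng.choice(pool.n_samples, size=size, replace=False)
    return pool.subset(np.sort(rows))


def _evaluate_arm(config, table, plan, spec, sim):
    """Mean of each metric over a plan's splits; drops degenerate splits."""
    sums = {m: 0.0 for m in config.metric_names}
    n_ok, n_dropped = 0, 0
    for si, (train, test) in enumerate(plan):
        try:
            result = classifiers.fit_predict(
                spec, table, train, test,
                seed=child_seed(config.seed, PURPOSE_CLASSIFIER, sim, si),
            )
        except DegenerateSplitError:
            n_dropped += 1
            logger.warning(
                "sim %d method %s: dropped degenerate split %d (%s arm)",
                sim, spec.name, si, plan.provenance,
            )
            continue
        for m in config.metric_names:
            sums[m] += metrics.score(result.y_true, result.y_pred, m)
        n_ok += 1
    if n_dropped > config.max_dropped_fraction * len(plan) or n_ok == 0:
        return None, n_dropped
    return {m: sums[m] / n_ok for m in config.metric_names}, n_dropped


def run_experiment(config: ExperimentConfig) -> PairedResults:
    """Run the full paired experiment defined by ``config``.

    All randomness is derived from ``config.seed`` through per-(simulation,
    purpose) child streams, so results are reproducible and independent of
    evaluation order.
    """
    method_items = config.method_items()
    collected = {
        (name, metric): {"mccv": [], "cv": []}
        for name, _ in method_items for metric in config.metric_names
    }
    sims_kept = {key: [] for key in collected}
    total_dropped = 0
    invalid = 0
    for sim in range(config.n_outer_sims):
        table = _realize_data(config, sim)
        if len(np.unique(table.y)) < 2:
            invalid += 1
            logger.warning("sim %d: realization has a single outcome class; skipped", sim)
            continue
        partition = make_folds(
            table.n_samples, config.k, seed=child_rng(config.seed, PURPOSE_FOLDS, sim)
        )
        plans = {
            "cv": enumerate_cv_rounds(partition, config.t),
            "mccv": mccv_splits(
                table.n_samples,
                1 - config.t / config.k,  # matches the CV arm's test fraction
                config.effective_s_mccv,
                seed=child_rng(config.seed, PURPOSE_MCCV, sim),
            ),
        }
        for name, spec in method_items:
            arm_means = {}
            valid = True
            for arm in ARMS:
                means, dropped = _evaluate_arm(config, table, plans[arm], spec, sim)
                total_dropped += dropped
                if means is None:
                    valid = False
                    break
                arm_means[arm] = means
            if not valid:
                invalid += 1
                logger.warning(
                    "sim %d method %s: >%.0f%% splits dropped; pair excluded",
                    sim, name, 100 * config.max_dropped_fraction,
                )
                continue
            for metric in config.metric_names:
                key = (name, metric)
                for arm in ARMS:
                    collected[key][arm].append(arm_means[arm][metric])
                sims_kept[key].append(sim)
    arm_values = {
        key: {arm: np.asarray(vals[arm], dtype=float) for arm in ARMS}
        for key, vals in collected.items()
    }
    sim_indices = {
        key: np.unique(np.asarray(v, dtype=int)) for key, v in sims_kept.items()
    }
    return PairedResults(config, arm_values, sim_indices, total_dropped, invalid)


def sd_by_arm(mccv_values, cv_values) -> dict[str, float]:
    """Sample standard deviation (n-1 denominator) of each arm."""
    out = {}
    for arm, values in (("mccv", mccv_values), ("cv", cv_values)):
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise InvalidArgumentError("arm length must be >= 2 for an SD")
        out[arm] = float(np.std(values, ddof=1))
    return out


def _is_constant(values: np.ndarray) -> bool:
    # constant up to float rounding: a degenerate case for scale-based tests
    return np.ptp(values) <= 1e-12 * max(1.0, float(np.max(np.abs(values))))


def _paired_tests(diff: np.ndarray) -> dict:
    n = diff.size
    out: dict = {"flags": []}
    if np.all(diff == 0):
        out.update(t_stat=0.0, t_p=1.0, wilcoxon_p=1.0)
        out["flags"].append("all_differences_zero")
    elif _is_constant(diff):  # constant non-zero difference: s_d = 0
        out.update(
            t_stat=math.inf if diff[0] > 0 else -math.inf, t_p=0.0
        )
        res = stats.wilcoxon(diff, zero_method="wilcox", method="auto")
        out["wilcoxon_p"] = float(res.pvalue)
        out["flags"].append("constant_difference")
    else:
        res = stats.ttest_1samp(diff, 0.0)  # paired t = one-sample t on differences
        out.update(t_stat=float(res.statistic), t_p=float(res.pvalue))
        try:
            out["wilcoxon_p"] = float(
                stats.wilcoxon(diff, zero_method="wilcox", method="auto").pvalue
            )
        except ValueError:
            out["wilcoxon_p"] = float("nan")
            out["flags"].append("wilcoxon_undefined")
    # normality of the paired differences
    if _is_constant(diff):
        out["shapiro_p"] = float("nan")
        out["dagostino_p"] = float("nan")
        out["flags"].append("normality_tests_undefined")
    else:
        out["shapiro_p"] = float(stats.shapiro(diff).pvalue)
        if n >= 8:
            out["dagostino_p"] = float(stats.normaltest(diff).pvalue)
        else:
            out["dagostino_p"] = float("nan")
            out["flags"].append("dagostino_needs_n_ge_8")
    return out


def summarize(paired: PairedResults) -> pd.DataFrame:
    """Statistical comparison per (method, metric).

    Columns: d, paired t statistic and p-value, Wilcoxon signed-rank p,
    Shapiro–Wilk and D'Agostino p on the differences, mean-centred Levene p
    between arms, per-arm means and sample SDs, n_sims, flags.
    """
    rows = []
    for (method, metric), v in paired.arm_values.items():
        mccv_arm, cv_arm = v["mccv"], v["cv"]
        n = mccv_arm.size
        if n < 3:
            raise InvalidArgumentError(
                f"{method}/{metric}: need >= 3 paired simulations, got {n}"
            )
        diff = mccv_arm - cv_arm
        row = {
            "method": method,
            "metric": metric,
            "n_sims": n,
            "d": float(np.mean(diff)),
            "mccv_mean": float(np.mean(mccv_arm)),
            "cv_mean": float(np.mean(cv_arm)),
        }
        sds = sd_by_arm(mccv_arm, cv_arm)
        row["mccv_sd"], row["cv_sd"] = sds["mccv"], sds["cv"]
        tests = _paired_tests(diff)
        flags = tests.pop("flags")
        row.update(tests)
        if _is_constant(mccv_arm) and _is_constant(cv_arm):
            row["levene_p"] = float("nan")
            flags.append("levene_undefined_constant_arms")
        else:
            row["levene_p"] = float(
                stats.levene(mccv_arm, cv_arm, center="mean").pvalue
            )
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)
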