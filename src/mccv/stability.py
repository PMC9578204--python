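"""How many MCCV simulations are enough: the S-convergence study.

For each value of S on a grid, several replicate estimates of the mean
MCCV accuracy are computed (fresh data realization + S Monte Carlo splits
per replicate); the spread of the replicate estimates quantifies the
Monte Carlo instability at that S.  ``recommend_S`` encodes the practical
rule: S = 3000 when N < 300 and S = 2000 when N >= 300.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifiers, metrics
from .exceptions import DegenerateSplitError, InvalidArgumentError
from .resampling import mccv_splits
from .rng import PURPOSE_CLASSIFIER, PURPOSE_DATA, PURPOSE_MCCV, child_rng, child_seed
from .synthetic_data import GeneratorConfig, generate


@dataclass
class StabilityResult:
    """Replicate mean-accuracy estimates per S, plus their spread."""

    estimates: pd.DataFrame  # columns: s, replicate, mean_accuracy
    generator_config: GeneratorConfig
    method: str
    seed: int

    def spread(self) -> pd.DataFrame:
        """Sample SD of the replicate estimates at each S."""
        return (
            self.estimates.groupby("s")["mean_accuracy"]
            .std(ddof=1)
            .rename("sd")
            .reset_index()
        )


def run_stability(
    generator_config: GeneratorConfig,
    method: str,
    s_grid,
    n_replicates: int = 20,
    seed: int = 0,
    train_fraction: float = 0.8,
    metric: str = "accuracy",
) -> StabilityResult:
    """Estimate mean MCCV accuracy at each S with ``n_replicates`` replicates.

    Each (S, replicate) cell draws a fresh data realization and S Monte
    Carlo splits; degenerate splits are dropped from the mean.
    """
    s_grid = [int(s) for s in s_grid]
    if not s_grid:
        raise InvalidArgumentError("s_grid must be non-empty")
    if sorted(s_grid) != s_grid or len(set(s_grid)) != len(s_grid):
        raise InvalidArgumentError("s_grid must be strictly increasing")
    if min(s_grid) < 1:
        raise InvalidArgumentError("every S must be >= 1")
    if n_replicates < 2:
        raise InvalidArgumentError("n_replicates must be >= 2")
    spec = classifiers.get_method(method)
    specs = generator_config.resolved_specs()
    rows = []
    for rep in range(n_replicates):
        sim_cfg = GeneratorConfig(
            n_samples=generator_config.n_samples,
            n_features=generator_config.n_features,
            beta0=generator_config.beta0,
            beta1=generator_config.beta1,
            seed=child_seed(seed, PURPOSE_DATA, rep),
            feature_specs=specs,
        )
        table = generate(sim_cfg)
        # one long split stream per replicate; S-prefixes share splits so the
        # S-comparison isolates the number of simulations, not fresh noise
        plan = mccv_splits(
            table.n_samples,
            train_fraction,
            max(s_grid),
            seed=child_rng(seed, PURPOSE_MCCV, rep),
        )
        values = np.full(len(plan), np.nan)
        for si, (train, test) in enumerate(plan):
            try:
                result = classifiers.fit_predict(
                    spec, table, train, test,
                    seed=child_seed(seed, PURPOSE_CLASSIFIER, rep, si),
                )
            except DegenerateSplitError:
                continue
            values[si] = metrics.score(result.y_true, result.y_pred, metric)
        for s in s_grid:
            prefix = values[:s]
            prefix = prefix[~np.isnan(prefix)]
            rows.append(
                {"s": s, "replicate": rep,
                 "mean_accuracy": float(prefix.mean()) if prefix.size else np.nan}
            )
    estimates = pd.DataFrame(rows, columns=["s", "replicate", "mean_accuracy"])
    return StabilityResult(estimates, generator_config, spec.name, seed)


def recommend_S(n_samples: int) -> int:
    """Recommended number of MCCV simulations for a study of size N."""
    if n_samples < 1:
        raise InvalidArgumentError("n_samples must be >= 1")
    return 3000 if n_samples < 300 else 2000
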