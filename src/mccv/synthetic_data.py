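"""Synthetic feature tables with a binary outcome on a logistic link.

The generator emulates a small clinical-classification setting: one
signal-bearing continuous feature drives a binary outcome through a
logistic model, surrounded by nuisance features of mixed type (normals
with random spreads, bounded counts, binaries).  Defaults: 20 features,
intercept beta0 = -1.6 and slope beta1 = 0.1 on the first feature, which
is N(0, sd=2).

Composition with ``n_features`` columns: column 1 is always the signal
normal (sigma = 2); the remaining slots are filled in order by up to 11
nuisance normals with sigma ~ U(0.5, 20), then up to 4 bounded-count
features Binomial(m, p) with m ~ U{3..8} and p ~ U(0.1, 0.9), then up to
4 binary features Bernoulli(p) with p ~ U(0.1, 0.9).  Beyond 20 features
extra slots are further nuisance normals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import expit

from .exceptions import InvalidArgumentError
from .rng import PURPOSE_DATA, PURPOSE_FEATURE_SPECS, as_rng, child_rng

SIGNAL_SIGMA = 2.0
_N_NUISANCE_NORMAL = 11
_N_COUNT = 4
_N_BINARY = 4


@dataclass(frozen=True)
class FeatureSpec:
    """Distributional recipe for one feature column.

    kind:   "normal" (mean 0, sd ``sigma``), "count" (Binomial(``m``, ``p``),
            integer support 0..m) or "binary" (Bernoulli(``p``)).
    """

    kind: str
    sigma: float | None = None
    m: int | None = None
    p: float | None = None

    def __post_init__(self):
        if self.kind == "normal":
            if self.sigma is None or not np.isfinite(self.sigma) or self.sigma <= 0:
                raise InvalidArgumentError("normal feature requires sigma > 0")
        elif self.kind == "count":
            if self.m is None or self.m < 1:
                raise InvalidArgumentError("count feature requires m >= 1")
            if self.p is None or not 0 < self.p < 1:
                raise InvalidArgumentError("count feature requires p in (0, 1)")
        elif self.kind == "binary":
            if self.p is None or not 0 < self.p < 1:
                raise InvalidArgumentError("binary feature requires p in (0, 1)")
        else:
            raise InvalidArgumentError(f"unknown feature kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(**d)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one data-generating design.

    Identical config (including ``seed``) produces bit-identical tables.
    ``feature_specs`` may be supplied to pin the design; otherwise specs are
    drawn once, deterministically from ``seed``.
    """

    n_samples: int
    n_features: int = 20
    beta0: float = -1.6
    beta1: float = 0.1
    seed: int = 0
    feature_specs: tuple[FeatureSpec, ...] | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidArgumentError("n_samples must be >= 1")
        if self.n_features < 1:
            raise InvalidArgumentError("n_features must be >= 1")
        if self.feature_specs is not None:
            object.__setattr__(self, "feature_specs", tuple(self.feature_specs))
            if len(self.feature_specs) != self.n_features:
                raise InvalidArgumentError(
                    "feature_specs length must equal n_features"
                )

    def resolved_specs(self) -> tuple[FeatureSpec, ...]:
        """The feature specs in force: supplied ones, or drawn from the seed."""
        if self.feature_specs is not None:
            return self.feature_specs
        rng = child_rng(self.seed, PURPOSE_FEATURE_SPECS)
        return tuple(draw_feature_specs(self.n_features, rng))

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "seed": self.seed,
            "feature_specs": [s.to_dict() for s in self.resolved_specs()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        specs = d.pop("feature_specs", None)
        if specs is not None:
            specs = tuple(FeatureSpec.from_dict(s) for s in specs)
        return cls(feature_specs=specs, **d)


@dataclass
class FeatureTable:
    """An N x p feature matrix, binary outcome and per-column provenance."""

    X: np.ndarray
    y: np.ndarray
    feature_specs: tuple[FeatureSpec, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise InvalidArgumentError("X and y shapes are inconsistent")
        if not np.isin(self.y, (0, 1)).all():
            raise InvalidArgumentError("y must contain only 0/1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f"x{j + 1}" for j in range(self.n_features)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["y"] = self.y
        return df

    def subset(self, indices: np.ndarray) -> "FeatureTable":
        indices = np.asarray(indices)
        return FeatureTable(self.X[indices], self.y[indices], self.feature_specs)


def draw_feature_specs(n_features: int, rng) -> list[FeatureSpec]:
    """Draw the per-column distribution recipes for a design.

    Column 1 is the signal normal with sigma fixed at 2.  Remaining slots
    fill in order: nuisance normals (sigma ~ U(0.5, 20), up to 11), counts
    (m ~ U{3..8}, p ~ U(0.1, 0.9), up to 4), binaries (p ~ U(0.1, 0.9),
    up to 4), then further nuisance normals.
    """
    if n_features < 1:
        raise InvalidArgumentError("n_features must be >= 1")
    rng = as_rng(rng)
    specs = [FeatureSpec("normal", sigma=SIGNAL_SIGMA)]
    slots = n_features - 1
    n_norm = min(slots, _N_NUISANCE_NORMAL)
    n_count = min(max(slots - _N_NUISANCE_NORMAL, 0), _N_COUNT)
    n_bin = min(max(slots - _N_NUISANCE_NORMAL - _N_COUNT, 0), _N_BINARY)
    n_norm += max(slots - _N_NUISANCE_NORMAL - _N_COUNT - _N_BINARY, 0)
    for _ in range(n_norm):
        specs.append(FeatureSpec("normal", sigma=float(rng.uniform(0.5, 20.0))))
    for _ in range(n_count):
        specs.append(
            FeatureSpec(
                "count",
                m=int(rng.integers(3, 9)),
                p=float(rng.uniform(0.1, 0.9)),
            )
        )
    for _ in range(n_bin):
        specs.append(FeatureSpec("binary", p=float(rng.uniform(0.1, 0.9))))
    return specs


def _draw_column(spec: FeatureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "normal":
        return rng.normal(0.0, spec.sigma, size=n)
    if spec.kind == "count":
        return rng.binomial(spec.m, spec.p, size=n).astype(float)
    return rng.binomial(1, spec.p, size=n).astype(float)


def generate(config: GeneratorConfig) -> FeatureTable:
    """Generate a feature table under ``config``.

    The outcome is Bernoulli with success probability
    expit(beta0 + beta1 * x_1).  Pure function of the config: the same
    config (same seed) always returns the identical table.
    """
    specs = config.resolved_specs()
    rng = child_rng(config.seed, PURPOSE_DATA)
    X = np.column_stack(
        [_draw_column(spec, config.n_samples, rng) for spec in specs]
    )
    prob = expit(config.beta0 + config.beta1 * X[:, 0])
    y = rng.binomial(1, prob)
    return FeatureTable(X, y, specs)


def expected_prevalence(beta0: float, beta1: float, sigma: float) -> float:
    """Marginal P(Y=1) implied by the logistic generator.

    Computes E[expit(beta0 + beta1 * X)] for X ~ N(0, sigma) by adaptive
    Gauss-Kronrod quadrature (absolute tolerance below 1e-6).
    """
    for name, v in (("beta0", beta0), ("beta1", beta1), ("sigma", sigma)):
        if not np.isfinite(v):
            raise InvalidArgumentError(f"{name} must be finite")
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be > 0")
    value, _ = integrate.quad(
        lambda x: expit(beta0 + beta1 * x) * stats.norm.pdf(x, 0.0, sigma),
        -np.inf,
        np.inf,
        epsabs=1e-9,
    )
    return float(value)


def write_csv(table: FeatureTable, csv_path, config: GeneratorConfig | None = None) -> None:
    """Write a table as CSV (outcome column "y"); optional sidecar JSON of the config."""
    csv_path = Path(csv_path)
    table.to_dataframe().to_csv(csv_path, index=False)
    if config is not None:
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def read_csv(csv_path, outcome_column: str = "y") -> FeatureTable:
    """Read a feature table from CSV with a binary outcome column."""
    df = pd.read_csv(csv_path)
    if outcome_column not in df.columns:
        raise InvalidArgumentError(
            f"outcome column {outcome_column!r} not found in {csv_path}"
        )
    y = df[outcome_column].to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise InvalidArgumentError(f"outcome column {outcome_column!r} must be 0/1")
    X = df.drop(columns=[outcome_column]).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise InvalidArgumentError("feature table contains missing values")
    # provenance unknown for external tables: mark every column as numeric
    specs = tuple(FeatureSpec("normal", sigma=1.0) for _ in range(X.shape[1]))
    return FeatureTable(X, y.astype(int), specs)
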