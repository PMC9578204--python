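"""YAML experiment configuration, run manifests and result serialization.

A YAML config file drives each CLI command.  Recognized sections:

``generator:``   n_samples, n_features, beta0, beta1 (defaults 20, -1.6, 0.1)
``data_csv:``    path to a feature-table CSV (outcome column "y") used as a
                 subsampling pool instead of the generator
``experiment:``  n_outer_sims, k, t, s_mccv, subsample_size, metrics
``methods:``     list of registry names (unknown names fail fast)
``stability:``   s_grid, n_replicates, method, train_fraction
``seed:``        master seed (overridable on the command line)

Every command writes a ``manifest.json`` capturing the config snapshot,
seeds, package version, output inventory (with SHA-256 checksums) and any
warnings, so a run can be replayed bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import yaml

from . import classifiers
from .comparison import ExperimentConfig
from .exceptions import ConfigError
from .synthetic_data import GeneratorConfig, read_csv

logger = logging.getLogger("mccv")


def package_version() -> str:
    try:
        return version("mccv")
    except PackageNotFoundError:
        return "unknown"


def load_yaml(path) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed YAML in {path}{where}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def generator_from_config(cfg: dict, seed: int) -> GeneratorConfig:
    gen = dict(cfg.get("generator") or {})
    if "n_samples" not in gen:
        raise ConfigError("generator section requires n_samples")
    try:
        return GeneratorConfig(
            n_samples=int(gen["n_samples"]),
            n_features=int(gen.get("n_features", 20)),
            beta0=float(gen.get("beta0", -1.6)),
            beta1=float(gen.get("beta1", 0.1)),
            seed=seed,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid generator section: {exc}") from exc


def experiment_from_config(cfg: dict, seed: int) -> ExperimentConfig:
    exp = dict(cfg.get("experiment") or {})
    raw_methods = cfg.get("methods") or ["lda", "glm", "bayes", "knn"]
    known = {s.name for s in classifiers.list_methods()}
    if isinstance(raw_methods, dict):
        names, options = list(raw_methods), raw_methods
    else:
        names, options = list(raw_methods), {}
    unknown = [m for m in names if m not in known]
    if unknown:
        raise ConfigError(
            f"unknown methods {unknown}; valid names: {sorted(known)}"
        )
    methods = []
    for name in names:
        opts = options.get(name) or {}
        if not isinstance(opts, dict):
            raise ConfigError(f"method {name!r}: options must be a mapping")
        bad = set(opts) - {"grid", "inner_folds"}
        if bad:
            raise ConfigError(
                f"method {name!r}: unknown option keys {sorted(bad)} "
                "(valid: grid, inner_folds)"
            )
        spec = classifiers.get_method(name)
        if opts:
            spec = replace(
                spec,
                tuning_grid=tuple(opts.get("grid", spec.tuning_grid)),
                inner_folds=int(opts.get("inner_folds", spec.inner_folds)),
            )
        methods.append(spec if opts else name)
    if "data_csv" in cfg:
        data = read_csv(cfg["data_csv"], outcome_column=cfg.get("outcome_column", "y"))
    else:
        data = generator_from_config(cfg, seed)
    try:
        return ExperimentConfig(
            data=data,
            n_outer_sims=int(exp.get("n_outer_sims", 100)),
            k=int(exp.get("k", 10)),
            t=int(exp.get("t", 2)),
            s_mccv=exp.get("s_mccv"),
            subsample_size=exp.get("subsample_size"),
            methods=tuple(methods),
            metric_names=tuple(exp.get("metrics", ("accuracy", "f1"))),
            seed=seed,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid experiment section: {exc}") from exc


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config_snapshot: dict
    seed: int
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    warnings: list = field(default_factory=list)
    version: str = field(default_factory=package_version)

    def record_output(self, path) -> None:
        path = Path(path)
        self.outputs[path.name] = sha256_of(path)

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / "manifest.json"
        payload = {
            "command": self.command,
            "package_version": self.version,
            "seed": self.seed,
            "config": self.config_snapshot,
            "outputs": self.outputs,
            "warnings": self.warnings,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def setup_logging(out_dir) -> Path:
    """Log to console and to <out_dir>/run.log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    root = logging.getLogger("mccv")
    root.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(log_path, mode="w")
    fh.setFormatter(fmt)
    root.addHandler(fh)
    return log_path
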