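"""Fold partitions, exhaustive leave-t-out round enumeration, and MCCV splits.

Two resampling engines share one ``SplitPlan`` contract:

* exhaustive leave-t-out CV: a balanced k-fold partition, with one round
  per unordered choice of t test folds — C(k, t) rounds in total
  (k=10, t=2 gives the canonical 45 rounds);
* Monte Carlo CV (MCCV): S independent train/test splits, each drawn
  uniformly without replacement at a fixed training fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .exceptions import InvalidArgumentError
from .rng import as_rng


@dataclass(frozen=True)
class FoldPartition:
    """Assignment of N samples to k disjoint folds with sizes differing by <= 1."""

    n_samples: int
    k: int
    assignment: np.ndarray  # length-N vector of fold labels in 0..k-1

    def __post_init__(self):
        object.__setattr__(
            self, "assignment", np.asarray(self.assignment, dtype=int)
        )
        if self.assignment.shape != (self.n_samples,):
            raise InvalidArgumentError("assignment length must equal n_samples")
        sizes = np.bincount(self.assignment, minlength=self.k)
        if len(sizes) != self.k or sizes.min() < 1:
            raise InvalidArgumentError("every fold must be non-empty")
        if sizes.max() - sizes.min() > 1:
            raise InvalidArgumentError("fold sizes must differ by at most 1")

    def fold_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == label)

    @property
    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)


@dataclass(frozen=True)
class SplitPlan:
    """Ordered train/test index pairs from either CV enumeration or MCCV draws."""

    splits: tuple[tuple[np.ndarray, np.ndarray], ...]
    provenance: str  # "cv_rounds" | "mccv"
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "seed": self.seed,
            "index_base": 0,
            "splits": [
                {"train": train.tolist(), "test": test.tolist()}
                for train, test in self.splits
            ],
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        if payload.get("index_base", 0) != 0:
            raise InvalidArgumentError("only index_base 0 is supported")
        splits = tuple(
            (np.asarray(s["train"], dtype=int), np.asarray(s["test"], dtype=int))
            for s in payload["splits"]
        )
        return cls(splits, payload["provenance"], payload.get("seed"))


def make_folds(n_samples: int, k: int, seed=None, stratify_by=None) -> FoldPartition:
    """Randomly partition ``n_samples`` indices into ``k`` balanced folds.

    Fold sizes differ by at most one; when ``n_samples`` is not divisible by
    ``k`` the larger folds take the lowest labels.  With ``stratify_by`` (a
    length-N label vector) the partition balances each class across folds.
    """
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    if k > n_samples:
        raise InvalidArgumentError("k must not exceed n_samples")
    rng = as_rng(seed)
    assignment = np.empty(n_samples, dtype=int)
    if stratify_by is None:
        order = rng.permutation(n_samples)
        # labels 0..k-1 repeated cyclically: fold sizes differ by <= 1 and
        # the remainder goes to the lowest labels
        assignment[order] = np.arange(n_samples) % k
    else:
        stratify_by = np.asarray(stratify_by)
        if stratify_by.shape != (n_samples,):
            raise InvalidArgumentError("stratify_by length must equal n_samples")
        next_label = 0
        for cls in np.unique(stratify_by):
            members = np.flatnonzero(stratify_by == cls)
            members = rng.permutation(members)
            labels = (next_label + np.arange(len(members))) % k
            assignment[members] = labels
            next_label = int((next_label + len(members)) % k)
    return FoldPartition(n_samples, k, assignment)


def enumerate_cv_rounds(partition: FoldPartition, t: int) -> SplitPlan:
    """All leave-t-out CV rounds for a fold partition.

    One split per unordered choice of t test folds (train = remaining
    k - t folds), ordered lexicographically by test-fold labels, so the
    plan is canonical given the partition.
    """
    if not 1 <= t <= partition.k - 1:
        raise InvalidArgumentError("t must satisfy 1 <= t <= k-1")
    per_fold = [partition.fold_indices(label) for label in range(partition.k)]
    splits = []
    for test_folds in combinations(range(partition.k), t):
        test = np.sort(np.concatenate([per_fold[f] for f in test_folds]))
        mask = np.ones(partition.n_samples, dtype=bool)
        mask[test] = False
        splits.append((np.flatnonzero(mask), test))
    return SplitPlan(tuple(splits), provenance="cv_rounds")


def mccv_splits(
    n_samples: int,
    train_fraction: float,
    n_splits: int,
    seed=None,
    stratify_by=None,
) -> SplitPlan:
    """S independent Monte Carlo train/test splits, sampled without replacement.

    Train size is floor(train_fraction * n_samples); each split is drawn
    uniformly and independently of the others (duplicate splits across the
    S draws are possible by design).
    """
    if not 0 < train_fraction < 1:
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    if n_splits < 1:
        raise InvalidArgumentError("n_splits must be >= 1")
    # tiny epsilon guards floor() against float error in fractions like 0.7 * 10
    n_train = int(np.floor(train_fraction * n_samples + 1e-9))
    if n_train == 0 or n_train == n_samples:
        raise InvalidArgumentError(
            f"train_fraction {train_fraction} gives a degenerate split at N={n_samples}"
        )
    rng = as_rng(seed)
    splits = []
    for _ in range(n_splits):
        if stratify_by is None:
            perm = rng.permutation(n_samples)
            train = np.sort(perm[:n_train])
            test = np.sort(perm[n_train:])
        else:
            train_parts = []
            labels = np.asarray(stratify_by)
            # proportional allocation per class; remainder assigned at random
            counts = {c: int(np.floor(train_fraction * (labels == c).sum()))
                      for c in np.unique(labels)}
            short = n_train - sum(counts.values())
            classes = rng.permutation(np.unique(labels))
            for c in classes[:short]:
                counts[c] += 1
            for c, m in counts.items():
                members = rng.permutation(np.flatnonzero(labels == c))
                train_parts.append(members[:m])
            train = np.sort(np.concatenate(train_parts))
            mask = np.ones(n_samples, dtype=bool)
            mask[train] = False
            test = np.flatnonzero(mask)
        splits.append((train, test))
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return SplitPlan(tuple(splits), provenance="mccv", seed=seed_int)
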