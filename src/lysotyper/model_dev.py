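"""Model-development protocol: split, grid evaluation, selection, refit.

The labeled dataset is split 60:40 into training and testing sets; the
test partition is set aside entirely (operations here require the 'train'
partition tag and raise on anything else).  Every hyperparameter
combination in the grid is evaluated on 20 random training/validation
resplits of the training set (the same 20 resplits for every
combination), and the combination with the highest *minimum* validation
accuracy wins — a conservative rule preferring settings that never do
badly over settings that are merely good on average.  Per-resplit F1 is
recorded alongside for inspection.  The winner is then refit on the full
training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score

from . import classifier
from .classifier import Hyperparameters, LifestyleModel
from .feature_table import LabeledDataset, TEMPERATE

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split and resplit settings.

    ``resplit_train_fraction`` is the train share inside each of the
    ``n_resplits`` sub-splits of the training set (75:25 by default).
    Splits are uniform random, non-stratified by default.
    """

    train_fraction: float = 0.6
    n_resplits: int = 20
    seed: int = 0
    resplit_train_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.resplit_train_fraction < 1:
            raise ValueError("resplit_train_fraction must be in (0, 1)")
        if self.n_resplits < 1:
            raise ValueError("n_resplits must be >= 1")


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid; defaults span the published search space
    (2 x 2 x 2 x 19 x 16 = 2432 combinations)."""

    bootstrap_options: tuple[bool, ...] = (True, False)
    class_weight_options: tuple[str, ...] = ("balanced", "balanced_subsample")
    min_samples_leaf_options: tuple[int, ...] = (1, 2)
    n_estimators_values: tuple[int, ...] = tuple(range(10, 105, 5))
    max_depth_values: tuple[int, ...] = tuple(range(10, 42, 2))

    def __post_init__(self) -> None:
        for name in (
            "bootstrap_options",
            "class_weight_options",
            "min_samples_leaf_options",
            "n_estimators_values",
            "max_depth_values",
        ):
            vals = tuple(getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, vals)

    @property
    def size(self) -> int:
        return (
            len(self.bootstrap_options)
            * len(self.class_weight_options)
            * len(self.min_samples_leaf_options)
            * len(self.n_estimators_values)
            * len(self.max_depth_values)
        )

    def combinations(self, random_seed: int = 0) -> Iterator[Hyperparameters]:
        """Enumerate combinations in the documented fixed order:
        bootstrap, class_weight, min_samples_leaf, n_estimators, max_depth
        (rightmost varying fastest)."""
        for bs, cw, msl, ne, md in itertools.product(
            self.bootstrap_options,
            self.class_weight_options,
            self.min_samples_leaf_options,
            self.n_estimators_values,
            self.max_depth_values,
        ):
            yield Hyperparameters(
                bootstrap=bs,
                class_weight=cw,
                min_samples_leaf=msl,
                n_estimators=ne,
                max_depth=md,
                random_seed=random_seed,
            )


@dataclass(frozen=True)
class GridEntry:
    hyperparameters: Hyperparameters
    accuracies: tuple[float, ...]
    f1_scores: tuple[float, ...]

    @property
    def min_accuracy(self) -> float:
        return min(self.accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


@dataclass(frozen=True)
class GridResult:
    entries: tuple[GridEntry, ...]
    n_resplits: int

    def __post_init__(self) -> None:
        for e in self.entries:
            if len(e.accuracies) != self.n_resplits:
                raise ValueError("each entry needs one accuracy per resplit")
            if not all(0.0 <= a <= 1.0 for a in e.accuracies):
                raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            hp = e.hyperparameters
            row = {
                "bootstrap": hp.bootstrap,
                "class_weight": hp.class_weight,
                "min_samples_leaf": hp.min_samples_leaf,
                "n_estimators": hp.n_estimators,
                "max_depth": hp.max_depth,
                "min_accuracy": e.min_accuracy,
                "mean_accuracy": e.mean_accuracy,
            }
            for i, (a, f) in enumerate(zip(e.accuracies, e.f1_scores)):
                row[f"acc_{i}"] = a
                row[f"f1_{i}"] = f
            rows.append(row)
        return pd.DataFrame(rows)


def _require_train(dataset: LabeledDataset, op: str) -> None:
    if dataset.partition != "train":
        raise ValueError(
            f"{op} accepts only the training partition "
            f"(got partition={dataset.partition!r}); the test set is set aside"
        )


def _random_partition(n: int, n_first: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return perm[:n_first], perm[n_first:]


def train_test_split(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive 60:40 (by default) partition; deterministic
    given the seed.  Sizes are round(train_fraction * n) and remainder."""
    n = dataset.n
    n_train = round(spec.train_fraction * n)
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = _random_partition(n, n_train, rng)
    train = dataset.subset_rows(train_idx, partition="train")
    test = dataset.subset_rows(test_idx, partition="test")
    for part, name in ((train, "train"), (test, "test")):
        counts = pd.Series(part.labels).value_counts()
        if len(counts) < 2 or counts.min() < 1:
            raise ValueError(
                f"dataset too small: {name} side lacks a class after splitting"
            )
    return train, test


def _resplit_indices(
    train: LabeledDataset, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The shared resplit index pairs, derived deterministically from
    spec.seed (one child seed per resplit)."""
    n_sub = round(spec.resplit_train_fraction * train.n)
    pairs = []
    for r in range(spec.n_resplits):
        sub_seed = (spec.seed * 100_003 + 7 * r + 1) % _SEED_MOD
        rng = np.random.default_rng(sub_seed)
        pairs.append(_random_partition(train.n, n_sub, rng))
    return pairs


def evaluate_grid(
    train: LabeledDataset, grid: GridSpec, spec: SplitSpec
) -> GridResult:
    """Validation accuracy (and F1) of every grid combination on each of
    the shared resplits of the training set."""
    _require_train(train, "evaluate_grid")
    resplits = _resplit_indices(train, spec)
    entries = []
    for hp in grid.combinations(random_seed=spec.seed % _SEED_MOD):
        accs, f1s = [], []
        for sub_idx, val_idx in resplits:
            sub = train.subset_rows(sub_idx, partition="train")
            val = train.subset_rows(val_idx, partition="train")
            model = classifier.fit(sub, hp)
            pred = model.forest.predict(val.matrix)
            truth = val.label_array()
            accs.append(float(accuracy_score(truth, pred)))
            f1s.append(float(f1_score(truth, pred, pos_label=TEMPERATE)))
        entries.append(GridEntry(hp, tuple(accs), tuple(f1s)))
    return GridResult(tuple(entries), spec.n_resplits)


def select_best(result: GridResult) -> Hyperparameters:
    """Argmax of minimum validation accuracy; ties broken by higher mean
    accuracy, then by grid enumeration order (first wins)."""
    if not result.entries:
        raise ValueError("empty grid result")
    best = result.entries[0]
    for entry in result.entries[1:]:
        if entry.min_accuracy > best.min_accuracy or (
            entry.min_accuracy == best.min_accuracy
            and entry.mean_accuracy > best.mean_accuracy
        ):
            best = entry
    return best.hyperparameters


def finalize(train: LabeledDataset, hp: Hyperparameters) -> LifestyleModel:
    """Refit the selected hyperparameters on the entire training set."""
    _require_train(train, "finalize")
    return classifier.fit(train, hp)
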