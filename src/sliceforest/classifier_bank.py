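"""One random forest per (direction, position), and slice-level prediction.

Training builds, for every position of every direction, a design matrix of
flattened slices over the training cohort and fits an independent random
forest on it.  Prediction runs each test slice through its own forest and
takes a *hard* majority vote over the trees' class decisions: the slice is
called positive iff strictly more than half of the trees vote class 1, so a
tie (possible with an even tree count) resolves to class 0, conservatively
toward non-diagnosis.

The bank never needs all design matrices in memory at once: matrices are
built, fitted and discarded one position at a time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .slicing import DIRECTIONS, _slice_data, build_design_matrix, n_positions
from .volume_io import Cohort, Volume

__all__ = [
    "BankConfig",
    "TrainedBank",
    "DecisionVectors",
    "train_bank",
    "predict_decision_vectors",
    "predict_slice",
    "save_bank",
    "load_bank",
]


@dataclass(frozen=True)
class BankConfig:
    """Random-forest settings shared by every model in the bank.

    The defaults are the published operating point: 700 trees, maximum depth
    100, minimum samples to split 2, with the square-root feature-subsampling
    rule at each split.
    """

    n_trees: int = 700
    max_depth: int = 100
    min_samples_split: int = 2
    seed: int = 0
    features_per_split: str = "sqrt"
    class_weight: str | None = None  # e.g. "balanced"; off by default

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1 or self.min_samples_split < 2:
            raise ValueError("invalid forest hyperparameters")


@dataclass
class DecisionVectors:
    """Per-direction binary slice predictions for one test subject (Y_i)."""

    y1: np.ndarray
    y2: np.ndarray
    y3: np.ndarray

    def get(self, direction: int) -> np.ndarray:
        return (self.y1, self.y2, self.y3)[direction - 1]

    def as_tuple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.y1, self.y2, self.y3)


@dataclass
class TrainedBank:
    models: dict[tuple[int, int], RandomForestClassifier]
    shape: tuple[int, int, int]
    config: BankConfig = field(default_factory=BankConfig)

    def __len__(self) -> int:
        return len(self.models)


def model_seed(seed: int, direction: int, position: int) -> int:
    """Deterministic per-model seed, independent of training order."""
    ss = np.random.SeedSequence(entropy=(seed & 0x7FFFFFFF, direction, position))
    return int(ss.generate_state(1)[0] % (2**31))


def _make_forest(config: BankConfig, direction: int, position: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        max_features=config.features_per_split,
        class_weight=config.class_weight,
        random_state=model_seed(config.seed, direction, position),
        n_jobs=1,
    )


def train_bank(train: Cohort, config: BankConfig = BankConfig()) -> TrainedBank:
    """Fit one forest per (direction, position) over the training cohort."""
    train.validate_for_training()
    models: dict[tuple[int, int], RandomForestClassifier] = {}
    for direction in DIRECTIONS:
        for position in range(n_positions(train.shape, direction)):
            dm = build_design_matrix(train, direction, position)
            forest = _make_forest(config, direction, position)
            forest.fit(dm.rows, dm.labels)
            models[(direction, position)] = forest
    return TrainedBank(models=models, shape=train.shape, config=config)


def _hard_vote(votes_for_one: int, n_trees: int) -> int:
    """Strict majority of tree votes; ties resolve to class 0."""
    return int(votes_for_one * 2 > n_trees)


def _majority_predict(forest: RandomForestClassifier, rows: np.ndarray) -> np.ndarray:
    """Hard majority vote of the forest's trees on each row."""
    # Trees predict in their own class coding; map back to the {0,1} labels.
    votes = np.zeros(rows.shape[0], dtype=int)
    for tree in forest.estimators_:
        votes += (forest.classes_[tree.predict(rows).astype(int)] == 1).astype(int)
    n = len(forest.estimators_)
    return np.fromiter((_hard_vote(v, n) for v in votes), dtype=int, count=len(votes))


def predict_slice(bank: TrainedBank, volume: Volume, direction: int, position: int) -> int:
    """Binary prediction of the single model (direction, position)."""
    row = _slice_data(volume.data, direction, position)[None, :]
    return int(_majority_predict(bank.models[(direction, position)], row)[0])


def predict_decision_vectors(bank: TrainedBank, volume: Volume) -> DecisionVectors:
    """Per-direction slice predictions for one test volume."""
    if volume.shape != bank.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match bank shape {bank.shape}"
        )
    vectors = []
    for direction in DIRECTIONS:
        n = n_positions(bank.shape, direction)
        y = np.zeros(n, dtype=int)
        for position in range(n):
            row = _slice_data(volume.data, direction, position)[None, :]
            y[position] = _majority_predict(bank.models[(direction, position)], row)[0]
        vectors.append(y)
    return DecisionVectors(*vectors)


def save_bank(bank: TrainedBank, directory: str | Path) -> None:
    """Persist a bank as one joblib file per model plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (direction, position), model in bank.models.items():
        joblib.dump(model, directory / f"model_d{direction}_p{position:04d}.joblib")
    manifest = {"shape": list(bank.shape), "config": asdict(bank.config)}
    (directory / "bank.json").write_text(json.dumps(manifest, indent=2))


def load_bank(directory: str | Path) -> TrainedBank:
    directory = Path(directory)
    manifest = json.loads((directory / "bank.json").read_text())
    shape = tuple(manifest["shape"])
    config = BankConfig(**manifest["config"])
    models = {}
    for direction in DIRECTIONS:
        for position in range(n_positions(shape, direction)):
            path = directory / f"model_d{direction}_p{position:04d}.joblib"
            if not path.exists():
                raise FileNotFoundError(f"bank is missing {path.name}")
            models[(direction, position)] = joblib.load(path)
    return TrainedBank(models=models, shape=shape, config=config)
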