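"""Extreme learning machine (ELM) classification with repeated
random-subsampling cross-validation.

The ELM is a single-hidden-layer network whose input weights and biases are
random and untrained; only the output weights are learned, as the
minimum-norm least-squares solution beta = pinv(H) T, where H is the hidden
layer output matrix of logistic nodes.  Diagnostic accuracy is estimated by
repeatedly splitting the sample pool into equal train/test halves
(16/16 by default, 1000 splits) and averaging sensitivity and specificity
over splits.  The positive class is "precancerous" (CIN1-3 pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PRECANCER_CLASSES

#: column order of the one-hot targets: [normal, precancerous]
NEGATIVE, POSITIVE = 0, 1

DEFAULT_L = 20
DEFAULT_L_GRID = (5, 10, 15, 20, 30, 40, 50)


class UndefinedMetricError(ValueError):
    """Sensitivity/specificity undefined because a class is absent."""


def binarize_label(label: str) -> int:
    return POSITIVE if label in PRECANCER_CLASSES else NEGATIVE


@dataclass
class TrainingSet:
    """Feature matrix with one-hot targets (m = 2: normal, precancerous)."""

    X: np.ndarray  # (N, n)
    T: np.ndarray  # (N, m) one-hot
    labels: list[str] = field(default_factory=list)

    @classmethod
    def from_labels(cls, X: np.ndarray, y: np.ndarray) -> "TrainingSet":
        y = np.asarray(y, dtype=int)
        T = np.zeros((len(y), 2))
        T[np.arange(len(y)), y] = 1.0
        return cls(np.asarray(X, dtype=float), T)


@dataclass
class ELMModel:
    A: np.ndarray  # (L, n) random input weights
    b: np.ndarray  # (L,) biases
    beta: np.ndarray  # (L, m) trained output weights

    @property
    def L(self) -> int:
        return len(self.b)


def _hidden(X: np.ndarray, A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Logistic hidden-node outputs g(a, b, x) = 1 / (1 + exp(-(a.x + b)))."""
    z = np.clip(X @ A.T + b, -500, 500)
    return 1.0 / (1.0 + np.exp(-z))


def elm_train(train: TrainingSet, L: int, rng: np.random.Generator) -> ELMModel:
    """Random hidden layer (uniform weights on [-1, 1]) + pseudoinverse.

    beta = pinv(H) T is the minimum-norm least-squares solution of
    H beta = T; training is a single linear solve, no iteration.
    """
    X = np.asarray(train.X, dtype=float)
    if L < 1 or len(X) < 1:
        raise ValueError("need L >= 1 hidden nodes and at least one sample")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    n = X.shape[1]
    A = rng.uniform(-1.0, 1.0, size=(L, n))
    b = rng.uniform(-1.0, 1.0, size=L)
    H = _hidden(X, A, b)
    beta = np.linalg.pinv(H) @ train.T
    return ELMModel(A=A, b=b, beta=beta)


def elm_output(model: ELMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.A.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.A.shape[1]}"
        )
    return _hidden(X, model.A, model.b) @ model.beta


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Class index per sample: argmax output, ties broken toward positive."""
    out = elm_output(model, X)
    return np.where(out[:, POSITIVE] >= out[:, NEGATIVE], POSITIVE, NEGATIVE)


def confusion_metrics(
    predicted: np.ndarray, truth: np.ndarray, positive: int = POSITIVE
) -> tuple[float, float]:
    """(sensitivity %, specificity %) with positive = precancerous."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    pos = truth == positive
    if not pos.any() or pos.all():
        raise UndefinedMetricError("both classes must be present in truth")
    tp = np.sum((predicted == positive) & pos)
    tn = np.sum((predicted != positive) & ~pos)
    sensitivity = 100.0 * tp / pos.sum()
    specificity = 100.0 * tn / (~pos).sum()
    return float(sensitivity), float(specificity)


@dataclass
class CVReport:
    sensitivity: np.ndarray  # per split, %
    specificity: np.ndarray  # per split, %
    n_splits: int
    L: int
    seed: int | None = None

    @property
    def mean_sensitivity(self) -> float:
        return float(self.sensitivity.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.specificity.mean())

    @property
    def balanced_mean(self) -> float:
        return 0.5 * (self.mean_sensitivity + self.mean_specificity)

    def to_dict(self) -> dict:
        return {
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "balanced_mean": self.balanced_mean,
            "n_splits": self.n_splits,
            "L": self.L,
            "seed": self.seed,
            "per_split_sensitivity": self.sensitivity.tolist(),
            "per_split_specificity": self.specificity.tolist(),
        }


def draw_split_schedule(
    y: np.ndarray,
    n_splits: int,
    train_size: int,
    rng: np.random.Generator,
    max_attempts_factor: int = 1000,
) -> list[np.ndarray]:
    """Unstratified random half-splits; degenerate splits are redrawn.

    A split is degenerate when its test half lacks one of the two classes;
    it is redrawn (not skipped) so exactly ``n_splits`` valid splits result.
    The schedule depends only on (labels, n_splits, train_size, rng), so the
    same seed yields identical splits for every feature set -- comparisons
    across feature models then isolate the features themselves.
    """
    y = np.asarray(y)
    n = len(y)
    if n < train_size + 2:
        raise ValueError("pool too small for the requested train size")
    schedule = []
    attempts = 0
    while len(schedule) < n_splits:
        attempts += 1
        if attempts > max_attempts_factor * n_splits:
            raise ValueError("cannot draw valid splits (a class is too rare)")
        perm = rng.permutation(n)
        test = perm[train_size:]
        if len(np.unique(y[test])) < 2:
            continue
        schedule.append(perm)
    return schedule


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    L: int = DEFAULT_L,
    n_splits: int = 1000,
    train_size: int = 16,
    seed: int | np.random.SeedSequence = 0,
    standardize: bool = True,
    schedule: list[np.ndarray] | None = None,
) -> CVReport:
    """Repeated random-subsampling CV of the ELM on a labelled pool.

    Features are z-scored with training-half statistics of each split.
    Deterministic in (X, y, L, n_splits, train_size, seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    split_ss, weight_ss = ss.spawn(2)
    if schedule is None:
        schedule = draw_split_schedule(
            y, n_splits, train_size, np.random.default_rng(split_ss)
        )
    weight_rng = np.random.default_rng(weight_ss)
    sens = np.empty(len(schedule))
    spec = np.empty(len(schedule))
    for i, perm in enumerate(schedule):
        tr, te = perm[:train_size], perm[train_size:]
        Xtr, Xte = X[tr], X[te]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        model = elm_train(TrainingSet.from_labels(Xtr, y[tr]), L, weight_rng)
        pred = elm_predict(model, Xte)
        sens[i], spec[i] = confusion_metrics(pred, y[te])
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return CVReport(sens, spec, len(schedule), L, seed_val)


def tune_hidden_nodes(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[int, ...] = DEFAULT_L_GRID,
    **cv_kwargs,
) -> tuple[int, CVReport, dict[int, CVReport]]:
    """Pick the hidden-node count maximizing mean CV balanced accuracy.

    Mirrors the usual ELM practice of adjusting L for maximum discrimination
    accuracy; the whole grid of reports is returned for transparency.
    Ties go to the smaller network.
    """
    reports = {L: cross_validate(X, y, L=L, **cv_kwargs) for L in grid}
    best_L = max(sorted(reports), key=lambda L: reports[L].balanced_mean)
    return best_L, reports[best_L], reports
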