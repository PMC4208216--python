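"""Ensemble of binary kernel SVMs (E-SVM) for informative-frame classification.

Capsule video content is too heterogeneous for one classifier, so K members
are trained by K-fold splitting — member k trains on all folds but fold k and
tunes its hyperparameters on the held-out fold — and their calibrated
probabilities are combined by a product, sum (mean) or median rule.  The
median rule is the default aggregator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LabeledDataset",
    "TrainedEnsemble",
    "kfold_split",
    "train_ensemble",
    "aggregate",
    "classify",
    "classify_batch",
    "save_ensemble",
    "load_ensemble",
]

MODEL_FORMAT_VERSION = 1

_C_GRID = (0.1, 1.0, 10.0, 100.0)
_GAMMA_GRID = ("scale", 0.01, 0.1, 1.0)


@dataclass
class LabeledDataset:
    """Feature vectors with binary labels (1 = informative, 0 = non-informative)."""

    features: np.ndarray
    labels: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels length mismatch")
        if self.ids is None:
            self.ids = np.arange(self.features.shape[0])


@dataclass
class TrainedEnsemble:
    """K fitted members plus the aggregation rule and training provenance."""

    members: list
    kernel: str
    agg_rule: str
    kfold_seed: int
    member_hyperparams: list = field(default_factory=list)
    n_features: int = 0

    def member_probabilities(self, X: np.ndarray) -> np.ndarray:
        """Probability of the informative class from every member, shape (K, n)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError("feature dimension mismatch")
        probs = []
        for m in self.members:
            classes = list(m.named_steps["svc"].classes_)
            probs.append(m.predict_proba(X)[:, classes.index(1)])
        return np.stack(probs)


def kfold_split(n: int, K: int, seed: int) -> list[np.ndarray]:
    """Partition indices 0..n-1 into K disjoint shuffled folds of near-equal size."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < K:
        raise ValueError("n must be >= K")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, K)]


def _stratified_folds(labels: np.ndarray, K: int, seed: int) -> list[np.ndarray]:
    """Class-stratified folds so every training split sees both classes."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(K)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, chunk in enumerate(np.array_split(idx, K)):
            folds[j].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _param_grid(kernel: str):
    if kernel == "linear":
        return [{"C": c} for c in _C_GRID]
    if kernel in ("rbf", "sigmoid"):
        return [{"C": c, "gamma": g} for c in _C_GRID for g in _GAMMA_GRID]
    raise ValueError(f"unknown kernel: {kernel!r}")


class _PlattSVC(ClassifierMixin, BaseEstimator):
    """Margin SVM with a monotone sigmoid (Platt) calibration fitted on its
    own training split, so member scores live on a common [0, 1] scale."""

    def __init__(self, kernel: str = "rbf", C: float = 1.0, gamma="scale") -> None:
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.svc = SVC(kernel=kernel, C=C, gamma=gamma)
        self.calibrator = LogisticRegression()

    def fit(self, X, y):
        self.svc.fit(X, y)
        margins = self.svc.decision_function(X).reshape(-1, 1)
        self.calibrator.fit(margins, y)
        self.fitted_ = True
        return self

    @property
    def classes_(self):
        return self.svc.classes_

    def predict(self, X):
        return self.svc.predict(X)

    def predict_proba(self, X):
        margins = self.svc.decision_function(np.asarray(X)).reshape(-1, 1)
        return self.calibrator.predict_proba(margins)


def _make_member(kernel: str, params: dict) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", _PlattSVC(kernel=kernel, **params)),
        ]
    )


def train_ensemble(
    data: LabeledDataset,
    K: int = 5,
    kernel: str = "rbf",
    agg_rule: str = "median",
    seed: int = 0,
) -> TrainedEnsemble:
    """Train K SVM members via stratified K-fold splitting.

    Member k trains on every fold except fold k; a small logarithmic grid over
    C (and kernel width for rbf/sigmoid) is scored by accuracy on the held-out
    fold k.  Features are standardized by training-split statistics and member
    probabilities are Platt-calibrated on the training split.  Deterministic
    for a fixed seed.
    """
    X, y = data.features, data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    if agg_rule not in ("product", "sum", "median"):
        raise ValueError(f"unknown aggregation rule: {agg_rule!r}")
    folds = _stratified_folds(y, K, seed)

    members, hyperparams = [], []
    for k, fold in enumerate(folds):
        train_idx = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != k]))
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[fold], y[fold]
        best, best_acc = None, -1.0
        for params in _param_grid(kernel):
            model = _make_member(kernel, params)
            model.fit(Xtr, ytr)
            acc = float(np.mean(model.predict(Xval) == yval)) if len(yval) else 0.0
            if acc > best_acc:
                best, best_acc = (model, params), acc
        members.append(best[0])
        hyperparams.append({**best[1], "val_accuracy": best_acc})

    return TrainedEnsemble(
        members=members,
        kernel=kernel,
        agg_rule=agg_rule,
        kfold_seed=seed,
        member_hyperparams=hyperparams,
        n_features=X.shape[1],
    )


def aggregate(member_scores, rule: str = "median") -> float:
    """Combine member probabilities into one probability in [0, 1].

    sum: arithmetic mean; product: geometric combination renormalized against
    the complementary class, p = prod(p_k) / (prod(p_k) + prod(1 - p_k));
    median: middle order statistic (mean of the two middles for even K).
    """
    s = np.asarray(list(member_scores), dtype=float)
    if s.size < 1:
        raise ValueError("no scores")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("score outside [0, 1]")
    if rule == "sum":
        return float(s.mean())
    if rule == "median":
        return float(np.median(s))
    if rule == "product":
        p = np.prod(s)
        q = np.prod(1.0 - s)
        if p + q == 0.0:  # unanimous contradiction (some 0 and some 1)
            return 0.5
        return float(p / (p + q))
    raise ValueError(f"unknown aggregation rule: {rule!r}")


def classify(ens: TrainedEnsemble, features) -> tuple[int, float]:
    """Label one feature vector: 1 (informative) iff the aggregated probability >= 0.5.

    The tie at exactly 0.5 counts as informative — recall of diagnostically
    useful frames is favoured.
    """
    from .multifractal import MultifractalFeature

    if isinstance(features, MultifractalFeature):
        features = features.e_alpha
    x = np.asarray(features, dtype=float).reshape(1, -1)
    if not ens.members:
        raise ValueError("untrained ensemble")
    prob = aggregate(ens.member_probabilities(x)[:, 0], ens.agg_rule)
    return (1 if prob >= 0.5 else 0), prob


def classify_batch(ens: TrainedEnsemble, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`classify` over rows of ``X``."""
    if not ens.members:
        raise ValueError("untrained ensemble")
    member_probs = ens.member_probabilities(np.asarray(X, dtype=float))
    probs = np.array([aggregate(member_probs[:, i], ens.agg_rule) for i in range(member_probs.shape[1])])
    return (probs >= 0.5).astype(int), probs


def save_ensemble(ens: TrainedEnsemble, path) -> None:
    """Serialize with a versioned header recording kernel, K, seed and hyperparameters."""
    import joblib

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "kernel": ens.kernel,
        "agg_rule": ens.agg_rule,
        "K": len(ens.members),
        "kfold_seed": ens.kfold_seed,
        "member_hyperparams": ens.member_hyperparams,
        "n_features": ens.n_features,
        "members": ens.members,
    }
    joblib.dump(payload, path)


def load_ensemble(path) -> TrainedEnsemble:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return TrainedEnsemble(
        members=payload["members"],
        kernel=payload["kernel"],
        agg_rule=payload["agg_rule"],
        kfold_seed=payload["kfold_seed"],
        member_hyperparams=payload["member_hyperparams"],
        n_features=payload["n_features"],
    )
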