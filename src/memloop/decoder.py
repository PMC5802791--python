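"""Per-subject recall classifier: training, scoring, significance, attribution.

The classifier is L2-penalized logistic regression under the LIBLINEAR
convention (objective ``0.5 ||W||^2 + C * sum_i c_i * logloss_i``) with the
penalty constant fixed at C = 2.4e-4 and per-class weights inversely
proportional to class frequency (``n / (2 * n_k)``); the intercept is
unpenalized. Performance is quantified by ROC AUC (chance 0.50) and assessed
against a label-permutation null. Feature attributions use the forward-model
(activation-pattern) transformation A = Sigma_x W / var(logit(y_hat)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import ttest_1samp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from memloop.sigproc import PowerFeatures

DEFAULT_C = 2.4e-4


class TrainingError(ValueError):
    """Labels do not permit training (e.g. a single class)."""


class UndefinedAUCError(ValueError):
    """AUC is undefined because only one class is present."""


@dataclass
class ClassifierModel:
    """Fitted recall classifier: weights, intercept and training metadata."""

    weights: np.ndarray
    intercept: float
    C: float
    class_weights: dict[int, float]
    pair_labels: list[str]
    freqs: np.ndarray
    training_sessions: list = field(default_factory=list)
    n_training_events: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.C <= 0:
            raise ValueError("penalty constant C must be positive")

    @property
    def n_features(self) -> int:
        return self.weights.size

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "C": self.C,
            "class_weights": {str(k): v for k, v in self.class_weights.items()},
            "pair_labels": self.pair_labels,
            "freqs": self.freqs.tolist(),
            "training_sessions": list(self.training_sessions),
            "n_training_events": self.n_training_events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        if d.get("schema_version", 1) != 1:
            raise ValueError("unsupported model schema version")
        return cls(
            weights=np.asarray(d["weights"]),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            class_weights={int(k): float(v) for k, v in d["class_weights"].items()},
            pair_labels=list(d["pair_labels"]),
            freqs=np.asarray(d["freqs"]),
            training_sessions=list(d.get("training_sessions", [])),
            n_training_events=int(d.get("n_training_events", 0)),
        )

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "ClassifierModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DecisionScores:
    """Per-event decision values and probabilities; logit(prob) == score."""

    scores: np.ndarray
    probs: np.ndarray

    @property
    def var_logit(self) -> float:
        """Variance (population, 1/n) of the logit-transformed outputs."""
        return float(np.var(self.scores))


@dataclass
class PermutationResult:
    observed_auc: float
    null_aucs: np.ndarray
    p_value: float
    n_perm: int


@dataclass
class ForwardModelMap:
    """Per-feature attribution values from the activation-pattern transform."""

    values: np.ndarray
    pair_labels: list[str]
    freqs: np.ndarray
    pair_regions: Optional[list[str]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.freqs)
        for i, pair in enumerate(self.pair_labels):
            for j, f in enumerate(self.freqs):
                rows.append(
                    dict(pair=pair, freq=f, attribution=self.values[i * k + j],
                         region=self.pair_regions[i] if self.pair_regions else None)
                )
        return pd.DataFrame(rows)


def _as_matrix(feats) -> np.ndarray:
    if isinstance(feats, PowerFeatures):
        return feats.values
    return np.asarray(feats, dtype=float)


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise TrainingError("both recalled and forgotten events are required")
    return labels


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def train(
    feats,
    labels: Sequence[bool],
    C: float = DEFAULT_C,
    pair_labels: Optional[list[str]] = None,
    freqs: Optional[np.ndarray] = None,
    training_sessions: Optional[list] = None,
) -> ClassifierModel:
    """Fit the weighted L2 logistic recall classifier.

    Deterministic given the data (lbfgs on a strictly convex objective; the
    intercept is unpenalized).
    """
    X = _as_matrix(feats)
    y = _check_labels(np.asarray(labels))
    clf = LogisticRegression(
        C=C, class_weight="balanced", solver="lbfgs",
        max_iter=20_000, tol=1e-10,
    )
    clf.fit(X, y)
    n = len(y)
    counts = {int(k): int((y == k).sum()) for k in np.unique(y)}
    class_weights = {k: n / (2.0 * v) for k, v in counts.items()}
    if isinstance(feats, PowerFeatures):
        pair_labels = pair_labels or list(feats.pair_labels)
        freqs = feats.freqs if freqs is None else freqs
    return ClassifierModel(
        weights=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        C=C,
        class_weights=class_weights,
        pair_labels=pair_labels or [f"f{i}" for i in range(X.shape[1])],
        freqs=np.asarray([0.0]) if freqs is None else freqs,
        training_sessions=training_sessions or [],
        n_training_events=n,
    )


def predict(model: ClassifierModel, feats) -> DecisionScores:
    """Decision scores s = x.W + b and probabilities logistic(s)."""
    X = _as_matrix(feats)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.n_features})"
        )
    s = X @ model.weights + model.intercept
    return DecisionScores(scores=s, probs=expit(s))


def auc(scores, labels) -> float:
    """ROC AUC: Mann-Whitney U / (n_pos * n_neg), ties counting one half."""
    if isinstance(scores, DecisionScores):
        scores = scores.scores
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise UndefinedAUCError("AUC is undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cross_validated_auc(
    feats, labels, C: float = DEFAULT_C, n_folds: int = 5, seed: int = 0
) -> float:
    """Stratified k-fold held-out AUC of the recall classifier."""
    X = _as_matrix(feats)
    y = _check_labels(np.asarray(labels))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in skf.split(X, y):
        m = train(X[tr], y[tr], C=C)
        scores[te] = predict(m, X[te]).scores
    return auc(scores, y)


def permutation_test(
    feats,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = DEFAULT_C,
    n_folds: int = 5,
) -> PermutationResult:
    """Label-permutation significance of the classifier.

    Each iteration shuffles the recalled labels, refits the full training
    pipeline and records the cross-validated AUC; the p-value is
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = _as_matrix(feats)
    y = _check_labels(np.asarray(labels))
    rng = np.random.default_rng(seed)
    observed = cross_validated_auc(X, y, C=C, n_folds=n_folds, seed=seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(y)
        try:
            null[i] = cross_validated_auc(X, perm, C=C, n_folds=n_folds, seed=seed)
        except (TrainingError, UndefinedAUCError) as exc:  # pragma: no cover
            raise TrainingError(f"permutation iteration {i} failed: {exc}") from exc
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return PermutationResult(observed, null, p, n_perm)


def forward_model(
    model: ClassifierModel, feats, pair_regions: Optional[list[str]] = None
) -> ForwardModelMap:
    """Activation-pattern attributions A = Sigma_x W / var(logit(y_hat)).

    ``Sigma_x`` is the (biased, 1/n) covariance of the attribution events'
    features and the variance is over the same events' logit outputs, so the
    shared n-normalization cancels. Equivalent to regressing each feature on
    the decision score.
    """
    X = _as_matrix(feats)
    ds = predict(model, X)
    var_s = ds.var_logit
    if var_s <= 0:
        raise ValueError("decision scores are constant: zero-variance forward model")
    Xc = X - X.mean(axis=0)
    cov_xs = Xc.T @ (Xc @ model.weights) / X.shape[0]
    pl = model.pair_labels
    if isinstance(feats, PowerFeatures):
        pl = list(feats.pair_labels)
    return ForwardModelMap(cov_xs / var_s, pl, model.freqs, pair_regions)


def aggregate_forward_models(
    maps: Sequence[ForwardModelMap],
) -> pd.DataFrame:
    """Group-level region x frequency attribution map.

    Each subject's map is first averaged within region x frequency cells;
    one-sample t statistics across subjects test each cell against zero.
    """
    frames = []
    for i, m in enumerate(maps):
        if m.pair_regions is None:
            raise ValueError("forward-model maps need pair_regions for aggregation")
        df = m.to_frame()
        df["subject"] = i
        frames.append(df)
    cells = (
        pd.concat(frames)
        .groupby(["region", "freq", "subject"])["attribution"]
        .mean()
        .reset_index()
    )
    rows = []
    for (region, freq), grp in cells.groupby(["region", "freq"]):
        vals = grp["attribution"].to_numpy()
        if len(vals) > 1:
            t, p = ttest_1samp(vals, 0.0)
        else:
            t, p = np.nan, np.nan
        rows.append(
            dict(region=region, freq=freq, mean_attribution=vals.mean(),
                 t=float(t), p=float(p), n_subjects=len(vals))
        )
    return pd.DataFrame(rows)
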