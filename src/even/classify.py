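"""Linear-discriminant quality model: training, scoring, ranking.

The two quality metrics feed a pooled-covariance linear discriminant with
classes ``bad`` / ``good``.  Each class k has a decision function

    delta_k(x) = sum_f (x_f * c_{k,f} - 1/2 * mu_{k,f} * c_{k,f}) + log pi_k

with coefficients ``c_k = Sigma^-1 mu_k`` (Sigma the pooled within-class
covariance), class means ``mu_k`` and priors ``pi_k``.  The scalar
decision score ``delta_good(x) - delta_bad(x)`` is positive for images
assigned to the good class, and its magnitude orders competing correction
variants into a quality ranking.

Features are maximum-normalized by the *training-set* column maxima, both
at training and at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.model_selection import StratifiedGroupKFold

from .metrics import FEATURE_NAMES

__all__ = [
    "LDAModel",
    "QualityRanking",
    "max_normalize",
    "train_lda",
    "decision_score",
    "classify",
    "cross_validate",
    "rank_variants",
    "kendall_tau",
    "normalized_even_score",
    "save_model",
    "load_model",
    "default_model",
]

MODEL_SCHEMA_VERSION = "1"

#: condition-number threshold above which a small ridge stabilizes the
#: pooled covariance (two features can be nearly collinear)
_COND_LIMIT = 1e12


@dataclass
class LDAModel:
    """A trained pooled-covariance linear discriminant.

    ``class_labels`` is ordered (bad, good); arrays are indexed by class
    then feature.  ``feature_max`` stores the training-set column maxima
    used for maximum normalization.
    """

    class_labels: tuple[str, str]
    means: np.ndarray            # (2, F) in normalized feature space
    coefficients: np.ndarray     # (2, F), c_k = Sigma^-1 mu_k
    priors: np.ndarray           # (2,)
    feature_max: np.ndarray      # (F,), raw-feature training maxima
    shared_covariance: np.ndarray  # (F, F) pooled covariance
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        self.feature_max = np.asarray(self.feature_max, dtype=float)
        self.shared_covariance = np.asarray(self.shared_covariance, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0) or np.any(self.priors <= 0):
            raise ValueError("class priors must be positive and sum to 1")

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def good_direction(self) -> np.ndarray:
        """Coefficient difference c_good - c_bad (the score gradient)."""
        return self.coefficients[1] - self.coefficients[0]


@dataclass
class QualityRanking:
    """Correction variants of one channel, ordered best-first."""

    channel_id: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        ids = [v for v, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    @property
    def best(self) -> str:
        return self.entries[0][0]


def max_normalize(features: np.ndarray, feature_max: np.ndarray) -> np.ndarray:
    """Divide each feature column by its training-set maximum.

    Prediction-time values larger than the training maximum simply map
    above 1; no clipping is applied.
    """
    features = np.asarray(features, dtype=float)
    feature_max = np.asarray(feature_max, dtype=float)
    if np.any(feature_max <= 0):
        raise ValueError("feature maxima must be > 0 for maximum normalization")
    return features / feature_max


def train_lda(
    features: np.ndarray,
    labels: Sequence[str],
    priors_mode: str = "empirical",
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> LDAModel:
    """Fit the pooled-covariance discriminant on raw (unnormalized) features.

    The routine computes the training-set feature maxima, maximum-
    normalizes, and fits class means, the pooled (unbiased) within-class
    covariance and the coefficients ``c_k = Sigma^-1 mu_k``.  Priors are
    the empirical class fractions, or uniform with
    ``priors_mode="uniform"``.  A near-singular covariance is ridged by
    ``1e-8 * trace / n_features`` before inversion; if it stays singular an
    error is raised.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2D array")
    classes = ("bad", "good")
    if set(np.unique(y)) - set(classes):
        raise ValueError(f"labels must be in {classes}")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 samples per class")

    feature_max = X.max(axis=0)
    Xn = max_normalize(X, feature_max)

    n, F = Xn.shape
    means = np.vstack([Xn[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((F, F))
    for i, c in enumerate(classes):
        d = Xn[y == c] - means[i]
        pooled += d.T @ d
    pooled /= n - len(classes)

    if np.linalg.cond(pooled) > _COND_LIMIT:
        pooled = pooled + np.eye(F) * (1e-8 * np.trace(pooled) / F)
    if np.linalg.cond(pooled) > 1e15:
        raise np.linalg.LinAlgError("pooled covariance is singular even after ridge")
    coefficients = np.linalg.solve(pooled, means.T).T

    if priors_mode == "empirical":
        priors = np.array([counts[c] / n for c in classes])
    elif priors_mode == "uniform":
        priors = np.array([0.5, 0.5])
    else:
        raise ValueError(f"unknown priors_mode {priors_mode!r}")

    return LDAModel(
        class_labels=classes,
        means=means,
        coefficients=coefficients,
        priors=priors,
        feature_max=feature_max,
        shared_covariance=pooled,
        feature_names=tuple(feature_names),
    )


def _delta(model: LDAModel, Xn: np.ndarray, k: int) -> np.ndarray:
    c = model.coefficients[k]
    mu = model.means[k]
    return Xn @ c - 0.5 * float(mu @ c) + np.log(model.priors[k])


def decision_score(model: LDAModel, features: np.ndarray) -> np.ndarray | float:
    """Decision score delta_good(x) - delta_bad(x) for normalized features.

    ``features`` must already be maximum-normalized with the model's
    ``feature_max`` (see :func:`max_normalize`).  Accepts a single feature
    vector or a 2D batch; positive scores mean the good class.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    score = _delta(model, X, 1) - _delta(model, X, 0)
    return float(score[0]) if np.asarray(features).ndim == 1 else score


def score_raw(model: LDAModel, raw_features: np.ndarray) -> np.ndarray | float:
    """Convenience: maximum-normalize raw features, then score them."""
    return decision_score(model, max_normalize(raw_features, model.feature_max))


def classify(model: LDAModel, features: np.ndarray) -> tuple[str, float]:
    """Label a single normalized feature vector.

    Positive score -> good; a score of exactly 0 is resolved conservatively
    to bad.
    """
    s = decision_score(model, np.asarray(features, dtype=float))
    s = float(np.asarray(s).ravel()[0])
    return ("good" if s > 0 else "bad", s)


def cross_validate(
    features: np.ndarray,
    labels: Sequence[str],
    group_ids: Sequence,
    n_folds: int = 5,
    seed: int = 0,
    priors_mode: str = "empirical",
) -> dict:
    """Grouped, class-balanced k-fold cross-validation of the discriminant.

    Groups (all images derived from one sample) never straddle the
    train/test boundary.  Reports per-fold and mean accuracy, sensitivity
    (true rate for good images) and specificity (true rate for bad
    images).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    g = np.asarray(group_ids)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    for gid in np.unique(g):
        if len(np.unique(y[g == gid])) > 1:
            raise ValueError(
                f"group {gid!r} contains both labels and cannot be split into "
                "balanced folds"
            )
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in splitter.split(X, y, groups=g):
        model = train_lda(X[train_idx], y[train_idx], priors_mode=priors_mode)
        Xn = max_normalize(X[test_idx], model.feature_max)
        pred = np.where(np.asarray(decision_score(model, Xn)) > 0, "good", "bad")
        truth = y[test_idx]
        acc = float((pred == truth).mean())
        good = truth == "good"
        bad = ~good
        sens = float((pred[good] == "good").mean()) if good.any() else np.nan
        spec = float((pred[bad] == "bad").mean()) if bad.any() else np.nan
        folds.append({"accuracy": acc, "sensitivity": sens, "specificity": spec,
                      "test_index": test_idx})
    out = {"folds": folds}
    for key in ("accuracy", "sensitivity", "specificity"):
        out[f"mean_{key}"] = float(np.nanmean([f[key] for f in folds]))
    return out


def rank_variants(
    model: LDAModel,
    variant_features: Mapping[str, np.ndarray],
    channel_id: str = "",
    method_priority: Sequence[str] = (),
) -> QualityRanking:
    """Order correction variants of one channel by decision score.

    ``variant_features`` maps variant id to its *raw* feature vector
    (normalization with the model's training maxima happens here).  Ties
    break by the configured method-priority list, then lexically.
    """
    if not variant_features:
        raise ValueError("no variants to rank")
    prio = {m: i for i, m in enumerate(method_priority)}

    def sort_key(item):
        vid, score = item
        return (-score, prio.get(vid, len(prio)), vid)

    scored = [
        (vid, float(np.asarray(score_raw(model, np.asarray(f, dtype=float))).ravel()[0]))
        for vid, f in variant_features.items()
    ]
    scored.sort(key=sort_key)
    return QualityRanking(channel_id=channel_id, entries=scored)


def kendall_tau(ranking_a: Sequence[str], ranking_b: Sequence[str]) -> float:
    """Kendall tau-b rank consistency of two orderings of the same ids."""
    a = list(ranking_a)
    b = list(ranking_b)
    if set(a) != set(b) or len(a) != len(b):
        raise ValueError("rankings must order the same set of ids")
    pos_b = {vid: i for i, vid in enumerate(b)}
    ranks_a = np.arange(len(a))
    ranks_b = np.array([pos_b[vid] for vid in a])
    tau, _ = kendalltau(ranks_a, ranks_b)
    return float(tau)


def normalized_even_score(scores: pd.DataFrame) -> pd.Series:
    """Per-image summed z-score of the per-channel decision scores.

    ``scores`` has one row per multichannel image and one column per
    channel.  Each channel is z-score normalized over the dataset
    (zero mean, unit std) and the channel z-scores of each image are
    summed into a single quality number.
    """
    scores = pd.DataFrame(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 images per channel to z-score")
    std = scores.std(axis=0, ddof=0)  # population z-score
    zero = std[std == 0]
    if len(zero):
        raise ValueError(f"zero score std in channel(s) {list(zero.index)}")
    z = (scores - scores.mean(axis=0)) / std
    return z.sum(axis=1)


def save_model(model: LDAModel, path: str | Path) -> None:
    """Serialize a model to versioned JSON."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "class_labels": list(model.class_labels),
        "feature_names": list(model.feature_names),
        "means": model.means.tolist(),
        "coefficients": model.coefficients.tolist(),
        "priors": model.priors.tolist(),
        "feature_max": model.feature_max.tolist(),
        "shared_covariance": model.shared_covariance.tolist(),
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _model_from_payload(payload: dict) -> LDAModel:
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        warnings.warn(
            f"model schema version {version!r} differs from expected "
            f"{MODEL_SCHEMA_VERSION!r}; attempting to load anyway"
        )
    required = (
        "class_labels", "means", "coefficients", "priors",
        "feature_max", "shared_covariance",
    )
    for key in required:
        if key not in payload:
            raise ValueError(f"model file is missing required field {key!r}")
    return LDAModel(
        class_labels=tuple(payload["class_labels"]),
        means=np.array(payload["means"]),
        coefficients=np.array(payload["coefficients"]),
        priors=np.array(payload["priors"]),
        feature_max=np.array(payload["feature_max"]),
        shared_covariance=np.array(payload["shared_covariance"]),
        feature_names=tuple(payload.get("feature_names", FEATURE_NAMES)),
        metadata=payload.get("metadata", {}),
    )


def load_model(path: str | Path) -> LDAModel:
    """Load a model saved by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    return _model_from_payload(payload)


def default_model() -> LDAModel:
    """The packaged default model, trained on the synthetic generator.

    This model was fitted on features of seeded synthetic phantoms (see
    ``metadata['training_data'] == 'synthetic'``); it is a reasonable
    starting point but training on one's own data is recommended for
    quantitative work.
    """
    text = resources.files("even").joinpath("data/default_model.json").read_text()
    return _model_from_payload(json.loads(text))
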