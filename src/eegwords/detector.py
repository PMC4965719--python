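"""Seizure/non-seizure classification from the fused feature vectors.

Each fragment is represented by the concatenation of its M-dimensional
hidden feature (channel-mean top-layer autoencoder activation) and the
d-dimensional temporal embedding of its EEG word.  A support vector
machine on standardized features provides continuous decision scores;
evaluation reports the zero-threshold error rate, the ROC curve over all
thresholds and the trapezoidal AUC.  Because seizures are rare, the test
pool can be trimmed to a ~50-50 class balance before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cbow import CBOWModel
from .sae import SAEModel, fragment_features
from .segmentation import LABEL_SEIZURE, FragmentPool
from .translation import EEGSentence


@dataclass
class FeatureVector:
    hidden: np.ndarray    # length M
    temporal: np.ndarray  # length d
    label: str

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.hidden, self.temporal])


@dataclass
class DetectionModel:
    """Fitted scaler + margin classifier, with the label convention used."""

    scaler: StandardScaler
    svm: SVC
    positive_label: str = LABEL_SEIZURE


@dataclass
class EvalReport:
    error_rate: float
    roc: np.ndarray  # (n, 2) columns (fpr, tpr)
    auc: float
    confusion: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "error_rate": self.error_rate,
            "auc": self.auc,
            "confusion": self.confusion,
            "roc": [[float(a), float(b)] for a, b in self.roc],
        }


def assemble_features(
    pool: FragmentPool,
    sae: SAEModel,
    cbow: CBOWModel,
    sentence: EEGSentence | list[EEGSentence],
) -> list[FeatureVector]:
    """Fuse hidden and temporal features, fragment by fragment.

    `sentence` may be one sentence or the per-record list from translate();
    either way the concatenated word ids must align 1:1 with the pool.
    """
    if isinstance(sentence, EEGSentence):
        word_ids = list(sentence.word_ids)
    else:
        word_ids = [w for s in sentence for w in s.word_ids]
    if len(word_ids) != len(pool):
        raise ValueError(
            f"sentence length {len(word_ids)} does not match pool size {len(pool)}"
        )
    hidden = fragment_features(sae, pool)
    return [
        FeatureVector(hidden=hidden[i], temporal=cbow.word_vector(word_ids[i]).copy(),
                      label=frag.label)
        for i, frag in enumerate(pool)
    ]


def balance_test_pool(pool: FragmentPool, seed: int = 0) -> FragmentPool:
    """Subsample the majority class to a ~50-50 balance, without replacement."""
    idx = balance_indices(pool.labels(), seed)
    return FragmentPool(
        fragments=[pool[i] for i in idx], window_s=pool.window_s, step_s=pool.step_s
    )


def balance_indices(labels: list[str], seed: int = 0) -> list[int]:
    labels = list(labels)
    pos = [i for i, l in enumerate(labels) if l == LABEL_SEIZURE]
    neg = [i for i, l in enumerate(labels) if l != LABEL_SEIZURE]
    if not pos or not neg:
        raise ValueError("balancing requires both classes present")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        pos = sorted(rng.choice(pos, size=len(neg), replace=False).tolist())
    elif len(neg) > len(pos):
        neg = sorted(rng.choice(neg, size=len(pos), replace=False).tolist())
    return sorted(pos + neg)


def train_detector(
    features: list[FeatureVector],
    kernel: str = "rbf",
    C: float = 1.0,
) -> DetectionModel:
    """Standardize the fused features and fit the margin classifier."""
    if not features:
        raise ValueError("no training features")
    X = np.array([f.values for f in features])
    y = np.array([1 if f.label == LABEL_SEIZURE else 0 for f in features])
    if len(np.unique(y)) < 2:
        raise ValueError("training features contain a single class")
    scaler = StandardScaler().fit(X)
    svm = SVC(kernel=kernel, C=C).fit(scaler.transform(X), y)
    return DetectionModel(scaler=scaler, svm=svm)


def predict(model: DetectionModel, features) -> tuple[list[str], np.ndarray]:
    """Labels (sign of the decision score) and continuous scores."""
    if isinstance(features, list) and features and isinstance(features[0], FeatureVector):
        X = np.array([f.values for f in features])
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.size == 0:
            return [], np.array([])
    scores = model.svm.decision_function(model.scaler.transform(X))
    labels = [model.positive_label if s > 0 else "non_seizure" for s in scores]
    return labels, scores


def evaluate(scores, labels, positive_class: str = LABEL_SEIZURE) -> EvalReport:
    """Zero-threshold error rate plus full-threshold ROC and trapezoid AUC.

    With a single class present the ROC is undefined; the report then
    carries an empty curve and NaN AUC but still a valid error rate.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if l == positive_class else 0 for l in labels])
    if len(y) == 0:
        raise ValueError("nothing to evaluate")
    pred = (scores > 0).astype(int)
    errors = int(np.sum(pred != y))
    confusion = {
        "tp": int(np.sum((pred == 1) & (y == 1))),
        "fp": int(np.sum((pred == 1) & (y == 0))),
        "tn": int(np.sum((pred == 0) & (y == 0))),
        "fn": int(np.sum((pred == 0) & (y == 1))),
    }
    if len(np.unique(y)) < 2:
        return EvalReport(error_rate=errors / len(y), roc=np.empty((0, 2)),
                          auc=float("nan"), confusion=confusion)
    fpr, tpr, _ = roc_curve(y, scores)
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(error_rate=errors / len(y), roc=roc, auc=auc, confusion=confusion)


def baseline_features(
    pool: FragmentPool,
    method: str = "downsample",
    target_dim: int = 276,
    fit_indices: list[int] | None = None,
) -> list[FeatureVector]:
    """Dimensionality-reduction baselines on the raw flattened fragments.

    "downsample" keeps target_dim uniformly spaced points of the flattened
    channels x samples fragment; "pca" projects onto the top target_dim
    principal components fitted on `fit_indices` only (default: all), so a
    train/test split can avoid leakage.  Returned FeatureVectors carry the
    reduced vector in `hidden` and an empty temporal part.
    """
    if len(pool) == 0:
        return []
    X = np.array([f.values.reshape(-1) for f in pool])
    raw_dim = X.shape[1]
    if not 1 <= target_dim <= raw_dim:
        raise ValueError(f"target_dim must be in [1, {raw_dim}], got {target_dim}")
    if method == "downsample":
        keep = np.linspace(0, raw_dim - 1, target_dim).round().astype(int)
        Z = X[:, keep]
    elif method == "pca":
        fit_X = X if fit_indices is None else X[list(fit_indices)]
        n_comp = min(target_dim, fit_X.shape[0])
        Z = PCA(n_components=n_comp, random_state=0).fit(fit_X).transform(X)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return [
        FeatureVector(hidden=Z[i], temporal=np.empty(0), label=frag.label)
        for i, frag in enumerate(pool)
    ]
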