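"""Soft-margin linear SVMs over explicit spectrum feature spaces.

The classifier is a standard soft-margin SVM with the linear kernel applied
to explicit (sparse) feature maps, so the primal weight vector
w = sum_i alpha_i y_i x_i is recoverable exactly and each feature's weight
ranks its contribution to the decision function — the quantity the whole
analysis revolves around.  Model selection iterates over the k-mer length
bounds (K1, K2) and the misclassification cost C, scoring each cell by
stratified cross-validated ROC AUC on an 80% training split and validating
the winner on the held-out 20%.

The combined (domain-adapted) model pools two domains after restricting
each record to the features selected by the per-domain models and applying
feature augmentation, so shared and domain-specific effects compete in a
single linear program.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_extraction import DictVectorizer
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .evaluation import MetricsReport, compute_metrics
from .features import FeatureVector, build_vectors

__all__ = [
    "TrainedModel",
    "GridSearchConfig",
    "GridSearchResult",
    "CombinedResult",
    "train_svm",
    "decision_values",
    "predict_labels",
    "feature_weights",
    "stratified_split",
    "cross_validate",
    "grid_search",
    "train_combined",
    "out_of_domain_eval",
    "save_model",
    "load_model",
]

DEFAULT_C_GRID = tuple(10.0 ** e for e in range(-10, 5))


@dataclass
class TrainedModel:
    """A linear SVM decision function over an explicit feature space."""

    weights: dict[str, float]
    bias: float
    params: dict
    training_meta: dict = field(default_factory=dict)
    domains: tuple | None = None  # set for augmented (combined) models

    def decision_value(self, vec: FeatureVector) -> float:
        w = self.weights
        return sum(w[f] * x for f, x in vec.entries.items() if f in w) + self.bias


@dataclass
class GridSearchConfig:
    """Search space and evaluation protocol for model selection.

    Defaults mirror the reference protocol: K1, K2 in 7..13 with K1 <= K2,
    C from 1e-10 to 1e4 in powers of 10, 10-fold stratified CV on an 80%
    training split with ROC AUC as the selection metric.
    """

    k_min: int = 7
    k_max: int = 13
    k_pairs: tuple | None = None  # explicit (K1, K2) list, overrides range
    c_grid: tuple = DEFAULT_C_GRID
    folds: int = 10
    holdout_fraction: float = 0.20
    seed: int = 0
    engineered: bool = False

    def __post_init__(self):
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid must be strictly positive")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        if self.k_pairs is not None:
            return [tuple(p) for p in self.k_pairs]
        return [
            (k1, k2)
            for k1, k2 in itertools.product(
                range(self.k_min, self.k_max + 1), repeat=2
            )
            if k1 <= k2
        ]


@dataclass
class GridSearchResult:
    best_params: dict
    cv_roc: float
    holdout_report: MetricsReport
    model: TrainedModel
    trace: pd.DataFrame


@dataclass
class CombinedResult:
    """Per-domain models plus the feature-augmented combined model."""

    hur_model: TrainedModel
    ttp_model: TrainedModel
    combined_model: TrainedModel
    candidate_features: set


def _labels_array(labels) -> np.ndarray:
    y = np.asarray(labels)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be +/-1")
    return y.astype(int)


def record_labels(records) -> np.ndarray:
    return np.array([1 if r.label == "positive" else -1 for r in records])


def train_svm(vectors, labels, c: float, params: dict | None = None) -> TrainedModel:
    """Fit a soft-margin linear SVM and recover explicit per-feature weights.

    The dual problem is solved exactly (SMO); the primal weights are
    sum_i alpha_i y_i x_i over the support vectors, mapped back to feature
    names.  Deterministic given identical inputs.
    """
    y = _labels_array(labels)
    if len(vectors) != len(y):
        raise ValueError("vectors and labels differ in length")
    if len(set(y.tolist())) < 2:
        raise ValueError("training data contains a single class")
    if c <= 0:
        raise ValueError("C must be > 0")
    for vec in vectors:
        for name, value in vec.entries.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite value for feature {name!r}")
    vectorizer = DictVectorizer(sparse=True)
    X = vectorizer.fit_transform([v.entries for v in vectors]).tocsr()
    # SVC requires 32-bit sparse indices
    X.indices = X.indices.astype(np.int32)
    X.indptr = X.indptr.astype(np.int32)
    clf = SVC(kernel="linear", C=c)
    clf.fit(X, y)
    coef = np.asarray(clf.coef_.todense()).ravel()
    names = vectorizer.get_feature_names_out()
    weights = {n: float(w) for n, w in zip(names, coef) if w != 0.0}
    return TrainedModel(
        weights=weights,
        bias=float(clf.intercept_[0]),
        params=dict(params or {}, C=c),
        training_meta={"n_train": len(y), "n_support": int(clf.support_.size)},
    )


def decision_values(model: TrainedModel, vectors) -> np.ndarray:
    """w.x + b for each vector; features absent from the model contribute 0."""
    return np.array([model.decision_value(v) for v in vectors])


def predict_labels(model: TrainedModel, vectors) -> np.ndarray:
    """Sign of the decision value; exactly 0 maps to the negative class."""
    return np.where(decision_values(model, vectors) > 0, 1, -1)


def feature_weights(model: TrainedModel, top_n: int | None = None):
    """Features ranked by descending weight; ``top_n`` truncates the list."""
    ranked = sorted(model.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if top_n is None else ranked[:top_n]


def stratified_split(records, fraction: float, seed: int):
    """(train, holdout) split preserving class proportions within one example."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    y = record_labels(records)
    train, holdout = train_test_split(
        list(records), test_size=fraction, stratify=y, random_state=seed,
        shuffle=True,
    )
    return train, holdout


def _vectors_for(records, params: dict, restrict=None) -> list[FeatureVector]:
    return build_vectors(
        records,
        params["k1"],
        params["k2"],
        engineered=params.get("engineered", False),
        restrict=restrict,
    )


def cross_validate(
    records, params: dict, folds: int = 10, seed: int = 0, vectors=None
) -> float:
    """Mean ROC AUC over stratified CV folds for one parameter cell.

    ``params`` carries k1, k2, C and the ``engineered`` block flag.  A
    pre-built vector list may be passed to avoid recomputing profiles when
    scanning C at fixed (k1, k2).
    """
    y = record_labels(records)
    counts = {label: int((y == label).sum()) for label in (-1, 1)}
    if min(counts.values()) < folds:
        raise ValueError(
            f"smallest class has {min(counts.values())} examples; "
            f"use folds <= {min(counts.values())}"
        )
    if vectors is None:
        vectors = _vectors_for(records, params)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rocs = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        m = train_svm(
            [vectors[i] for i in train_idx], y[train_idx], params["C"], params
        )
        scores = decision_values(m, [vectors[i] for i in test_idx])
        rocs.append(roc_auc_score(y[test_idx], scores))
    return float(np.mean(rocs))


def grid_search(records, config: GridSearchConfig, evaluator=None) -> GridSearchResult:
    """Exhaustive (K1, K2, C) search scored by cross-validated ROC AUC.

    Ties break toward the smallest C, then the narrowest k-range, then the
    smallest K1 (prefer simpler models).  The winning cell is refit on the
    full training split and validated on the holdout.  ``evaluator`` may
    replace :func:`cross_validate` (same signature, minus ``vectors``).
    """
    train, holdout = stratified_split(records, config.holdout_fraction, config.seed)
    rows = []
    for k1, k2 in config.pairs:
        base = {"k1": k1, "k2": k2, "engineered": config.engineered}
        vectors = None
        if evaluator is None:
            vectors = _vectors_for(train, base)
        for c in config.c_grid:
            params = dict(base, C=c)
            if evaluator is None:
                roc = cross_validate(
                    train, params, config.folds, config.seed, vectors=vectors
                )
            else:
                roc = evaluator(train, params, config.folds, config.seed)
            rows.append({"k1": k1, "k2": k2, "C": c, "cv_roc": roc})
    trace = pd.DataFrame(rows)
    best_row = min(
        rows, key=lambda r: (-r["cv_roc"], r["C"], r["k2"] - r["k1"], r["k1"])
    )
    best_params = {
        "k1": best_row["k1"],
        "k2": best_row["k2"],
        "C": best_row["C"],
        "engineered": config.engineered,
    }
    train_vectors = _vectors_for(train, best_params)
    model = train_svm(train_vectors, record_labels(train), best_params["C"], best_params)
    model.training_meta.update(seed=config.seed, folds=config.folds)
    holdout_vectors = _vectors_for(holdout, best_params)
    scores = decision_values(model, holdout_vectors)
    report = compute_metrics(
        record_labels(holdout), np.where(scores > 0, 1, -1), scores
    )
    return GridSearchResult(
        best_params=best_params,
        cv_roc=best_row["cv_roc"],
        holdout_report=report,
        model=model,
        trace=trace,
    )


def train_combined(hur_records, ttp_records, params: dict) -> CombinedResult:
    """Per-domain models plus a feature-augmented combined model.

    The HuR and TTP models are trained independently; the union of their
    nonzero-weight features forms the candidate set.  Each record's vector
    is restricted to the candidates, augmented by its domain tag, and the
    pooled data trains the combined model, whose features are either shared
    (unprefixed) or domain-specific ("HuR_"/"TTP_").
    """
    for recs, domain in ((hur_records, "HuR"), (ttp_records, "TTP")):
        for r in recs:
            if r.domain is None:
                r.domain = domain
    m_h = train_svm(
        _vectors_for(hur_records, params), record_labels(hur_records),
        params["C"], params,
    )
    m_t = train_svm(
        _vectors_for(ttp_records, params), record_labels(ttp_records),
        params["C"], params,
    )
    candidates = set(m_h.weights) | set(m_t.weights)
    if not candidates:
        raise ValueError("candidate feature set is empty")
    pooled = list(hur_records) + list(ttp_records)
    vectors = build_vectors(
        pooled,
        params["k1"],
        params["k2"],
        engineered=params.get("engineered", False),
        restrict=candidates,
        augment_by_domain=True,
    )
    m_b = train_svm(vectors, record_labels(pooled), params["C"], params)
    m_b.domains = ("HuR", "TTP")
    return CombinedResult(
        hur_model=m_h,
        ttp_model=m_t,
        combined_model=m_b,
        candidate_features=candidates,
    )


def out_of_domain_eval(
    model: TrainedModel, records, domain: str | None = None
) -> MetricsReport:
    """Score a model on a (possibly foreign-domain) labeled dataset.

    For a combined model, each record is augmented with its own domain tag
    before scoring, matching the feature space the model was trained in;
    ``domain`` tags any untagged records first.
    """
    if not records:
        raise ValueError("empty test set")
    if domain is not None:
        for r in records:
            if r.domain is None:
                r.domain = domain
    vectors = build_vectors(
        records,
        model.params["k1"],
        model.params["k2"],
        engineered=model.params.get("engineered", False),
        augment_by_domain=model.domains is not None,
    )
    scores = decision_values(model, vectors)
    return compute_metrics(
        record_labels(records), np.where(scores > 0, 1, -1), scores
    )


def save_model(model: TrainedModel, path) -> None:
    """Structured-text serialization: params, bias, full weight table."""
    with open(path, "w") as fh:
        for key, value in sorted(model.params.items()):
            fh.write(f"#param\t{key}\t{value}\n")
        if model.domains:
            fh.write(f"#domains\t{','.join(model.domains)}\n")
        fh.write(f"#bias\t{model.bias!r}\n")
        for name, weight in feature_weights(model):
            fh.write(f"{name}\t{weight!r}\n")


def load_model(path) -> TrainedModel:
    params: dict = {}
    weights: dict[str, float] = {}
    bias = 0.0
    domains = None
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#param":
                key, raw = fields[1], fields[2]
                if key in ("k1", "k2"):
                    params[key] = int(raw)
                elif key == "engineered":
                    params[key] = raw == "True"
                else:
                    params[key] = float(raw)
            elif fields[0] == "#domains":
                domains = tuple(fields[1].split(","))
            elif fields[0] == "#bias":
                bias = float(fields[1])
            else:
                weights[fields[0]] = float(fields[1])
    return TrainedModel(weights, bias, params, domains=domains)
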