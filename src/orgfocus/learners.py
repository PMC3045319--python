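"""Naive Bayes and ensemble learners over sparse feature vectors.

The base learner is a multinomial Naive Bayes with add-alpha smoothing over
count features, plus a separate per-class conditional table for categorical
features (the journal name), which keeps the independence factorization
correct for mixed feature types.  Bagging (bootstrap resampling, equal
member weights) and AdaBoost.M1 (sample re-weighting, member weights
ln((1-eps)/eps)) wrap the same base learner.

The section-sequence idea — label each section, then the document from the
sequence of section labels — is kept as :func:`classify_by_sections`, a
length-normalized aggregation of per-section log-posteriors; a full
sequence model (e.g. a linear-chain CRF) can be benchmarked through the
:func:`register_learner` plug-in interface instead of being reimplemented.

Feature vectors are ``{name: value}`` mappings: numeric values are counts
for the multinomial model, string values are categorical.  Feature names
unseen in training are ignored at prediction time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .corpus_io import ValidationError
from .features import FeatureVector

_MODEL_FORMAT_VERSION = 1


def _feats(vector) -> Mapping[str, float | str]:
    return vector.features if isinstance(vector, FeatureVector) else vector


def _split_types(
    feats: Mapping[str, float | str]
) -> tuple[dict[str, float], dict[str, str]]:
    counts, cats = {}, {}
    for name, value in feats.items():
        if isinstance(value, str):
            cats[name] = value
        else:
            v = float(value)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"feature {name!r} must be finite and >= 0")
            counts[name] = v
    return counts, cats


def _logsumexp(values: Sequence[float]) -> float:
    m = max(values)
    return m + math.log(sum(math.exp(v - m) for v in values))


@dataclass
class NBModel:
    """A fitted multinomial/categorical Naive Bayes model."""

    labels: tuple[str, ...]
    class_log_priors: dict[str, float]
    count_log_lik: dict[str, dict[str, float]]  # label -> feature -> log P(f|c)
    count_default_log: dict[str, float]  # label -> log P(unseen-in-class f|c)
    count_domain: frozenset[str]
    cat_tables: dict[str, dict[str, dict[str, float]]]  # name -> label -> value -> logp
    alpha: float = 1.0


def train_naive_bayes(
    vectors: Sequence,
    labels: Sequence[str],
    alpha: float = 1.0,
    sample_weight: Sequence[float] | None = None,
) -> NBModel:
    """Fit Naive Bayes with add-``alpha`` smoothing.

    Count features follow a multinomial event model; categorical features
    get per-class conditional tables with add-``alpha`` over the observed
    value domain.  ``sample_weight`` (used by boosting) scales each
    example's contribution to every count.  Requires at least two classes,
    each with at least one (positively weighted) example.
    """
    if len(vectors) != len(labels):
        raise ValidationError("vectors and labels must be aligned")
    if not vectors:
        raise ValidationError("cannot train on an empty corpus")
    if alpha <= 0:
        raise ValidationError("alpha must be > 0")
    w = (
        np.asarray(sample_weight, dtype=float)
        if sample_weight is not None
        else np.ones(len(vectors))
    )
    if len(w) != len(vectors) or (w < 0).any():
        raise ValidationError("sample_weight must be non-negative and aligned")
    if w.sum() <= 0:
        raise ValidationError("sample_weight must have positive total")
    # Normalize to mean 1 so the effective sample size (and hence the
    # relative strength of the add-alpha smoothing) is independent of the
    # weights' scale; uniform weights then reproduce unweighted training.
    w = w * (len(w) / w.sum())
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValidationError("training requires at least two classes")

    class_weight = {c: 0.0 for c in classes}
    count_totals: dict[str, dict[str, float]] = {c: {} for c in classes}
    cat_counts: dict[str, dict[str, dict[str, float]]] = {}
    cat_class_totals: dict[str, dict[str, float]] = {}
    domain: set[str] = set()

    for vector, label, weight in zip(vectors, labels, w):
        class_weight[label] += float(weight)
        counts, cats = _split_types(_feats(vector))
        totals = count_totals[label]
        for name, value in counts.items():
            domain.add(name)
            totals[name] = totals.get(name, 0.0) + weight * value
        for name, value in cats.items():
            table = cat_counts.setdefault(name, {c: {} for c in classes})
            table[label][value] = table[label].get(value, 0.0) + float(weight)
            per_class = cat_class_totals.setdefault(name, {c: 0.0 for c in classes})
            per_class[label] += float(weight)

    if any(class_weight[c] <= 0 for c in classes):
        empty = [c for c in classes if class_weight[c] <= 0]
        raise ValidationError(f"classes with zero (weighted) examples: {empty}")

    total_weight = sum(class_weight.values())
    priors = {c: math.log(class_weight[c] / total_weight) for c in classes}

    n_features = len(domain)
    count_log_lik: dict[str, dict[str, float]] = {}
    count_default_log: dict[str, float] = {}
    for c in classes:
        totals = count_totals[c]
        denom = sum(totals.values()) + alpha * n_features
        if denom <= 0:
            denom = 1.0
        count_log_lik[c] = {
            name: math.log((totals.get(name, 0.0) + alpha) / denom) for name in totals
        }
        count_default_log[c] = math.log(alpha / denom) if n_features else 0.0

    cat_tables: dict[str, dict[str, dict[str, float]]] = {}
    for name, per_class_counts in cat_counts.items():
        values = sorted({v for cc in per_class_counts.values() for v in cc})
        cat_tables[name] = {}
        for c in classes:
            denom = cat_class_totals[name][c] + alpha * len(values)
            cat_tables[name][c] = {
                v: math.log((per_class_counts[c].get(v, 0.0) + alpha) / denom)
                for v in values
            }

    return NBModel(
        labels=classes,
        class_log_priors=priors,
        count_log_lik=count_log_lik,
        count_default_log=count_default_log,
        count_domain=frozenset(domain),
        cat_tables=cat_tables,
        alpha=alpha,
    )


def predict_naive_bayes(model: NBModel, vector) -> dict[str, float]:
    """Posterior over labels; unseen feature names/values are ignored."""
    counts, cats = _split_types(_feats(vector))
    scores = []
    for c in model.labels:
        score = model.class_log_priors[c]
        table = model.count_log_lik[c]
        default = model.count_default_log[c]
        for name, value in counts.items():
            if name not in model.count_domain or value == 0:
                continue
            score += value * table.get(name, default)
        for name, value in cats.items():
            class_table = model.cat_tables.get(name)
            if class_table is None:
                continue
            logp = class_table[c].get(value)
            if logp is not None:
                score += logp
        scores.append(score)
    norm = _logsumexp(scores)
    return {c: math.exp(s - norm) for c, s in zip(model.labels, scores)}


def argmax_label(posterior: Mapping[str, float]) -> str:
    """Deterministic argmax: ties broken by label sort order."""
    return max(sorted(posterior), key=lambda c: posterior[c])


@dataclass
class Ensemble:
    """Weighted Naive Bayes members; bagging or AdaBoost.M1."""

    members: tuple[tuple[NBModel, float], ...]
    method: str  # "bagging" | "adaboost"
    seed: int = 0


def train_bagging(
    vectors: Sequence,
    labels: Sequence[str],
    n_bags: int = 10,
    alpha: float = 1.0,
    seed: int = 0,
) -> Ensemble:
    """Bootstrap-resampled Naive Bayes members with equal weights.

    A resample missing a class is redrawn (up to 100 attempts per bag).
    Deterministic under ``seed``.
    """
    if n_bags < 1:
        raise ValidationError("n_bags must be >= 1")
    rng = np.random.default_rng(seed)
    classes = set(labels)
    n = len(vectors)
    members = []
    for _ in range(n_bags):
        for attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if {labels[i] for i in idx} == classes:
                break
        else:
            raise ValidationError("could not draw a bootstrap sample with all classes")
        model = train_naive_bayes(
            [vectors[i] for i in idx], [labels[i] for i in idx], alpha=alpha
        )
        members.append((model, 1.0))
    return Ensemble(members=tuple(members), method="bagging", seed=seed)


def train_adaboost(
    vectors: Sequence,
    labels: Sequence[str],
    rounds: int = 10,
    alpha: float = 1.0,
    seed: int = 0,
) -> Ensemble:
    """Multiclass AdaBoost.M1 with a weighted Naive Bayes base learner.

    Round member weight is ln((1-eps)/eps); a round with eps = 0 keeps its
    member and stops, a round with eps >= 0.5 stops (the offending member is
    kept only when it is the first).
    """
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    n = len(vectors)
    w = np.full(n, 1.0 / n)
    members: list[tuple[NBModel, float]] = []
    for _ in range(rounds):
        model = train_naive_bayes(vectors, labels, alpha=alpha, sample_weight=w)
        preds = [argmax_label(predict_naive_bayes(model, v)) for v in vectors]
        miss = np.array([p != g for p, g in zip(preds, labels)], dtype=float)
        eps = float(w @ miss)
        if eps <= 0.0:
            eps_f = 1e-10
            members.append((model, math.log((1 - eps_f) / eps_f)))
            break
        if eps >= 0.5:
            if not members:
                members.append((model, 1.0))
            break
        beta = eps / (1.0 - eps)
        members.append((model, math.log(1.0 / beta)))
        w = w * np.where(miss > 0, 1.0, beta)
        w = w / w.sum()
    return Ensemble(members=tuple(members), method="adaboost", seed=seed)


def predict_ensemble(ensemble: Ensemble, vector) -> dict[str, float]:
    """Bagging: weight-normalized mean posterior.  AdaBoost: weighted
    argmax votes normalized to a distribution."""
    if not ensemble.members:
        raise ValidationError("empty ensemble")
    labels = ensemble.members[0][0].labels
    if ensemble.method == "bagging":
        acc = {c: 0.0 for c in labels}
        total = sum(weight for _, weight in ensemble.members)
        for model, weight in ensemble.members:
            post = predict_naive_bayes(model, vector)
            for c in labels:
                acc[c] += weight * post[c]
        return {c: acc[c] / total for c in labels}
    votes = {c: 0.0 for c in labels}
    for model, weight in ensemble.members:
        votes[argmax_label(predict_naive_bayes(model, vector))] += weight
    total = sum(votes.values())
    if total <= 0:
        return {c: 1.0 / len(labels) for c in labels}
    return {c: v / total for c, v in votes.items()}


def classify_by_sections(
    model: NBModel,
    section_vectors: Sequence,
    kinds: Sequence[str] | None = None,
    kind_weights: Mapping[str, float] | None = None,
) -> str:
    """Two-stage document label from per-section posteriors.

    Each section is scored by the (section-level) base model; the document
    label is the argmax of the length-normalized, kind-weighted sum of
    section log-posteriors.  Default weights are uniform.
    """
    if not section_vectors:
        raise ValidationError("document has no sections to classify")
    weights = []
    for i in range(len(section_vectors)):
        kind = kinds[i] if kinds is not None else None
        weights.append(
            (kind_weights or {}).get(kind, 1.0) if kind is not None else 1.0
        )
    total_w = sum(weights)
    scores = {c: 0.0 for c in model.labels}
    for vector, weight in zip(section_vectors, weights):
        post = predict_naive_bayes(model, vector)
        for c in model.labels:
            scores[c] += weight * math.log(max(post[c], 1e-300))
    for c in scores:
        scores[c] /= total_w
    return argmax_label(scores)


# ---------------------------------------------------------------------------
# plug-in learner registry

TrainFn = Callable[[Sequence, Sequence[str], int], object]
PredictFn = Callable[[object, object], Mapping[str, float]]

_REGISTRY: dict[str, tuple[TrainFn, PredictFn]] = {}


def register_learner(name: str, train_fn: TrainFn, predict_fn: PredictFn) -> None:
    """Register an external learner under ``name`` (collisions are errors)."""
    if name in _REGISTRY:
        raise ValidationError(f"learner {name!r} already registered")
    _REGISTRY[name] = (train_fn, predict_fn)


def get_learner(name: str) -> tuple[TrainFn, PredictFn]:
    if name not in _REGISTRY:
        raise ValidationError(
            f"unknown learner {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def registered_learners() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


register_learner(
    "nb",
    lambda vectors, labels, seed: train_naive_bayes(vectors, labels),
    lambda model, vector: predict_naive_bayes(model, vector),
)
register_learner(
    "nb_bag",
    lambda vectors, labels, seed: train_bagging(vectors, labels, seed=seed),
    lambda model, vector: predict_ensemble(model, vector),
)
register_learner(
    "nb_boost",
    lambda vectors, labels, seed: train_adaboost(vectors, labels, seed=seed),
    lambda model, vector: predict_ensemble(model, vector),
)


# ---------------------------------------------------------------------------
# serialization


def _nb_to_dict(model: NBModel) -> dict:
    return {
        "labels": list(model.labels),
        "class_log_priors": model.class_log_priors,
        "count_log_lik": model.count_log_lik,
        "count_default_log": model.count_default_log,
        "count_domain": sorted(model.count_domain),
        "cat_tables": model.cat_tables,
        "alpha": model.alpha,
    }


def _nb_from_dict(payload: dict) -> NBModel:
    return NBModel(
        labels=tuple(payload["labels"]),
        class_log_priors=dict(payload["class_log_priors"]),
        count_log_lik={c: dict(t) for c, t in payload["count_log_lik"].items()},
        count_default_log=dict(payload["count_default_log"]),
        count_domain=frozenset(payload["count_domain"]),
        cat_tables={
            name: {c: dict(vals) for c, vals in table.items()}
            for name, table in payload["cat_tables"].items()
        },
        alpha=float(payload["alpha"]),
    )


def save_model(model: NBModel | Ensemble, path: str | Path) -> None:
    """Write a model as versioned structured text (JSON)."""
    if isinstance(model, NBModel):
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "kind": "nb",
            "model": _nb_to_dict(model),
        }
    elif isinstance(model, Ensemble):
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "kind": "ensemble",
            "method": model.method,
            "seed": model.seed,
            "members": [
                {"model": _nb_to_dict(m), "weight": weight}
                for m, weight in model.members
            ],
        }
    else:
        raise ValidationError(f"cannot serialize model of type {type(model)!r}")
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> NBModel | Ensemble:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValidationError("unsupported model format version")
    if payload["kind"] == "nb":
        return _nb_from_dict(payload["model"])
    if payload["kind"] == "ensemble":
        return Ensemble(
            members=tuple(
                (_nb_from_dict(m["model"]), float(m["weight"]))
                for m in payload["members"]
            ),
            method=payload["method"],
            seed=int(payload["seed"]),
        )
    raise ValidationError(f"unknown model kind {payload['kind']!r}")
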