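"""Scoring, cross-validation, the corrected resampled t-test and ablation runs.

Scoring is one-vs-rest per class: for each organism label the multi-class
predictions are binarized and precision P = TP/(TP+FP), recall
R = TP/(TP+FN) and F = 2PR/(P+R) are computed exactly as conventionally
printed.  Cross-class summaries use the macro-average F.

Cross-validation is stratified.  Documents resolved by the title rule are
scored with their rule labels and excluded from learner training (they can
also be excluded from scoring with ``score_rule_docs=False``).  The
training-data-dependent feature selectors (MeSH headings, corpus gene
list) are refitted inside each training fold, so no test information leaks
into feature selection.

For comparing two pipeline specifications, repeated (runs × k) CV produces
paired per-fold macro-F differences on identical fold partitions, and
:func:`corrected_resampled_ttest` applies the variance correction of
Nadeau–Bengio / Bouckaert–Frank, which inflates the variance by the
test/train size ratio to account for overlapping training sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Document, ValidationError
from .features import FeatureConfig, FeatureExtractor
from .learners import argmax_label, get_learner
from .taggers import (
    GeneLexicon,
    OrganismLexicon,
    TaggedDocument,
    default_organism_lexicon,
    default_synonym_table,
    tag_document,
)
from .triage import TriageResult, classify_by_title, select_content
from .synthetic_corpus import corrupt_gene_tags


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f_score: float


def confusion_counts(
    gold: Sequence[str], predicted: Sequence[str], positive_class: str
) -> ConfusionMatrix:
    """One-vs-rest confusion counts for ``positive_class``."""
    if len(gold) != len(predicted):
        raise ValidationError("gold and predicted sequences must be aligned")
    tp = fp = fn = tn = 0
    for g, p in zip(gold, predicted):
        if g == positive_class and p == positive_class:
            tp += 1
        elif g == positive_class:
            fn += 1
        elif p == positive_class:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def f_score_from_pr(precision: float, recall: float) -> float:
    """F = 2PR/(P+R); 0 when P+R = 0."""
    if precision + recall <= 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f(cm: ConfusionMatrix) -> Metrics:
    """P, R and F from confusion counts; zero denominators yield 0."""
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
    return Metrics(
        precision=precision, recall=recall, f_score=f_score_from_pr(precision, recall)
    )


def macro_f(gold: Sequence[str], predicted: Sequence[str], labels: Sequence[str]) -> float:
    return float(
        np.mean(
            [
                precision_recall_f(confusion_counts(gold, predicted, c)).f_score
                for c in labels
            ]
        )
    )


# ---------------------------------------------------------------------------
# pipeline specification and preparation


@dataclass(frozen=True)
class EvalSpec:
    """Everything that defines one evaluated pipeline configuration."""

    learner: str = "nb"
    features: FeatureConfig = field(default_factory=FeatureConfig)
    content_selection: bool = True
    abstract_only: bool = False
    gene_noise: tuple[float, float] | None = None  # (fp_rate, fn_rate)
    score_rule_docs: bool = True
    pattern_rule: bool = False


@dataclass(frozen=True)
class PreparedDoc:
    tagged: TaggedDocument
    triage: TriageResult
    gold: str


def _abstract_view(doc: Document) -> Document:
    abstracts = [s for s in doc.sections if s.kind == "abstract"]
    return doc.with_sections(abstracts or doc.sections[:1])


def prepare_corpus(
    docs: Sequence[Document],
    spec: EvalSpec,
    organism_lexicon: OrganismLexicon,
    gene_lexicon: GeneLexicon | None = None,
    seed: int = 0,
    reference_distribution=None,
) -> list[PreparedDoc]:
    """Normalize view, triage, content-select and tag every document."""
    rng = np.random.default_rng(seed)
    prepared = []
    for doc in docs:
        if doc.gold_label is None:
            raise ValidationError(f"{doc.doc_id}: gold label required for evaluation")
        view = _abstract_view(doc) if spec.abstract_only else doc
        triage = classify_by_title(view, organism_lexicon)
        if spec.content_selection and view.sections:
            if any(s.kind in ("abstract", "introduction", "results", "conclusion") for s in view.sections):
                view = select_content(view)
            elif reference_distribution is not None:
                pre = tag_document(view, organism_lexicon, gene_lexicon, spec.pattern_rule)
                view = select_content(
                    view, ref=reference_distribution, gene_mentions=pre.gene_mentions
                )
        tagged = tag_document(view, organism_lexicon, gene_lexicon, spec.pattern_rule)
        if spec.gene_noise is not None and any(spec.gene_noise):
            fp, fn = spec.gene_noise
            noisy = corrupt_gene_tags(tagged.gene_mentions, fp, fn, rng, doc=view)
            tagged = replace(tagged, gene_mentions=noisy)
        prepared.append(PreparedDoc(tagged=tagged, triage=triage, gold=doc.gold_label))
    return prepared


# ---------------------------------------------------------------------------
# cross-validation


def stratified_folds(
    labels: Sequence[str], k: int, seed: int
) -> list[np.ndarray]:
    """Seeded stratified partition into k test folds (index arrays)."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, label in enumerate(labels):
        by_class.setdefault(label, []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if len(idx) < k:
            raise ValidationError(
                f"class {label!r} has {len(idx)} docs, fewer than k={k}"
            )
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


@dataclass
class CVResult:
    labels: tuple[str, ...]
    fold_class_metrics: list[dict[str, Metrics]]
    macro_f_per_fold: list[float]
    predictions: dict[str, str]
    folds: list[tuple[str, ...]]  # doc ids per test fold

    @property
    def macro_f(self) -> float:
        return float(np.mean(self.macro_f_per_fold))

    def pooled_per_class(self, gold: Mapping[str, str]) -> dict[str, Metrics]:
        ids = list(self.predictions)
        golds = [gold[i] for i in ids]
        preds = [self.predictions[i] for i in ids]
        return {
            c: precision_recall_f(confusion_counts(golds, preds, c))
            for c in self.labels
        }


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * 9973 + salt * 7919 + 17) % (2**31 - 1))


def _run_cv(
    prepared: Sequence[PreparedDoc],
    folds: Sequence[np.ndarray],
    spec: EvalSpec,
    organism_lexicon: OrganismLexicon,
    gene_lexicon: GeneLexicon | None,
    synonym_table,
    seed: int,
) -> CVResult:
    labels_set = tuple(sorted({p.gold for p in prepared}))
    train_fn, predict_fn = get_learner(spec.learner)
    fold_metrics: list[dict[str, Metrics]] = []
    macro_per_fold: list[float] = []
    predictions: dict[str, str] = {}
    fold_ids: list[tuple[str, ...]] = []
    all_idx = set(range(len(prepared)))
    for fi, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train_idx = sorted(all_idx - test_set)
        train = [
            prepared[i] for i in train_idx if not prepared[i].triage.rule_fired
        ]
        if not train:
            raise ValidationError("no training documents left after triage")
        extractor = FeatureExtractor(
            spec.features, organism_lexicon, gene_lexicon, synonym_table
        ).fit([p.tagged for p in train], [p.gold for p in train])
        train_vectors = [extractor.transform(p.tagged) for p in train]
        model = train_fn(
            train_vectors, [p.gold for p in train], _derive_seed(seed, fi)
        )
        gold_scored: list[str] = []
        pred_scored: list[str] = []
        ids: list[str] = []
        for i in sorted(test_set):
            p = prepared[i]
            if p.triage.rule_fired:
                pred = p.triage.label
                if not spec.score_rule_docs:
                    predictions[p.tagged.doc.doc_id] = pred
                    ids.append(p.tagged.doc.doc_id)
                    continue
            else:
                posterior = predict_fn(model, extractor.transform(p.tagged))
                pred = argmax_label(posterior)
            predictions[p.tagged.doc.doc_id] = pred
            ids.append(p.tagged.doc.doc_id)
            gold_scored.append(p.gold)
            pred_scored.append(pred)
        fold_ids.append(tuple(ids))
        per_class = {
            c: precision_recall_f(confusion_counts(gold_scored, pred_scored, c))
            for c in labels_set
        }
        fold_metrics.append(per_class)
        macro_per_fold.append(
            float(np.mean([m.f_score for m in per_class.values()]))
        )
    return CVResult(
        labels=labels_set,
        fold_class_metrics=fold_metrics,
        macro_f_per_fold=macro_per_fold,
        predictions=predictions,
        folds=fold_ids,
    )


def k_fold_cv(
    docs: Sequence[Document],
    learner_name: str = "nb",
    feature_config: FeatureConfig | str | None = None,
    k: int = 10,
    seed: int = 0,
    organism_lexicon: OrganismLexicon | None = None,
    gene_lexicon: GeneLexicon | None = None,
    synonym_table=None,
    content_selection: bool = True,
    abstract_only: bool = False,
    gene_noise: tuple[float, float] | None = None,
    score_rule_docs: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of one pipeline configuration."""
    if isinstance(feature_config, str):
        feature_config = FeatureConfig.from_name(feature_config)
    spec = EvalSpec(
        learner=learner_name,
        features=feature_config or FeatureConfig(),
        content_selection=content_selection,
        abstract_only=abstract_only,
        gene_noise=gene_noise,
        score_rule_docs=score_rule_docs,
    )
    organism_lexicon = organism_lexicon or default_organism_lexicon()
    synonym_table = (
        synonym_table
        if synonym_table is not None
        else (default_synonym_table() if "AGN" in spec.features.enabled else {})
    )
    prepared = prepare_corpus(
        docs, spec, organism_lexicon, gene_lexicon, seed=_derive_seed(seed, 101)
    )
    folds = stratified_folds([p.gold for p in prepared], k, seed)
    return _run_cv(
        prepared, folds, spec, organism_lexicon, gene_lexicon, synonym_table, seed
    )


@dataclass
class RepeatedCVResult:
    diffs: np.ndarray  # runs*k paired macro-F differences (spec_a - spec_b)
    macro_a: float
    macro_b: float
    n_train: int
    n_test: int

    @property
    def mean_diff(self) -> float:
        return float(self.diffs.mean())


def repeated_cv(
    docs: Sequence[Document],
    spec_a: EvalSpec,
    spec_b: EvalSpec,
    runs: int = 10,
    k: int = 10,
    seed: int = 0,
    organism_lexicon: OrganismLexicon | None = None,
    gene_lexicon: GeneLexicon | None = None,
    synonym_table=None,
) -> RepeatedCVResult:
    """runs × k CV of two specs on identical fold partitions.

    Returns the runs*k paired per-fold macro-F differences (a - b), the
    ingredients for :func:`corrected_resampled_ttest`.
    """
    organism_lexicon = organism_lexicon or default_organism_lexicon()
    if synonym_table is None:
        need_agn = "AGN" in (spec_a.features.enabled | spec_b.features.enabled)
        synonym_table = default_synonym_table() if need_agn else {}
    prepared = {
        id(spec): prepare_corpus(
            docs, spec, organism_lexicon, gene_lexicon, seed=_derive_seed(seed, 101)
        )
        for spec in (spec_a, spec_b)
    }
    diffs: list[float] = []
    totals_a: list[float] = []
    totals_b: list[float] = []
    golds = [d.gold_label for d in docs]
    for run in range(runs):
        folds = stratified_folds(golds, k, _derive_seed(seed, 300 + run))
        res_a = _run_cv(
            prepared[id(spec_a)], folds, spec_a, organism_lexicon, gene_lexicon,
            synonym_table, _derive_seed(seed, run),
        )
        res_b = _run_cv(
            prepared[id(spec_b)], folds, spec_b, organism_lexicon, gene_lexicon,
            synonym_table, _derive_seed(seed, run),
        )
        diffs.extend(
            a - b for a, b in zip(res_a.macro_f_per_fold, res_b.macro_f_per_fold)
        )
        totals_a.append(res_a.macro_f)
        totals_b.append(res_b.macro_f)
    n = len(docs)
    n_test = n // k
    return RepeatedCVResult(
        diffs=np.array(diffs),
        macro_a=float(np.mean(totals_a)),
        macro_b=float(np.mean(totals_b)),
        n_train=n - n_test,
        n_test=n_test,
    )


def corrected_resampled_ttest(
    diffs: Sequence[float], n_train: int, n_test: int
) -> tuple[float, float]:
    """Corrected resampled t-test on paired CV score differences.

    t = mean(d) / sqrt((1/J + n_test/n_train) * var(d)) with J differences
    and unbiased sample variance; two-tailed p from Student-t with J-1
    degrees of freedom.  With the correction term zeroed (n_test = 0) this
    is the classic paired resampled t statistic.  Zero variance: t=0, p=1
    when the mean is also zero, else a degenerate (inf, 0) result.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValidationError("need at least two differences")
    if n_train <= 0:
        raise ValidationError("n_train must be positive")
    j = d.size
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    if var == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        import logging

        logging.getLogger(__name__).warning(
            "corrected_resampled_ttest: zero variance with nonzero mean; "
            "degenerate result"
        )
        return math.copysign(math.inf, mean), 0.0
    t = mean / math.sqrt((1.0 / j + n_test / n_train) * var)
    p = float(2.0 * stats.t.sf(abs(t), df=j - 1))
    return t, p


# ---------------------------------------------------------------------------
# ablation harness


@dataclass
class AblationReport:
    """Grid of (model, feature set, class) → metrics on shared folds."""

    grid: dict[tuple[str, str, str], Metrics]
    macro: dict[tuple[str, str], float]
    seed: int
    k: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (model, feature_set, label), m in sorted(self.grid.items()):
            rows.append(
                {
                    "model": model,
                    "features": feature_set,
                    "class": label,
                    "P": round(m.precision, 3),
                    "R": round(m.recall, 3),
                    "F": round(m.f_score, 3),
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        df = self.to_dataframe()
        macro_rows = pd.DataFrame(
            [
                {"model": m, "features": fs, "class": "macro", "F": round(v, 3)}
                for (m, fs), v in sorted(self.macro.items())
            ]
        )
        return (
            df.to_string(index=False)
            + "\n\nmacro-averaged F:\n"
            + macro_rows.to_string(index=False)
        )

    def delta(self, model: str, set_a: str, set_b: str) -> float:
        """Macro-F difference between two feature sets for one model."""
        return self.macro[(model, set_a)] - self.macro[(model, set_b)]


def ablation_run(
    docs: Sequence[Document],
    learner_names: Sequence[str],
    feature_sets: Sequence[str | FeatureConfig],
    k: int = 10,
    seed: int = 0,
    organism_lexicon: OrganismLexicon | None = None,
    gene_lexicon: GeneLexicon | None = None,
    synonym_table=None,
    content_selection: bool = True,
    abstract_only: bool = False,
) -> AblationReport:
    """Full (model × feature-set) grid on identical fold partitions."""
    organism_lexicon = organism_lexicon or default_organism_lexicon()
    configs: list[tuple[str, FeatureConfig]] = []
    for fs in feature_sets:
        cfg = FeatureConfig.from_name(fs) if isinstance(fs, str) else fs
        configs.append((cfg.name or "+".join(sorted(cfg.enabled)), cfg))
    if synonym_table is None:
        need_agn = any("AGN" in cfg.enabled for _, cfg in configs)
        synonym_table = default_synonym_table() if need_agn else {}
    golds = {d.doc_id: d.gold_label for d in docs}
    grid: dict[tuple[str, str, str], Metrics] = {}
    macro: dict[tuple[str, str], float] = {}
    fold_labels = [d.gold_label for d in docs]
    folds = stratified_folds(fold_labels, k, seed)
    for set_name, cfg in configs:
        spec = EvalSpec(
            features=cfg,
            content_selection=content_selection,
            abstract_only=abstract_only,
        )
        prepared = prepare_corpus(
            docs, spec, organism_lexicon, gene_lexicon, seed=_derive_seed(seed, 101)
        )
        for learner_name in learner_names:
            run_spec = replace(spec, learner=learner_name)
            result = _run_cv(
                prepared, folds, run_spec, organism_lexicon, gene_lexicon,
                synonym_table, seed,
            )
            for label, metrics in result.pooled_per_class(golds).items():
                grid[(learner_name, set_name, label)] = metrics
            macro[(learner_name, set_name)] = result.macro_f
    return AblationReport(grid=grid, macro=macro, seed=seed, k=k)
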