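"""The eight document feature families and their assembly into one vector.

Families (short names follow the field's usage):

* ``GN`` — per-gene counts for the document's top-n most frequent genes.
* ``OF`` — raw organism mention counts per label.
* ``MH`` — indicators for the per-class most frequent MeSH headings,
  selected on training data only.
* ``DT`` — organism / gene indicators for the document title.
* ``TS`` — the term-species score: for every gene mention *g* and organism
  mention *s* in the same sentence, the organism's label receives weight
  ``1/(1+d)`` with ``d`` the token distance; weights are tallied per label
  over the whole article.  This is the feature that resolves gene-name
  ambiguity across species.
* ``JN`` — the (normalized) journal name, a categorical feature.
* ``NT`` — how many of the corpus-level top-100 genes occur in the document
  (gene list fitted on training data only).
* ``AGN`` — additional gene names looked up from a local
  (gene, organism) → name table for co-sentence gene–species pairs.

Feature vectors are sparse name → value mappings: numeric counts for most
families, a string value for the categorical journal feature.  Disabling a
family removes its features entirely, which is what gives ablation runs
their semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

from .corpus_io import Document, ValidationError, tokenize
from .taggers import (
    GeneLexicon,
    GeneList,
    Mention,
    OrganismLexicon,
    TaggedDocument,
    rank_genes,
)

FEATURE_FAMILIES = ("GN", "OF", "MH", "DT", "TS", "JN", "NT", "AGN")

#: The basic feature set used as the ablation baseline.
F1_FAMILIES = frozenset({"GN", "MH", "JN", "DT"})

_ALIASES = {"ADN": "AGN", "AND": "AGN"}

#: Distance decay functions for the TS feature.  ``inverse_distance`` is the
#: default: the simplest monotone choice with w(0)=1.
DECAY_FUNCTIONS: dict[str, Callable[[int], float]] = {
    "inverse_distance": lambda d: 1.0 / (1.0 + d),
    "exponential": lambda d: math.exp(-d),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Which families are enabled and their knobs.

    ``n_top_genes`` caps both the per-document GN list and the corpus-level
    NT list (default 100).  ``mesh_per_class`` is the number of MeSH
    headings selected per class (default 3).
    """

    enabled: frozenset[str] = F1_FAMILIES
    n_top_genes: int = 100
    mesh_per_class: int = 3
    ts_decay: str = "inverse_distance"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.enabled:
            raise ValidationError("at least one feature family must be enabled")
        unknown = set(self.enabled) - set(FEATURE_FAMILIES)
        if unknown:
            raise ValidationError(f"unknown feature families: {sorted(unknown)}")
        if self.n_top_genes < 1 or self.mesh_per_class < 1:
            raise ValidationError("n_top_genes and mesh_per_class must be >= 1")
        if self.ts_decay not in DECAY_FUNCTIONS:
            raise ValidationError(f"unknown ts_decay: {self.ts_decay!r}")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "FeatureConfig":
        """Parse a feature-set name like ``F1``, ``F1+TS`` or ``full``.

        ``F1`` expands to {GN, MH, JN, DT}; ``full`` to all eight families;
        ``ADN``/``AND`` are accepted as aliases for ``AGN``.
        """
        label = name.strip()
        if label.casefold() == "full":
            return cls(enabled=frozenset(FEATURE_FAMILIES), name="full", **kwargs)
        enabled: set[str] = set()
        for part in label.split("+"):
            token = part.strip().upper()
            token = _ALIASES.get(token, token)
            if token == "F1":
                enabled |= F1_FAMILIES
            elif token in FEATURE_FAMILIES:
                enabled.add(token)
            else:
                raise ValidationError(f"unknown feature-set component: {part!r}")
        return cls(enabled=frozenset(enabled), name=label, **kwargs)


@dataclass(frozen=True)
class FeatureVector:
    """Named features for one document under a configuration."""

    doc_id: str
    features: Mapping[str, float | str]
    config: FeatureConfig | None = None


# ---------------------------------------------------------------------------
# individual extractors


def gene_name_features(
    doc: Document, gene_mentions: Sequence[Mention], config: FeatureConfig
) -> dict[str, float]:
    """GN: counts for the document's top-n most frequent genes."""
    ranked = rank_genes(gene_mentions, n_cap=config.n_top_genes)
    return {f"gn:{sym}": float(count) for sym, count in ranked.ranked}


def organism_frequency(
    doc: Document,
    organism_mentions: Sequence[Mention],
    labels: Sequence[str],
) -> dict[str, float]:
    """OF: raw mention count per organism label (zeros included)."""
    counts = {label: 0 for label in labels}
    for m in organism_mentions:
        if m.canonical in counts:
            counts[m.canonical] += 1
    return {f"of:{label}": float(c) for label, c in counts.items()}


class MeshSelector:
    """Per-class top-k MeSH heading selection, fitted on training data only."""

    def __init__(self, mesh_per_class: int = 3) -> None:
        self.mesh_per_class = mesh_per_class
        self.per_class: dict[str, tuple[str, ...]] = {}
        self.selected: frozenset[str] = frozenset()
        self.fitted = False

    def fit(self, docs: Sequence[Document], labels: Sequence[str]) -> "MeshSelector":
        by_class: dict[str, dict[str, int]] = {}
        any_mesh = False
        for doc, label in zip(docs, labels):
            counts = by_class.setdefault(label, {})
            for heading in set(doc.mesh_headings):
                any_mesh = True
                counts[heading] = counts.get(heading, 0) + 1
        for label, counts in by_class.items():
            top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            self.per_class[label] = tuple(h for h, _ in top[: self.mesh_per_class])
        self.selected = frozenset(h for hs in self.per_class.values() for h in hs)
        self.fitted = True
        if not any_mesh:
            import logging

            logging.getLogger(__name__).warning(
                "MeshSelector: training corpus has no MeSH headings; "
                "MH features will be absent"
            )
        return self

    def transform(self, doc: Document) -> dict[str, float]:
        if not self.fitted:
            raise ValidationError("MeshSelector used before fitting")
        present = set(doc.mesh_headings) & self.selected
        return {f"mh:{h}": 1.0 for h in sorted(present)}


def title_features(
    doc: Document,
    organism_lexicon: OrganismLexicon,
    gene_lexicon: GeneLexicon | None = None,
) -> dict[str, float]:
    """DT: organism-in-title indicators (all labels, 0/1) + gene-in-title."""
    tokens = [t for s in tokenize(doc.title) for t in s.tokens]
    org_hits = {canonical for _, _, canonical in organism_lexicon.scan(tokens)}
    feats = {
        f"dt:org:{label}": (1.0 if label in org_hits else 0.0)
        for label in organism_lexicon.labels
    }
    if gene_lexicon is not None:
        for _, _, canonical in gene_lexicon.scan(tokens):
            feats[f"dt:gene:{canonical}"] = 1.0
    return feats


def co_sentence_pairs(
    gene_mentions: Sequence[Mention], organism_mentions: Sequence[Mention]
) -> list[tuple[Mention, Mention, int]]:
    """All (gene, organism) mention pairs sharing a sentence, with token distance."""
    by_sentence: dict[tuple[int, int], list[Mention]] = {}
    for m in organism_mentions:
        by_sentence.setdefault((m.section_index, m.sentence_index), []).append(m)
    pairs = []
    for g in gene_mentions:
        for s in by_sentence.get((g.section_index, g.sentence_index), ()):
            pairs.append((g, s, abs(g.token_index - s.token_index)))
    return pairs


def term_species_weights(
    gene_mentions: Sequence[Mention],
    organism_mentions: Sequence[Mention],
    config: FeatureConfig | None = None,
    labels: Sequence[str] | None = None,
) -> dict[str, float]:
    """TS: per-label total of distance-decayed gene–organism pair weights.

    Every co-sentence pair contributes ``decay(d)`` to the organism's label;
    pairs in different sentences contribute nothing.  Each contribution lies
    in (0, 1] and the totals are invariant to sentence order.
    """
    decay = DECAY_FUNCTIONS[(config or FeatureConfig()).ts_decay]
    totals: dict[str, float] = {label: 0.0 for label in (labels or ())}
    for _, s, d in co_sentence_pairs(gene_mentions, organism_mentions):
        totals[s.canonical] = totals.get(s.canonical, 0.0) + decay(d)
    return totals


def journal_feature(doc: Document) -> dict[str, str]:
    """JN: the journal name as a categorical feature (trimmed, case-folded)."""
    name = doc.journal.strip().casefold()
    return {"jn": name} if name else {}


def term_count_feature(
    doc: Document,
    gene_mentions: Sequence[Mention],
    corpus_gene_list: GeneList,
) -> dict[str, float]:
    """NT: number of distinct corpus-top-n genes occurring in the document."""
    present = {m.canonical for m in gene_mentions}
    return {"nt": float(len(present & corpus_gene_list.symbols))}


def additional_gene_names(
    pairs: Sequence[tuple[Mention, Mention, int]],
    synonym_table: Mapping[tuple[str, str], str],
) -> dict[str, float]:
    """AGN: counts of additional names found for co-sentence gene–species pairs."""
    feats: dict[str, float] = {}
    for g, s, _ in pairs:
        name = synonym_table.get((g.canonical, s.canonical))
        if name is not None:
            key = f"agn:{name}"
            feats[key] = feats.get(key, 0.0) + 1.0
    return feats


# ---------------------------------------------------------------------------
# assembly


class FeatureExtractor:
    """Fits the training-data-dependent selectors and assembles vectors.

    The MeSH selector (MH) and the corpus gene list (NT) are fitted on
    training documents only, so cross-validation refits them inside each
    training fold and no information leaks from test folds.
    """

    def __init__(
        self,
        config: FeatureConfig,
        organism_lexicon: OrganismLexicon,
        gene_lexicon: GeneLexicon | None = None,
        synonym_table: Mapping[tuple[str, str], str] | None = None,
    ) -> None:
        self.config = config
        self.organism_lexicon = organism_lexicon
        self.gene_lexicon = gene_lexicon
        self.synonym_table = synonym_table or {}
        self.mesh_selector: MeshSelector | None = None
        self.corpus_gene_list: GeneList | None = None

    def fit(
        self, tagged_docs: Sequence[TaggedDocument], labels: Sequence[str]
    ) -> "FeatureExtractor":
        if "MH" in self.config.enabled:
            self.mesh_selector = MeshSelector(self.config.mesh_per_class).fit(
                [t.doc for t in tagged_docs], labels
            )
        if "NT" in self.config.enabled:
            all_mentions = [m for t in tagged_docs for m in t.gene_mentions]
            self.corpus_gene_list = rank_genes(
                all_mentions, n_cap=self.config.n_top_genes
            )
        return self

    def transform(self, tagged: TaggedDocument) -> FeatureVector:
        cfg, doc = self.config, tagged.doc
        feats: dict[str, float | str] = {}
        if "GN" in cfg.enabled:
            feats.update(gene_name_features(doc, tagged.gene_mentions, cfg))
        if "OF" in cfg.enabled:
            feats.update(
                organism_frequency(
                    doc, tagged.organism_mentions, self.organism_lexicon.labels
                )
            )
        if "MH" in cfg.enabled:
            if self.mesh_selector is None:
                raise ValidationError("MH enabled but extractor not fitted")
            feats.update(self.mesh_selector.transform(doc))
        if "DT" in cfg.enabled:
            feats.update(title_features(doc, self.organism_lexicon, self.gene_lexicon))
        pairs = None
        if "TS" in cfg.enabled:
            weights = term_species_weights(
                tagged.gene_mentions,
                tagged.organism_mentions,
                cfg,
                labels=self.organism_lexicon.labels,
            )
            feats.update({f"ts:{label}": w for label, w in weights.items()})
        if "JN" in cfg.enabled:
            feats.update(journal_feature(doc))
        if "NT" in cfg.enabled:
            if self.corpus_gene_list is None:
                raise ValidationError("NT enabled but extractor not fitted")
            feats.update(
                term_count_feature(doc, tagged.gene_mentions, self.corpus_gene_list)
            )
        if "AGN" in cfg.enabled:
            pairs = co_sentence_pairs(tagged.gene_mentions, tagged.organism_mentions)
            feats.update(additional_gene_names(pairs, self.synonym_table))
        return FeatureVector(doc_id=doc.doc_id, features=feats, config=cfg)


def assemble_features(
    tagged: TaggedDocument,
    config: FeatureConfig,
    organism_lexicon: OrganismLexicon,
    gene_lexicon: GeneLexicon | None = None,
    trained: FeatureExtractor | None = None,
    synonym_table: Mapping[tuple[str, str], str] | None = None,
) -> FeatureVector:
    """Assemble one vector; requires a fitted extractor when MH/NT are enabled."""
    needs_fit = {"MH", "NT"} & set(config.enabled)
    if needs_fit and trained is None:
        raise ValidationError(
            f"features {sorted(needs_fit)} require a fitted FeatureExtractor"
        )
    if trained is not None:
        return trained.transform(tagged)
    extractor = FeatureExtractor(
        config, organism_lexicon, gene_lexicon, synonym_table
    )
    return extractor.transform(tagged)


def section_vectors(
    tagged: TaggedDocument, extractor: FeatureExtractor
) -> list[FeatureVector]:
    """Per-section feature vectors, for the section-sequence classifier."""
    out = []
    for si, section in enumerate(tagged.doc.sections):
        sub_doc = tagged.doc.with_sections([section])
        genes = tuple(
            replace_section(m) for m in tagged.gene_mentions if m.section_index == si
        )
        orgs = tuple(
            replace_section(m)
            for m in tagged.organism_mentions
            if m.section_index == si
        )
        out.append(
            extractor.transform(
                TaggedDocument(doc=sub_doc, gene_mentions=genes, organism_mentions=orgs)
            )
        )
    return out


def replace_section(m: Mention) -> Mention:
    from dataclasses import replace as _replace

    return _replace(m, section_index=0)
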