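"""Lexicon-driven gene and organism mention tagging.

The original workflow used a trained gene tagger (AbGene) for gene names;
here a deterministic lexicon/pattern tagger provides the same interface, so
tagging itself is noise-free and reproducible.  Tagger noise at realistic
levels is instead injected downstream by
:func:`orgfocus.synthetic_corpus.corrupt_gene_tags`, which keeps the two
concerns separable in experiments.

Matching conventions: organism matching is case-insensitive with
longest-match over token n-grams (so "Drosophila melanogaster" is one
mention and never also a nested "Drosophila" mention); gene matching is
case-sensitive because gene symbol case is semantic ("Copg1" vs "COPG1").
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import Document, ValidationError, tokenize

#: Symbol-like token: letters + at least one digit, 2-12 chars (e.g. "IL2").
_SYMBOL_RE = re.compile(r"^(?=.*\d)(?=.*[A-Za-z])[A-Za-z][A-Za-z0-9-]{1,11}$")

_SURFACE_TOKEN_RE = re.compile(r"[^\s]+")


def _surface_tokens(surface: str) -> tuple[str, ...]:
    # Lexicon surfaces are tokenized like document text so n-gram keys line
    # up with Sentence.tokens ("D. melanogaster" -> ("D", "melanogaster")).
    sentences = tokenize(surface)
    if sentences:
        return tuple(t for s in sentences for t in s.tokens)
    return tuple(_SURFACE_TOKEN_RE.findall(surface))


@dataclass(frozen=True)
class Mention:
    """A tagged span addressed by (section, sentence, first-token) indices."""

    surface: str
    canonical: str
    kind: str  # "gene" | "organism"
    section_index: int
    sentence_index: int
    token_index: int

    @property
    def coords(self) -> tuple[int, int, int]:
        return (self.section_index, self.sentence_index, self.token_index)


class _Lexicon:
    """Shared n-gram index over surface forms."""

    case_sensitive = True

    def __init__(self, entries: Mapping[str, str], provenance: str = "") -> None:
        self.entries = dict(entries)
        self.provenance = provenance
        self._index: dict[tuple[str, ...], str] = {}
        self.max_ngram = 0
        for surface, canonical in self.entries.items():
            if not surface:
                raise ValidationError("empty surface form in lexicon")
            if not canonical:
                raise ValidationError(f"empty canonical form for {surface!r}")
            key = _surface_tokens(surface if self.case_sensitive else surface.casefold())
            if not self.case_sensitive:
                key = tuple(t.casefold() for t in key)
            if not key:
                raise ValidationError(f"untokenizable surface form {surface!r}")
            existing = self._index.get(key)
            if existing is not None and existing != canonical:
                raise ValidationError(
                    f"conflicting canonicals for surface {surface!r}: "
                    f"{existing!r} vs {canonical!r}"
                )
            self._index[key] = canonical
            self.max_ngram = max(self.max_ngram, len(key))

    def __len__(self) -> int:
        return len(self._index)

    def scan(self, tokens: Sequence[str]) -> list[tuple[int, int, str]]:
        """Longest-match scan; returns (start, length, canonical) triples."""
        keys = tokens if self.case_sensitive else [t.casefold() for t in tokens]
        out, i, n = [], 0, len(tokens)
        while i < n:
            matched = False
            for length in range(min(self.max_ngram, n - i), 0, -1):
                canonical = self._index.get(tuple(keys[i : i + length]))
                if canonical is not None:
                    out.append((i, length, canonical))
                    i += length
                    matched = True
                    break
            if not matched:
                i += 1
        return out


class GeneLexicon(_Lexicon):
    """Surface form → canonical gene symbol; case-sensitive."""

    case_sensitive = True


class OrganismLexicon(_Lexicon):
    """Surface form → organism label; case-insensitive, synonym sets per class."""

    case_sensitive = False

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.entries.values())))


def load_lexicon(path: str | Path, kind: str) -> GeneLexicon | OrganismLexicon:
    """Load a 2-column tab-separated lexicon (``surface<TAB>canonical``).

    ``#`` comment lines and blank lines are ignored.  A malformed line or a
    surface mapped to two different canonicals raises
    :class:`ValidationError` naming the line.
    """
    if kind not in ("gene", "organism"):
        raise ValidationError(f"unknown lexicon kind: {kind!r}")
    path = Path(path)
    entries: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValidationError(f"{path}:{lineno}: malformed lexicon line {line!r}")
            surface, canonical = parts[0].strip(), parts[1].strip()
            if surface in entries and entries[surface] != canonical:
                raise ValidationError(
                    f"{path}:{lineno}: surface {surface!r} maps to both "
                    f"{entries[surface]!r} and {canonical!r}"
                )
            entries[surface] = canonical
    cls = GeneLexicon if kind == "gene" else OrganismLexicon
    return cls(entries, provenance=str(path))


def default_organism_lexicon() -> OrganismLexicon:
    """The shipped fly/mouse/yeast lexicon with common synonyms."""
    ref = resources.files("orgfocus.data").joinpath("organism_lexicon.tsv")
    with resources.as_file(ref) as p:
        lex = load_lexicon(p, "organism")
    assert isinstance(lex, OrganismLexicon)
    return lex


def load_synonym_table(path: str | Path) -> dict[tuple[str, str], str]:
    """Load a 3-column ``gene<TAB>organism<TAB>additional_name`` table."""
    table: dict[tuple[str, str], str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: malformed synonym line {line!r}")
            table[(parts[0].strip(), parts[1].strip())] = parts[2].strip()
    return table


def default_synonym_table() -> dict[tuple[str, str], str]:
    """Shipped local (gene, organism) → additional-name table."""
    ref = resources.files("orgfocus.data").joinpath("gene_synonyms.tsv")
    with resources.as_file(ref) as p:
        return load_synonym_table(p)


def _tag(doc: Document, lexicon: _Lexicon, kind: str) -> list[Mention]:
    mentions: list[Mention] = []
    for si, section in enumerate(doc.sections):
        for sei, sentence in enumerate(section.sentences):
            for start, length, canonical in lexicon.scan(sentence.tokens):
                mentions.append(
                    Mention(
                        surface=" ".join(sentence.tokens[start : start + length]),
                        canonical=canonical,
                        kind=kind,
                        section_index=si,
                        sentence_index=sei,
                        token_index=start,
                    )
                )
    return mentions


def tag_organism_mentions(doc: Document, lexicon: OrganismLexicon) -> list[Mention]:
    """All organism mentions in document order (longest-match, case-insensitive)."""
    return _tag(doc, lexicon, "organism")


def tag_gene_mentions(
    doc: Document, lexicon: GeneLexicon | None = None, pattern_rule: bool = False
) -> list[Mention]:
    """Gene mentions by exact (case-sensitive) lexicon match.

    With ``pattern_rule=True``, tokens that look like gene symbols (letters
    mixed with digits, e.g. "IL2") and are not already covered by a lexicon
    match are additionally tagged, canonicalized to their surface form.
    """
    mentions = _tag(doc, lexicon, "gene") if lexicon is not None else []
    if pattern_rule:
        covered = {
            (m.section_index, m.sentence_index, m.token_index + k)
            for m in mentions
            for k in range(len(m.surface.split()))
        }
        for si, section in enumerate(doc.sections):
            for sei, sentence in enumerate(section.sentences):
                for ti, token in enumerate(sentence.tokens):
                    if (si, sei, ti) in covered:
                        continue
                    if _SYMBOL_RE.match(token):
                        mentions.append(
                            Mention(token, token, "gene", si, sei, ti)
                        )
        mentions.sort(key=lambda m: m.coords)
    return mentions


@dataclass(frozen=True)
class GeneList:
    """Frequency-ranked gene symbols, capped at ``n_cap`` (default 100)."""

    ranked: tuple[tuple[str, int], ...]
    n_cap: int = 100

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(sym for sym, _ in self.ranked)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def rank_genes(mentions: Iterable[Mention], n_cap: int = 100) -> GeneList:
    """Rank gene mentions by frequency (ties broken lexicographically)."""
    if n_cap < 1:
        raise ValidationError("n_cap must be positive")
    counts = Counter()
    for m in mentions:
        if m.kind != "gene":
            raise ValidationError("rank_genes expects gene-kind mentions")
        counts[m.canonical] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n_cap]
    return GeneList(ranked=tuple(ranked), n_cap=n_cap)


@dataclass(frozen=True)
class TaggedDocument:
    """A document together with its gene and organism mentions."""

    doc: Document
    gene_mentions: tuple[Mention, ...]
    organism_mentions: tuple[Mention, ...]


def tag_document(
    doc: Document,
    organism_lexicon: OrganismLexicon,
    gene_lexicon: GeneLexicon | None = None,
    pattern_rule: bool = False,
) -> TaggedDocument:
    """Run both taggers over a document."""
    return TaggedDocument(
        doc=doc,
        gene_mentions=tuple(tag_gene_mentions(doc, gene_lexicon, pattern_rule)),
        organism_mentions=tuple(tag_organism_mentions(doc, organism_lexicon)),
    )
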