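"""Document model, cleaning, section segmentation, tokenization and corpus I/O.

The classification pipeline operates on articles reduced to a uniform
structure: an identifier, a title, the journal name, the MeSH headings
attached to the Medline record, and an ordered list of typed sections, each
holding tokenized sentences.  Abstracts are simply documents whose only
section is of kind ``abstract``, so the same machinery serves both
abstract-level and full-text classification.

Two on-disk formats are supported:

``records``
    One JSON object per line (UTF-8).  Sections store their sentences as
    token lists so that a corpus round-trips field-for-field, including the
    tokenization and the heading → kind assignment.

``plaintext_dir``
    One ``.txt`` file per document; the first line is the title, the
    filename stem is the document id, and the body is segmented by
    recognized section headings.  This format is lossy with respect to
    tokenization details and exists for ingesting raw text.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Canonical section kinds, in the order journals conventionally use them.
SECTION_KINDS = (
    "abstract",
    "introduction",
    "methods",
    "results",
    "discussion",
    "conclusion",
    "other",
)

#: Distinguished triage outcome; never a valid gold label.
UNDECIDED = "undecided"

#: Default label set: the three model organisms the pipeline targets
#: (fly = Drosophila melanogaster, mouse = Mus musculus,
#: yeast = Saccharomyces cerevisiae).
DEFAULT_LABELS = ("fly", "mouse", "yeast")


class ValidationError(ValueError):
    """An input violated a documented contract."""


# Heading → canonical kind, matched case-insensitively after stripping
# numbering and punctuation.  Journals differ in section naming; this table
# covers the common variants and is the single place to extend.
_HEADING_SYNONYMS = {
    "abstract": "abstract",
    "summary": "abstract",
    "introduction": "introduction",
    "background": "introduction",
    "methods": "methods",
    "method": "methods",
    "materials and methods": "methods",
    "material and methods": "methods",
    "experimental procedures": "methods",
    "experiment": "methods",
    "experiments": "methods",
    "results": "results",
    "result": "results",
    "results and discussion": "results",
    "findings": "results",
    "discussion": "discussion",
    "conclusion": "conclusion",
    "conclusions": "conclusion",
    "concluding remarks": "conclusion",
}

#: Abbreviations that never terminate a sentence (casefolded comparison).
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "e.g.",
        "i.e.",
        "et al.",
        "cf.",
        "vs.",
        "ca.",
        "approx.",
        "fig.",
        "figs.",
        "ref.",
        "refs.",
        "no.",
        "sp.",
        "spp.",
    }
)

# A token starts and ends with an alphanumeric character; hyphens,
# apostrophes, slashes, underscores and dots are kept inside tokens so gene
# symbols ("Copg1", "IL-2", "3.5") survive as single tokens.
_TOKEN_RE = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9'_\-./]*[A-Za-z0-9])?")
_TERMINAL_RE = re.compile(r"[.!?]+")
# A single capital followed by "." is treated as an initial, not a boundary.
_INITIAL_RE = re.compile(r"(?:^|[\s(\[])[A-Z]\.$")
_CONTROL_RE = re.compile(r"[\x00-\x08\x0b\x0c\x0e-\x1f\x7f]")


@dataclass(frozen=True)
class Sentence:
    """An ordered token sequence with its start offset in the section text."""

    tokens: tuple[str, ...]
    char_offset: int = 0


@dataclass(frozen=True)
class Section:
    heading: str
    kind: str
    sentences: tuple[Sentence, ...]

    def __post_init__(self) -> None:
        if self.kind not in SECTION_KINDS:
            raise ValidationError(f"unknown section kind: {self.kind!r}")

    @property
    def text(self) -> str:
        return " ".join(" ".join(s.tokens) for s in self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s.tokens) for s in self.sentences)


@dataclass(frozen=True)
class Document:
    doc_id: str
    title: str
    journal: str = ""
    mesh_headings: tuple[str, ...] = ()
    sections: tuple[Section, ...] = ()
    gold_label: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("doc_id must be non-empty")
        if self.gold_label == UNDECIDED:
            raise ValidationError("'undecided' is not a valid gold label")

    @property
    def n_tokens(self) -> int:
        return sum(s.n_tokens for s in self.sections)

    def with_sections(self, sections: Iterable[Section]) -> "Document":
        return replace(self, sections=tuple(sections))


def normalize_text(text: str) -> str:
    """Collapse whitespace runs and drop control characters."""
    text = _CONTROL_RE.sub(" ", text)
    return re.sub(r"\s+", " ", text).strip()


def normalize_heading(line: str) -> str | None:
    """Map a candidate heading line to a canonical section kind.

    Returns ``None`` when the line is not a recognizable heading.  Matching
    is case-insensitive after stripping leading numbering ("1.", "IV)") and
    trailing punctuation.
    """
    stripped = line.strip()
    if not stripped or len(stripped) > 60:
        return None
    stripped = re.sub(r"^[0-9IVXivx]+[.)]?\s+", "", stripped)
    stripped = stripped.strip(" :;.-")
    key = re.sub(r"\s+", " ", stripped).casefold()
    return _HEADING_SYNONYMS.get(key)


def _sentence_spans(
    text: str, abbreviations: frozenset[str]
) -> list[tuple[int, int]]:
    guards = tuple(g.casefold() for g in abbreviations)
    bounds: list[int] = []
    for m in _TERMINAL_RE.finditer(text):
        end = m.end()
        rest = text[end:]
        # Split only at end of text or before whitespace + capital/digit.
        if rest and not re.match(r"\s+[\"'(\[]?[A-Z0-9]", rest):
            continue
        head = text[:end]
        if head.casefold().endswith(guards):
            continue
        if _INITIAL_RE.search(head):
            continue
        bounds.append(end)
    if not bounds or bounds[-1] < len(text):
        bounds.append(len(text))
    spans, start = [], 0
    for b in bounds:
        if text[start:b].strip():
            spans.append((start, b))
        start = b
    return spans


def tokenize(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> tuple[Sentence, ...]:
    """Split text into sentences of word tokens.

    Deterministic and rule-based: sentences end at terminal punctuation
    followed by a capital/digit, guarded by an abbreviation list and a
    single-initial rule; tokens are maximal alphanumeric runs with internal
    hyphens/digits/dots preserved (so "Copg1" and "IL-2" stay single
    tokens).  Empty text yields an empty sequence.
    """
    sentences = []
    for start, end in _sentence_spans(text, abbreviations):
        seg = text[start:end]
        tokens = tuple(m.group(0) for m in _TOKEN_RE.finditer(seg))
        if tokens:
            offset = start + (len(seg) - len(seg.lstrip()))
            sentences.append(Sentence(tokens=tokens, char_offset=offset))
    return tuple(sentences)


def normalize_document(
    raw_title: str,
    raw_body: str = "",
    metadata: Mapping[str, object] | None = None,
) -> Document:
    """Clean raw text into a :class:`Document` with typed sections.

    Lines matching the heading table start a new section; body text with no
    recognizable headings becomes a single section of kind ``other``.
    Raises :class:`ValidationError` when both title and body are empty.
    """
    meta = dict(metadata or {})
    title = normalize_text(raw_title)
    blocks: list[tuple[str, str, list[str]]] = []  # (heading, kind, lines)
    for line in raw_body.splitlines():
        kind = normalize_heading(line)
        if kind is not None:
            blocks.append((line.strip(), kind, []))
        else:
            if not blocks:
                blocks.append(("", "other", []))
            blocks[-1][2].append(line)
    sections = []
    for heading, kind, lines in blocks:
        text = normalize_text(" ".join(lines))
        if not text:
            continue
        sections.append(Section(heading=heading, kind=kind, sentences=tokenize(text)))
    if not title and not sections:
        raise ValidationError("document has neither title nor body text")
    return Document(
        doc_id=str(meta.get("doc_id", "doc")),
        title=title,
        journal=normalize_text(str(meta.get("journal", ""))),
        mesh_headings=tuple(meta.get("mesh", ()) or ()),
        sections=tuple(sections),
        gold_label=meta.get("label"),  # type: ignore[arg-type]
    )


def _sentences_from_token_lists(token_lists: Sequence[Sequence[str]]) -> tuple[Sentence, ...]:
    sentences, offset = [], 0
    for toks in token_lists:
        toks = tuple(str(t) for t in toks)
        if not toks:
            continue
        sentences.append(Sentence(tokens=toks, char_offset=offset))
        offset += len(" ".join(toks)) + 1
    return tuple(sentences)


def _doc_from_record(rec: Mapping[str, object]) -> tuple[Document, int]:
    warnings = 0
    if "title" not in rec:
        warnings += 1
    sections = []
    for sec in rec.get("sections", ()) or ():  # type: ignore[union-attr]
        heading = str(sec.get("heading", ""))
        kind = sec.get("kind") or normalize_heading(heading) or "other"
        if "sentences" in sec:
            sentences = _sentences_from_token_lists(sec["sentences"])
        else:
            sentences = tokenize(normalize_text(str(sec.get("text", ""))))
        sections.append(Section(heading=heading, kind=str(kind), sentences=sentences))
    doc = Document(
        doc_id=str(rec.get("doc_id", "")),
        title=str(rec.get("title", "")),
        journal=str(rec.get("journal", "")),
        mesh_headings=tuple(str(m) for m in (rec.get("mesh", ()) or ())),
        sections=tuple(sections),
        gold_label=rec.get("label"),  # type: ignore[arg-type]
    )
    return doc, warnings


def _record_from_doc(doc: Document) -> dict:
    rec: dict = {
        "doc_id": doc.doc_id,
        "title": doc.title,
        "journal": doc.journal,
        "mesh": list(doc.mesh_headings),
        "sections": [
            {
                "heading": s.heading,
                "kind": s.kind,
                "sentences": [list(sent.tokens) for sent in s.sentences],
            }
            for s in doc.sections
        ],
    }
    if doc.gold_label is not None:
        rec["label"] = doc.gold_label
    return rec


def read_corpus(path: str | Path, format_name: str = "records") -> list[Document]:
    """Read a corpus; unparseable records are skipped (and counted in a log).

    Raises ``FileNotFoundError`` for a missing path and
    :class:`ValidationError` on duplicate document ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    docs: list[Document] = []
    skipped = warnings = 0
    if format_name == "records":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    doc, w = _doc_from_record(rec)
                except (json.JSONDecodeError, ValidationError, AttributeError, TypeError) as exc:
                    skipped += 1
                    logger.warning("skipping unparseable record at line %d: %s", lineno, exc)
                    continue
                warnings += w
                docs.append(doc)
    elif format_name == "plaintext_dir":
        if not path.is_dir():
            raise ValidationError(f"plaintext_dir expects a directory: {path}")
        for txt in sorted(path.glob("*.txt")):
            raw = txt.read_text(encoding="utf-8")
            first, _, body = raw.partition("\n")
            try:
                docs.append(
                    normalize_document(first, body, metadata={"doc_id": txt.stem})
                )
            except ValidationError as exc:
                skipped += 1
                logger.warning("skipping %s: %s", txt.name, exc)
    else:
        raise ValidationError(f"unknown corpus format: {format_name!r}")
    if skipped or warnings:
        logger.warning(
            "read_corpus: %d records skipped, %d field warnings", skipped, warnings
        )
    seen: set[str] = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise ValidationError(f"duplicate doc_id: {doc.doc_id!r}")
        seen.add(doc.doc_id)
    return docs


def write_corpus(
    docs: Sequence[Document], path: str | Path, format_name: str = "records"
) -> int:
    """Write a corpus; returns the number of records written.

    ``read_corpus(write_corpus(docs))`` reproduces ``docs`` field-for-field
    in the ``records`` format.
    """
    path = Path(path)
    if format_name == "records":
        with path.open("w", encoding="utf-8") as fh:
            for doc in docs:
                fh.write(json.dumps(_record_from_doc(doc), ensure_ascii=False) + "\n")
    elif format_name == "plaintext_dir":
        path.mkdir(parents=True, exist_ok=True)
        for doc in docs:
            lines = [doc.title]
            for s in doc.sections:
                lines.append("")
                lines.append(s.heading or s.kind.upper())
                lines.append(s.text)
            (path / f"{doc.doc_id}.txt").write_text(
                "\n".join(lines) + "\n", encoding="utf-8"
            )
    else:
        raise ValidationError(f"unknown corpus format: {format_name!r}")
    return len(docs)
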