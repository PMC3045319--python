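import pytest

from orgfocus.corpus_io import Document, Section, Sentence
from orgfocus.taggers import GeneLexicon, default_organism_lexicon


def make_doc(
    doc_id="d1",
    title="Untitled",
    sentences=None,
    kind="abstract",
    sections=None,
    **kwargs,
):
    """Build a document from token-list sentences (one section by default)."""
    if sections is None:
        sentence_objs, offset = [], 0
        for toks in sentences or []:
            sentence_objs.append(Sentence(tokens=tuple(toks), char_offset=offset))
            offset += len(" ".join(toks)) + 1
        sections = [Section(heading="", kind=kind, sentences=tuple(sentence_objs))]
    return Document(doc_id=doc_id, title=title, sections=tuple(sections), **kwargs)


@pytest.fixture(scope="session")
def organism_lexicon():
    return default_organism_lexicon()


@pytest.fixture(scope="session")
def gene_lexicon():
    return GeneLexicon({"Copg1": "Copg1", "Adh": "Adh", "CDC28": "CDC28", "IL2": "IL2"})


@pytest.fixture
def multi_species_doc(request):
    """Condensed multi-species abstract: fly and mouse mentioned, plus
    out-of-label-set species (zebrafish, Bombyx mori) that must be ignored."""
    return make_doc(
        doc_id="pmid-multi",
        title="Characterization of Copg genes encoding gamma-COP",
        sentences=[
            "We characterized cDNAs for Copg genes from mouse zebrafish "
            "Drosophila melanogaster and Bombyx mori".split(),
            "Mouse Copg1 showed ubiquitous expression with the highest "
            "level in testis".split(),
            "Zebrafish copg2 was biallelically expressed in hybrid larvae".split(),
        ],
    )
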