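import pytest
from hypothesis import given, settings, strategies as st

from orgfocus.corpus_io import ValidationError
from orgfocus.features import (
    FeatureConfig,
    FeatureExtractor,
    additional_gene_names,
    assemble_features,
    co_sentence_pairs,
    gene_name_features,
    journal_feature,
    organism_frequency,
    term_count_feature,
    term_species_weights,
    title_features,
)
from orgfocus.taggers import (
    GeneList,
    Mention,
    TaggedDocument,
    default_synonym_table,
    tag_document,
)
from conftest import make_doc


def gene(symbol, sentence=0, token=0, section=0):
    return Mention(symbol, symbol, "gene", section, sentence, token)


def org(label, sentence=0, token=0, section=0):
    return Mention(label, label, "organism", section, sentence, token)


class TestFeatureConfig:
    def test_f1_expansion(self):
        cfg = FeatureConfig.from_name("F1")
        assert cfg.enabled == frozenset({"GN", "MH", "JN", "DT"})

    def test_full_and_aliases(self):
        assert FeatureConfig.from_name("full").enabled == frozenset(
            {"GN", "OF", "MH", "DT", "TS", "JN", "NT", "AGN"}
        )
        assert "AGN" in FeatureConfig.from_name("F1+ADN").enabled
        assert "AGN" in FeatureConfig.from_name("F1+AND").enabled

    def test_unknown_component_rejected(self):
        with pytest.raises(ValidationError):
            FeatureConfig.from_name("F1+XX")


class TestGeneNameFeatures:
    def test_counts(self):
        doc = make_doc()
        mentions = [gene("A", token=i) for i in range(3)] + [gene("B", token=5)]
        feats = gene_name_features(doc, mentions, FeatureConfig())
        assert feats == {"gn:A": 3.0, "gn:B": 1.0}

    def test_no_genes(self):
        assert gene_name_features(make_doc(), [], FeatureConfig()) == {}

    def test_cap(self):
        mentions = [gene(f"g{i:03d}", token=i) for i in range(150)]
        feats = gene_name_features(make_doc(), mentions, FeatureConfig())
        assert len(feats) == 100


class TestOrganismFrequency:
    def test_multi_species_doc_counts(self, multi_species_doc, organism_lexicon):
        tagged = tag_document(multi_species_doc, organism_lexicon)
        feats = organism_frequency(
            multi_species_doc, tagged.organism_mentions, organism_lexicon.labels
        )
        assert feats == {"of:fly": 1.0, "of:mouse": 2.0, "of:yeast": 0.0}

    def test_empty_doc_all_zero(self):
        feats = organism_frequency(make_doc(), [], ("fly", "mouse", "yeast"))
        assert set(feats.values()) == {0.0}

    def test_repeated_mentions(self):
        mentions = [org("mouse", token=i) for i in range(3)]
        feats = organism_frequency(make_doc(), mentions, ("fly", "mouse"))
        assert feats["of:mouse"] == 3.0


class TestMeshSelection:
    def _tagged(self, doc):
        return TaggedDocument(doc=doc, gene_mentions=(), organism_mentions=())

    def test_planted_headings_recovered(self):
        docs, labels = [], []
        for i in range(10):
            docs.append(
                make_doc(f"f{i}", mesh_headings=("Drosophila", f"noise-{i}"))
            )
            labels.append("fly")
            docs.append(make_doc(f"m{i}", mesh_headings=("Mice", f"other-{i}")))
            labels.append("mouse")
        cfg = FeatureConfig(enabled=frozenset({"MH"}), mesh_per_class=1)
        extractor = FeatureExtractor(cfg, organism_lexicon=_dummy_lex()).fit(
            [self._tagged(d) for d in docs], labels
        )
        assert extractor.mesh_selector.per_class["fly"] == ("Drosophila",)
        assert extractor.mesh_selector.per_class["mouse"] == ("Mice",)

    def test_exactly_k_per_class_with_tie_break(self):
        docs = [
            make_doc(f"d{i}", mesh_headings=("b", "a", "c", "d", "e"))
            for i in range(4)
        ]
        cfg = FeatureConfig(enabled=frozenset({"MH"}), mesh_per_class=3)
        # two classes so training is well-posed
        labels = ["fly", "fly", "mouse", "mouse"]
        extractor = FeatureExtractor(cfg, organism_lexicon=_dummy_lex()).fit(
            [self._tagged(d) for d in docs], labels
        )
        # all 5 headings tie on frequency; lexicographic break picks a,b,c
        assert extractor.mesh_selector.per_class["fly"] == ("a", "b", "c")


def _dummy_lex():
    from orgfocus.taggers import OrganismLexicon

    return OrganismLexicon({"fly": "fly", "mouse": "mouse", "yeast": "yeast"})


class TestTitleFeatures:
    def test_organism_and_gene_indicators(self, organism_lexicon, gene_lexicon):
        doc = make_doc(title="Drosophila Copg1 study")
        feats = title_features(doc, organism_lexicon, gene_lexicon)
        assert feats["dt:org:fly"] == 1.0
        assert feats["dt:org:mouse"] == 0.0
        assert feats["dt:gene:Copg1"] == 1.0

    def test_organism_free_title_all_zero(self, organism_lexicon):
        feats = title_features(make_doc(title="Coatomer subunit genes"), organism_lexicon)
        assert all(v == 0.0 for k, v in feats.items() if k.startswith("dt:org:"))

    def test_two_organisms_both_set(self, organism_lexicon):
        doc = make_doc(title="Comparing mouse and drosophila orthologs")
        feats = title_features(doc, organism_lexicon)
        assert feats["dt:org:fly"] == feats["dt:org:mouse"] == 1.0


class TestTermSpecies:
    def test_single_pair_inverse_distance(self):
        weights = term_species_weights([gene("A", token=2)], [org("mouse", token=5)])
        assert weights["mouse"] == pytest.approx(0.25)  # 1/(1+3)

    def test_cross_sentence_pairs_contribute_nothing(self):
        weights = term_species_weights(
            [gene("A", sentence=0)], [org("mouse", sentence=1)]
        )
        assert weights.get("mouse", 0.0) == 0.0

    def test_sum_over_pairs(self):
        genes = [gene("A", token=0), gene("B", sentence=1, token=0)]
        orgs = [org("fly", token=1), org("fly", sentence=1, token=3)]
        weights = term_species_weights(genes, orgs)
        assert weights["fly"] == pytest.approx(0.5 + 0.25)

    def test_exponential_decay_option(self):
        import math

        cfg = FeatureConfig(enabled=frozenset({"TS"}), ts_decay="exponential")
        weights = term_species_weights([gene("A", token=0)], [org("fly", token=2)], cfg)
        assert weights["fly"] == pytest.approx(math.exp(-2))

    @given(st.integers(min_value=0, max_value=20), st.integers(min_value=0, max_value=20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_distance(self, d1, d2):
        """Moving the species farther from the gene never raises its weight."""
        w1 = term_species_weights([gene("A", token=0)], [org("fly", token=d1)])["fly"]
        w2 = term_species_weights([gene("A", token=0)], [org("fly", token=d2)])["fly"]
        if d1 <= d2:
            assert w1 >= w2

    def test_invariant_to_sentence_permutation(self):
        genes = [gene("A", sentence=0, token=1), gene("B", sentence=2, token=4)]
        orgs = [org("fly", sentence=0, token=3), org("mouse", sentence=2, token=0)]
        base = term_species_weights(genes, orgs)
        remap = {0: 2, 2: 0}
        permuted_g = [
            Mention(m.surface, m.canonical, m.kind, m.section_index,
                    remap.get(m.sentence_index, m.sentence_index), m.token_index)
            for m in genes
        ]
        permuted_o = [
            Mention(m.surface, m.canonical, m.kind, m.section_index,
                    remap.get(m.sentence_index, m.sentence_index), m.token_index)
            for m in orgs
        ]
        assert term_species_weights(permuted_g, permuted_o) == base


class TestJournalFeature:
    @pytest.mark.parametrize(
        "journal,expected",
        [("Genetics", {"jn": "genetics"}), ("  Genetics ", {"jn": "genetics"}), ("", {})],
    )
    def test_normalization(self, journal, expected):
        assert journal_feature(make_doc(journal=journal)) == expected


class TestTermCount:
    def test_distinct_hits(self):
        top = GeneList(ranked=tuple((f"g{i}", 10 - i) for i in range(10)), n_cap=100)
        mentions = [gene("g1"), gene("g1", token=3), gene("g5"), gene("zz")]
        feats = term_count_feature(make_doc(), mentions, top)
        assert feats == {"nt": 2.0}

    def test_no_hits(self):
        top = GeneList(ranked=(("a", 1),), n_cap=100)
        assert term_count_feature(make_doc(), [gene("zz")], top) == {"nt": 0.0}

    def test_union_of_disjoint_docs(self):
        top = GeneList(ranked=tuple((f"g{i}", 1) for i in range(10)), n_cap=100)
        part1 = [gene(f"g{i}") for i in range(3)]
        part2 = [gene(f"g{i}") for i in range(3, 7)]
        feats = term_count_feature(make_doc(), part1 + part2, top)
        assert feats == {"nt": 7.0}


class TestAdditionalGeneNames:
    def test_shipped_table_lookup(self):
        pairs = co_sentence_pairs([gene("IL2", token=0)], [org("mouse", token=2)])
        feats = additional_gene_names(pairs, default_synonym_table())
        assert feats == {"agn:Interleukin": 1.0}

    def test_empty_table(self):
        pairs = co_sentence_pairs([gene("IL2")], [org("mouse", token=1)])
        assert additional_gene_names(pairs, {}) == {}

    def test_repeated_pair_counted(self):
        pairs = co_sentence_pairs(
            [gene("IL2", sentence=0, token=0), gene("IL2", sentence=1, token=0)],
            [org("mouse", sentence=0, token=2), org("mouse", sentence=1, token=2)],
        )
        feats = additional_gene_names(pairs, default_synonym_table())
        assert feats == {"agn:Interleukin": 2.0}


class TestAssembly:
    def _tagged_fixture(self, organism_lexicon, gene_lexicon):
        doc = make_doc(
            title="Drosophila Copg1 study",
            journal="Genetics",
            mesh_headings=("Drosophila",),
            sentences=[["Adh", "regulates", "Drosophila", "development"]],
        )
        return tag_document(doc, organism_lexicon, gene_lexicon)

    def test_of_only_config(self, organism_lexicon, gene_lexicon):
        tagged = self._tagged_fixture(organism_lexicon, gene_lexicon)
        cfg = FeatureConfig(enabled=frozenset({"OF"}))
        vec = assemble_features(tagged, cfg, organism_lexicon, gene_lexicon)
        assert all(name.startswith("of:") for name in vec.features)

    def test_f1_excludes_ts_and_of(self, organism_lexicon, gene_lexicon):
        tagged = self._tagged_fixture(organism_lexicon, gene_lexicon)
        cfg = FeatureConfig.from_name("F1")
        extractor = FeatureExtractor(cfg, organism_lexicon, gene_lexicon).fit(
            [tagged, tagged], ["fly", "mouse"]
        )
        vec = extractor.transform(tagged)
        assert not any(n.startswith(("ts:", "of:")) for n in vec.features)

    def test_full_equals_union_of_families(self, organism_lexicon, gene_lexicon):
        tagged = self._tagged_fixture(organism_lexicon, gene_lexicon)
        full_cfg = FeatureConfig.from_name("full")
        table = default_synonym_table()
        extractor = FeatureExtractor(
            full_cfg, organism_lexicon, gene_lexicon, table
        ).fit([tagged, tagged], ["fly", "mouse"])
        combined = dict(extractor.transform(tagged).features)
        union = {}
        for family in ("GN", "OF", "MH", "DT", "TS", "JN", "NT", "AGN"):
            cfg = FeatureConfig(enabled=frozenset({family}))
            sub = FeatureExtractor(cfg, organism_lexicon, gene_lexicon, table).fit(
                [tagged, tagged], ["fly", "mouse"]
            )
            union.update(sub.transform(tagged).features)
        assert combined == union

    def test_ablation_restriction_property(self, organism_lexicon, gene_lexicon):
        """Removing a family removes exactly that family's features."""
        tagged = self._tagged_fixture(organism_lexicon, gene_lexicon)
        full = assemble_features(
            tagged,
            FeatureConfig(enabled=frozenset({"GN", "OF", "TS", "JN"})),
            organism_lexicon,
            gene_lexicon,
        ).features
        reduced = assemble_features(
            tagged,
            FeatureConfig(enabled=frozenset({"GN", "JN"})),
            organism_lexicon,
            gene_lexicon,
        ).features
        dropped = {n for n in full if n.startswith(("of:", "ts:"))}
        assert set(full) - set(reduced) == dropped
        assert all(full[n] == reduced[n] for n in reduced)

    def test_mh_without_fit_rejected(self, organism_lexicon, gene_lexicon):
        tagged = self._tagged_fixture(organism_lexicon, gene_lexicon)
        with pytest.raises(ValidationError):
            assemble_features(
                tagged, FeatureConfig.from_name("F1"), organism_lexicon, gene_lexicon
            )
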