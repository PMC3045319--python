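# orgfocus

Classifying biomedical articles by **focus organism** — the model species
an article's experiments primarily concern.  Organism databases (FlyBase,
MGD, SGD, …) are curated by experts who must first sort incoming
literature by species; `orgfocus` implements that triage step for
abstracts and full-text articles, targeting fly (*Drosophila
melanogaster*), mouse (*Mus musculus*) and yeast (*Saccharomyces
cerevisiae*) by default.

## What it does

The pipeline combines a cheap rule with a supervised classifier:

1. a **title rule** — a title mentioning exactly one distinct organism
   decides the document immediately (~5% of articles);
2. **content selection** — full texts are reduced to abstract +
   introduction + results + conclusion (for heading-less articles, by
   matching per-block gene-mention distributions against a reference);
3. lexicon **tagging** of gene and organism mentions;
4. eight **feature families** — gene counts (GN), organism frequency
   (OF), MeSH headings (MH), title mentions (DT), journal name (JN),
   top-gene-list hits (NT), additional gene names (AGN), and the
   **term-species score (TS)**: for every gene mention *g* and organism
   mention *s* in one sentence, the organism's label receives weight
   1/(1+d) with d the token distance, tallied over the article —
   ts(c) = Σ_{(g,s): label(s)=c} 1/(1+d(g,s));
5. a from-scratch **multinomial Naive Bayes** (add-α smoothing, separate
   categorical table for the journal), with **bagging** and
   **AdaBoost.M1** ensembles and a pluggable interface for external
   learners (SVM, CRF, …);
6. **evaluation**: one-vs-rest P/R/F, stratified k-fold CV, feature
   ablation grids, and runs × k repeated CV with the **corrected
   resampled t-test** (variance inflated by n_test/n_train to account for
   overlapping training sets).

A seeded synthetic-corpus generator reproduces the statistical structure
the pipeline assumes (per-class gene vocabularies with shared ambiguous
symbols, planted gene–species pairs, ~5% multi-species articles,
configurable tagger noise), so everything is testable without external
data.  See `docs/methods.md` for the full model description.

## Worked example

Generate an ambiguity-stressed corpus (gene vocabulary shared across
classes, so gene counts alone are weakly informative) and measure what
the term-species feature adds to the basic feature set
F1 = {GN, MH, JN, DT}:

```sh
orgfocus simulate --docs-per-class 40 --seed 3 --out amb --preset ambiguity
orgfocus evaluate --corpus amb/corpus.jsonl --features F1    --model nb --k 10 --seed 1
orgfocus evaluate --corpus amb/corpus.jsonl --features F1+TS --model nb --k 10 --seed 1
orgfocus compare  --corpus amb/corpus.jsonl --spec-a nb:F1+TS --spec-b nb:F1 \
                  --runs 10 --k 10 --seed 2
```

prints

```
model=nb features=F1 k=10 seed=1
  fly        P=0.795 R=0.875 F=0.833
  mouse      P=0.727 R=0.800 F=0.762
  yeast      P=0.781 R=0.625 F=0.694
  macro-F (fold mean) = 0.760

model=nb features=F1+TS k=10 seed=1
  fly        P=1.000 R=0.975 F=0.987
  mouse      P=1.000 R=1.000 F=1.000
  yeast      P=0.976 R=1.000 F=0.988
  macro-F (fold mean) = 0.992

spec A macro-F = 0.994
spec B macro-F = 0.737
mean paired difference (A-B) = +0.257
corrected resampled t = 6.154, two-tailed p = 1.61e-08
```

Reading: with the basic features the three classes are confused wherever
their (shared) gene vocabularies overlap (macro-F ≈ 0.76); adding the
distance-weighted gene–species pairing nearly resolves the ambiguity
(macro-F ≈ 0.99), and the paired 10×10-CV comparison shows the gain is
highly significant under the corrected resampled t-test.

Other commands: `orgfocus ablate` (model × feature-set grid on shared
folds), `orgfocus train` / `orgfocus classify` (fit and apply a
serialized model).  Library use mirrors the CLI:

```python
from orgfocus import GeneratorConfig, generate_corpus, gene_lexicon_for, k_fold_cv

cfg = GeneratorConfig(docs_per_class=100, seed=0)
docs, truth = generate_corpus(cfg)
result = k_fold_cv(docs, "nb", "full", k=10, seed=1,
                   gene_lexicon=gene_lexicon_for(cfg))
print(result.macro_f)
```

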