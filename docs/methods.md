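# Methods

## Task and model

`orgfocus` labels a biomedical article with its *focus organism* — the
single model species its experiments primarily concern (by default fly =
*Drosophila melanogaster*, mouse = *Mus musculus*, yeast =
*S. cerevisiae*).  The pipeline is:

1. **Normalization** — raw text is cleaned, section headings are mapped to
   canonical kinds (abstract / introduction / methods / results /
   discussion / conclusion / other) through a synonym table, and sentences
   are tokenized by a rule-based splitter.
2. **Title rule** — a title mentioning exactly one distinct organism
   decides the document immediately; those documents bypass the learner.
3. **Content selection** — full-text documents are reduced to abstract +
   introduction + results + conclusion.  Heading-less documents are split
   into 6 contiguous token blocks and the 4-block subset whose gene-mention
   distribution is most similar to a reference distribution is kept.
4. **Tagging** — lexicon-driven organism mentions (case-insensitive,
   longest n-gram match) and gene mentions (case-sensitive exact match,
   optional symbol-pattern rule).
5. **Features → learner** — eight feature families feed a multinomial
   Naive Bayes (or a bagging / AdaBoost.M1 ensemble of them).
6. **Evaluation** — one-vs-rest P/R/F per class, stratified k-fold CV,
   repeated (runs × k) CV with the corrected resampled t-test, and an
   ablation grid over feature sets and learners.

## The term-species (TS) feature

For every gene mention *g* and organism mention *s* occurring in the same
sentence, the organism's label receives weight

    w(g, s) = 1 / (1 + d),    d = |token index of g − token index of s|,

and the weights are tallied per label over the whole article.  Pairs in
different sentences contribute nothing.  The decay function is a design
choice: inverse distance is the simplest monotone function with w = 1 at
distance 0; an exponential decay `exp(-d)` is available via
`FeatureConfig(ts_decay="exponential")` for sensitivity runs.  All pairs in
a sentence contribute (not just the nearest), which preserves information
and keeps the statistic a simple sum.  TS is the feature that resolves
gene-symbol ambiguity across species: a shared symbol near "Drosophila"
votes fly, the same symbol near "mouse" votes mouse.

## Feature families and their defaults

| family | content | default knobs |
|--------|---------|---------------|
| GN | per-gene counts of the document's most frequent genes | top 100 |
| OF | raw organism mention count per label | — |
| MH | indicators for per-class top MeSH headings | 3 per class |
| DT | organism-in-title (0/1 per label) + gene-in-title indicators | — |
| TS | distance-weighted gene–species totals per label | 1/(1+d) decay |
| JN | journal name, categorical (trimmed, case-folded) | — |
| NT | count of corpus-top-100 genes present in the document | top 100 |
| AGN | additional gene names for co-sentence pairs, from a local table | shipped table |

The named sets `F1` = {GN, MH, JN, DT} (the basic set), `F1+TS`, `F1+OF`,
…, `full` are accepted everywhere; `ADN`/`AND` are treated as aliases of
`AGN`.  The MH selector and the NT gene list are fitted on training folds
only; refitting happens inside every CV fold so no test information leaks
into feature selection.  Counts are raw — no tf-idf or log scaling — which
keeps the multinomial likelihood interpretable.

The AGN lookup uses a local 3-column `(gene, organism) → additional name`
table shipped with the package instead of a live protein-database query,
so builds and tests are hermetic and deterministic; the table is
user-replaceable.

## Learners

*Naive Bayes.*  Multinomial event model over count features with
add-α smoothing (α = 1): `P(f|c) = (n_cf + α) / (N_c + α|V|)` with V the
training feature domain.  Categorical features (the journal name) get a
separate per-class conditional table with add-α over the observed value
domain — folding a categorical into counts would double-count evidence.
Prediction accumulates in log space; feature names or categorical values
unseen in training are ignored.  Weighted training (for boosting)
normalizes sample weights to mean 1 so the effective sample size — and
hence the relative strength of the smoothing — does not depend on the
weights' scale; uniform weights reproduce unweighted training exactly.

*Bagging.*  Bootstrap resamples of the training set (same size, with
replacement; a resample missing a class is redrawn, at most 100 times),
one NB per bag, equal weights, mean posterior at prediction.

*AdaBoost.M1.*  Weighted NB rounds; round error ε is the weight of
misclassified examples, member weight ln((1−ε)/ε), correct examples
down-weighted by ε/(1−ε).  ε = 0 stops with that member kept; ε ≥ 0.5
stops (the member is kept only if it is the first).  Prediction is a
weighted vote over member argmaxes, normalized to a distribution.

*Section aggregation.*  The two-stage idea — label sections, then the
document — is provided as `classify_by_sections`: the document label is
the argmax of the length-normalized, kind-weighted sum of per-section log
posteriors.  It needs no section-level gold labels.  A genuine sequence
model (CRF) or any other learner (SVM, trees, logistic regression) can be
attached through `register_learner(name, train_fn, predict_fn)` and then
used in every evaluation command; none of these is reimplemented here.

Argmax ties are broken by label sort order, deterministically.

## Evaluation machinery

Scoring is one-vs-rest per class (P = TP/(TP+FP), R = TP/(TP+FN),
F = 2PR/(P+R); zero denominators yield 0).  Cross-class summaries use the
macro-averaged F.  Folds are stratified (the corpora are near-balanced;
stratification mainly reduces fold variance).  Title-rule documents are
scored with their rule labels and excluded from learner training;
`score_rule_docs=False` excludes them from scoring as well, since either
reading of "evaluated documents" is defensible.

For comparing two configurations, repeated CV produces runs × k paired
per-fold macro-F differences on identical fold partitions, and the
corrected resampled t-test computes

    t = mean(d) / sqrt((1/J + n_test/n_train) · var(d)),

with J differences and unbiased variance, two-tailed p from Student-t with
J−1 degrees of freedom.  The n_test/n_train term inflates the variance to
account for overlapping training sets across folds; with it zeroed the
statistic reduces to the classic paired resampled t-test (a tested
identity).  Zero variance returns t = 0, p = 1 when the mean is zero and a
flagged degenerate (±inf, 0) otherwise.

## Synthetic corpora

The generator emits labelled pseudo-articles with the statistical
structure the pipeline assumes and nothing more — opaque tokens, no
linguistic realism, no real MeSH or journal vocabulary.  Defaults (the
study conditions):

* 300 documents per class, six-section structure, ~12-token sentences;
* per-class Zipf-ranked gene vocabularies (60 exclusive + 30 shared
  ambiguous symbols, exponent 1.1) — the shared pool creates the
  cross-species gene ambiguity TS is designed to resolve;
* organism mentions in 30% of signal sentences; 2 planted gene–species
  co-sentence pairs per document with controlled token distances;
* 5% multi-species articles (a second species mentioned in the body; the
  gold label stays single — multi-label classification is out of scope);
* 5% of titles name exactly the article's organism (the observed coverage
  of the title rule on real curation corpora);
* planted per-class MeSH headings (3, present with probability 0.9),
  per-class vs shared journal pools (fidelity 0.7);
* gene-tagger noise defaults fp = 0.27 / fn = 0.33 — the error regime
  reported for a trained gene tagger applied to full text (72.6%
  precision, 66.7% recall).  Noise is applied to tagged mentions by
  `corrupt_gene_tags`, not baked into the text, so the same corpus can be
  evaluated clean and noisy.

Two presets define stress regimes used by the tests and the acceptance
script.  `ambiguity_stressed` makes the gene vocabulary almost entirely
shared across classes and weakens MeSH/journal fidelity, so the basic
feature set is weakly informative and the TS pairs carry the signal: this
is the regime in which adding TS to the basic set yields a large,
significant macro-F gain.  `fulltext_advantage` confines class-signal
genes, organism mentions and planted pairs to body sections, so
abstract-only classification is close to uninformative while full-text
classification is nearly perfect — the directional full-text benefit.

Because the corpora are synthetic, passing tests demonstrate that the
*machinery* behaves as designed under controlled conditions (parameter
recovery, directional effects, oracle equality).  They do not certify
performance numbers on real literature, whose headline scores depend on an
external hand-collected corpus; real-corpus F-scores are deliberately not
reproduced here.

## Numerical and degenerate-input choices

* Posterior normalization via log-sum-exp; section-aggregation log
  posteriors floored at 1e-300 before log.
* Cosine similarity is undefined on zero vectors: a validation error for
  explicit distribution comparison; inside the content-selection window
  search, all-zero gene blocks fall back to the first four blocks.
* Empty documents, empty corpora, single-class training sets, classes
  smaller than k, and conflicting lexicon entries all raise
  `ValidationError` with context.
* Problem sizes in the test suite and acceptance script (300 docs/class
  for end-to-end recovery; 40/class for the 10×10 TS comparison; 60/class
  for the full-text comparison) are the package's declared study scales:
  large enough for stable binomial checks and significance, small enough
  that the whole suite runs in seconds.

## Known limitations

* The gene tagger is a lexicon matcher; statistical NER, abbreviation
  expansion and species disambiguation of gene symbols are out of scope.
* The shipped organism lexicon covers three species with common synonyms;
  other label sets require a user lexicon.
* Multi-species articles receive a single gold label; the generator marks
  them so they can be analysed, but multi-label output is not supported.
* The heading-less content-selection fallback assumes a roughly six-part
  document; articles with many more sections than the canonical structure
  are handled but the block windowing is coarse.
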