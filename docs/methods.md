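# Methods

## Model

A corpus is a set of forum posts from one source. Posts are treated as
independent bag-of-words documents (thread structure, if any, is ignored).
The document-term matrix V (n documents × m terms) counts each term's
occurrences per document; unigram and bigram analyses use separate matrices
and separate models, because a bigram model's terms are already word pairs
and mixing orders muddles both vocabularies.

Topic modeling is non-negative matrix factorization, V ≈ WH with W, H ≥ 0
and rank k, under the Frobenius objective ‖V − WH‖_F. Frobenius was chosen
over KL divergence because the method is framed throughout as least-squares
matrix approximation; the multiplicative (Lee–Seung) updates guarantee a
monotone non-increasing loss, which the implementation records per
iteration and the tests assert with 1e-10 slack (epsilon guards in the
denominators can perturb the last digits).

Conventions after fitting: H rows are normalized to sum to 1 (term
distributions) with the scale absorbed into W. A topic's size is its column
share of W's total mass; the published per-forum tables print sizes that
sum to ≈1 across each model's ten topics, which fixes this normalization
choice. Relevance ranks 0..k−1 sort sizes descending, ties to the lower
topic index (stable); ranks 0–4 form the "relevant" band eligible for
category assignment.

## Tunable parameters

| parameter | default | why |
|---|---|---|
| k (topics per source) | 10 | interpretability bound used for all three forums; reduced automatically when the matrix is smaller, but an explicit k beyond min(n, m) is an error |
| max_iter / tol | 500 / 1e-4 relative loss change | the 20×30 reference problems converge in well under 500 iterations; 1e-4 changes sizes only in the 4th decimal |
| init | NNDSVD, zeros filled | deterministic, reproducible without a seed; seeded uniform init available |
| min_df | 2 | singleton terms carry no co-occurrence signal and inflate the vocabulary |
| weighting | raw counts | TF/IDF is an explicit optional transform, not the default |
| stoplist | boilerplate set (deleted, removed, thanks, thank, sharing, user, https, www, reddit, com) | forum-UI artifacts; per-forum additions load from a plain text file |

Numerical choices worth knowing:

* **NNDSVD fill.** Exact zeros in the NNDSVD factors are fixed points of
  multiplicative updates, so they are filled. The fill value is
  sqrt(mean(V)/k) rather than the more common mean(V): a factor entry has
  the dimension of sqrt(matrix entry), and with this fill the entire
  initialization scales by sqrt(c) when V is scaled by c, making topic
  sizes and ranks exactly scale-invariant (asserted in the tests).
* **IDF.** tfidf uses plain ln(N/df) without smoothing; a term present in
  every document is deliberately zeroed — the transform exists to penalize
  corpus-wide terms. Applying it twice is a state error.
* **Tokenization.** Lowercase; URLs stripped; tokens are pure-letter runs
  of length ≥ 2 (str.isalpha, so umlauts and ß survive and unicode
  numerals like ² do not); pure-digit tokens are kept only for bigram
  matrices, so dosage terms ("400 mg") exist as bigrams while stray digits
  do not pollute unigram models; mixed alphanumerics ("400mg") are dropped.
  Hyphens split tokens, which also normalizes hyphen/space phrase variants
  for the keyword probe. Stopwords are removed before bigram formation, so
  no bigram contains a stopword.
* **Degenerate inputs.** All-zero document rows are rejected by name;
  documents emptied by filtering are excluded from the matrix and reported;
  a topic whose H row collapses to zero is re-normalized to the uniform
  distribution (its W column is ≈0, so it carries no size).

## Topic evolution

Each document's W row is normalized to its topic shares; the weight of
topic t in month m is the mean share over documents posted in m. Documents
— not tokens — are the unit, because forum posts vary enormously in length
and a verbose post should not dominate its month. Consequently every
covered month's weights sum to 1 across topics, and so do period averages
(computed over covered months only). Months without posts are gaps (NaN,
coverage 0), not zeros: the published analyses handle patchy forum history
by restricting the window, not by imputing silence as absence. Exports
carry both the unit-sum share and a ×100 scale; the absolute weight scale
used in the published evolution figures (values like ≈27.5) depends on an
unstated constant, so no equality with those absolute values is asserted
anywhere. One model is fitted on the full window and documents are grouped
by month afterwards (fixed named topics across years), rather than
refitting per month, which would break topic identity over time.

## Cross-forum matching

Matching is label-based: each topic's label (its top term) is mapped
through an editable synonym/translation table to a canonical label, and a
canonical label present in ≥ 2 forums is a match; the spread is max − min
of the relevance ranks involved. The shipped table contains exactly the
pairs needed across the three CML forums (leukämie→leukemia, arzt→doctor,
antwort/answer/reply→answer/reply); there is no machine translation. A
cosine similarity between topic-term rows is available as a secondary
diagnostic for models sharing a vocabulary, but the headline match count is
label-based because the published comparison is.

## Synthetic data: what it emulates and what it does not

The generator draws each post's topic mixture from a symmetric
Dirichlet(α = 0.1, k = 4 by default — short, mostly single-theme posts),
its length from Poisson(40), and its tokens topic-then-term from k
topic-term distributions over a 200-term vocabulary. Topic-term rows are
Dirichlet(0.05) draws (sparse, well-separated topics, as on themed boards);
a disjoint-support variant gives each topic its own vocabulary block.
Posts are stamped uniformly over a configurable month window; a trend
(topic, slope) moves that topic's expected prevalence linearly per month
via a month-dependent Dirichlet mean, with feasibility (prevalences staying
inside (0,1)) validated up front. Surface vocabularies are synthetic
syllable strings — the German-like profile mixes in umlauts/ß to exercise
unicode handling — and optional two-token collocation atoms induce bigram
structure. No real patient text is fabricated.

This validates the machinery, not the sociology: real forum text has
correlated topics, bursty posting, quoting, dialects and spelling noise
that the generator deliberately omits. Passing recovery tests shows the
pipeline finds planted structure under its own model assumptions; it does
not certify topic quality on real corpora. Recovery is scored as the mean
cosine between true and fitted topic-term rows under the optimal one-to-one
assignment (Hungarian algorithm), after re-indexing the truth onto the
fitted model's vocabulary.

Problem sizes used in the validation suite: recovery at 1,000 posts,
trend recovery at 1,500 posts × 24 months × 5 seeds, prevalence
conservation and phrase calibration at 10,000 posts — large enough that
sampling error is far from the asserted margins, small enough to keep the
whole suite fast.

## Known limitations and open choices

* The published per-forum topic tables cannot be regenerated from scratch
  here: that requires the original scraped corpora and the authors' exact
  preprocessing dialect. Everything derivable from the printed tables
  (ranks, match count, spreads) is reproduced exactly from the shipped
  reference tables; model-path claims are validated on synthetic ground
  truth instead.
* One printed row of the German forum's unigram table (sizes 0.0407 at
  rank 8 above 0.0474 at rank 9) contradicts size-descending order and is
  almost certainly a typesetting transposition; it is stored as printed and
  excluded from rank checks, and the implementation always ranks strictly
  by size.
* Whether the published sizes came from count or TF/IDF matrices is
  unstated; both paths are supported and neither is asserted against the
  printed sizes.
* Whether "1% of the discourse" means share of posts or share of tokens is
  ambiguous; the phrase probe reports both.
* No stemming or lemmatization: the published topic labels are surface
  forms, and conflating inflections would detach labels from what readers
  of the forums actually see.
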