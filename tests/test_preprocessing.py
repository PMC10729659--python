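"""Tokenization, n-grams and document-term matrix construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forum_topics import (
    DEFAULT_STOPWORDS,
    Corpus,
    build_dtm,
    extract_ngrams,
    generate_corpus,
    remove_stopwords,
    SyntheticSpec,
    tfidf_transform,
    tokenize,
)
from forum_topics.preprocessing import EmptyMatrixError

from conftest import make_post


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Nehme Glivec 400mg täglich!", ["nehme", "glivec", "täglich"]),
        ("", []),
        ("https://www.reddit.com test", ["test"]),
        ("BCR-ABL Wert", ["bcr", "abl", "wert"]),
        ("a b c", []),  # single letters dropped
        ("großes Maß", ["großes", "maß"]),
    ],
)
def test_tokenize_rules(text, expected):
    assert tokenize(text) == expected


def test_tokenize_keeps_pure_digits_only_on_request():
    assert tokenize("400 mg daily") == ["mg", "daily"]
    assert tokenize("400 mg daily", keep_numbers=True) == ["400", "mg", "daily"]
    # mixed alphanumerics stay out either way
    assert tokenize("400mg", keep_numbers=True) == []


def test_remove_stopwords_with_boilerplate_list():
    assert remove_stopwords(["thanks", "glivec", "user"], DEFAULT_STOPWORDS) == ["glivec"]
    assert remove_stopwords(["glivec", "tasigna"], frozenset()) == ["glivec", "tasigna"]
    assert remove_stopwords(["thanks", "thank"], DEFAULT_STOPWORDS) == []


@pytest.mark.parametrize(
    "tokens,n,expected",
    [
        (["bcr", "abl", "wert"], 2, ["bcr abl", "abl wert"]),
        (["a"], 2, []),
        (["bcr", "abl", "wert"], 1, ["bcr", "abl", "wert"]),
        ([], 2, []),
    ],
)
def test_extract_ngrams(tokens, n, expected):
    assert extract_ngrams(tokens, n) == expected


def test_dtm_counts_terms_per_document():
    corpus = Corpus.from_posts(
        [make_post("d1", "glivec glivec tasigna"), make_post("d2", "tasigna")],
        forum_id="forum-a",
    )
    dtm = build_dtm(corpus, stoplist=frozenset(), ngram_order=1, min_df=1)
    assert dtm.vocabulary.terms == ("glivec", "tasigna")
    assert dtm.toarray().tolist() == [[2.0, 1.0], [0.0, 1.0]]
    assert dtm.weighting == "count"

    dtm2 = build_dtm(corpus, stoplist=frozenset(), ngram_order=1, min_df=2)
    assert dtm2.vocabulary.terms == ("tasigna",)
    assert dtm2.doc_ids == ("d1", "d2")


def test_dtm_excludes_emptied_documents_and_reports_them():
    corpus = Corpus.from_posts(
        [make_post("d1", "glivec glivec"), make_post("d2", "thanks user")],
        forum_id="forum-a",
    )
    dtm = build_dtm(corpus, min_df=1)
    assert dtm.doc_ids == ("d1",)
    assert dtm.excluded_doc_ids == ("d2",)


def test_dtm_with_nothing_retainable_raises():
    corpus = Corpus.from_posts([make_post("d1", "thanks user")], forum_id="forum-a")
    with pytest.raises(EmptyMatrixError):
        build_dtm(corpus, min_df=1)


def test_dtm_total_equals_retained_token_tally():
    spec = SyntheticSpec(k=3, vocab_size=80, n_posts=200, doc_length=15, seed=5)
    corpus, _ = generate_corpus(spec)
    for ngram in (1, 2):
        dtm = build_dtm(corpus, stoplist=frozenset(), ngram_order=ngram, min_df=2)
        retained = set(dtm.vocabulary.terms)
        tally = sum(
            1
            for post in corpus
            for term in extract_ngrams(tokenize(post.text, keep_numbers=ngram == 2), ngram)
            if term in retained
        )
        assert dtm.values.sum() == tally


def test_dtm_pipeline_is_deterministic():
    spec = SyntheticSpec(k=2, vocab_size=50, n_posts=100, doc_length=10, seed=9)
    corpus, _ = generate_corpus(spec)
    a = build_dtm(corpus, min_df=2)
    b = build_dtm(corpus, min_df=2)
    assert a.vocabulary.terms == b.vocabulary.terms
    assert (a.values != b.values).nnz == 0


def test_tfidf_matches_percell_formula():
    corpus = Corpus.from_posts(
        [make_post(f"d{i}", text) for i, text in enumerate(
            ["aa bb cc", "aa aa dd", "aa cc cc dd", "bb bb", "aa dd dd dd"]
        )],
        forum_id="forum-a",
    )
    dtm = build_dtm(corpus, stoplist=frozenset(), min_df=1)
    out = tfidf_transform(dtm)
    counts = dtm.toarray()
    n_docs = counts.shape[0]
    expected = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        df = int((counts[:, j] > 0).sum())
        for i in range(n_docs):
            expected[i, j] = counts[i, j] * math.log(n_docs / df)
    assert np.allclose(out.toarray(), expected)
    assert out.weighting == "tfidf"
    assert (out.toarray() >= 0).all()
    # "aa" appears in 4 of 5 docs, "everywhere" terms vanish entirely:
    col_aa = dtm.vocabulary.index["aa"]
    assert expected[:, col_aa].sum() > 0
    with pytest.raises(ValueError, match="already"):
        tfidf_transform(out)


def test_tfidf_zeroes_allpresent_term_and_single_doc_corpus():
    corpus = Corpus.from_posts(
        [make_post("d1", "aa bb"), make_post("d2", "aa cc bb"), make_post("d3", "aa bb bb")],
        forum_id="forum-a",
    )
    dtm = build_dtm(corpus, stoplist=frozenset(), min_df=1)
    out = tfidf_transform(dtm).toarray()
    for term in ("aa", "bb"):
        assert np.all(out[:, dtm.vocabulary.index[term]] == 0)

    single = Corpus.from_posts([make_post("d1", "aa bb aa")], forum_id="forum-a")
    out1 = tfidf_transform(build_dtm(single, stoplist=frozenset(), min_df=1))
    assert out1.toarray().sum() == 0


token_lists = st.lists(
    st.sampled_from(["glivec", "tasigna", "wert", "thanks", "user", "pcr"]),
    max_size=12,
)


@settings(deadline=None, derandomize=True)
@given(tokens=token_lists)
def test_stopword_removal_before_bigrams_keeps_bigrams_clean(tokens):
    cleaned = remove_stopwords(tokens, DEFAULT_STOPWORDS)
    for bigram in extract_ngrams(cleaned, 2):
        assert not set(bigram.split()) & DEFAULT_STOPWORDS


@settings(deadline=None, derandomize=True)
@given(text=st.text(max_size=80))
def test_tokenize_output_is_normalized(text):
    for token in tokenize(text):
        assert token == token.lower()
        assert len(token) >= 2
        assert token.isalpha()
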