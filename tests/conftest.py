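import datetime as dt

import pytest

from forum_topics import (
    Corpus,
    ForumPost,
    SyntheticSpec,
    build_dtm,
    fit_nmf,
    generate_corpus,
)


def make_post(post_id, text, year=2020, month=1, day=15, forum="forum-a", lang="en"):
    return ForumPost(
        post_id=post_id,
        forum_id=forum,
        timestamp=dt.date(year, month, day),
        language=lang,
        text=text,
    )


@pytest.fixture
def tiny_corpus():
    """Three hand-written posts across two months."""
    return Corpus.from_posts(
        [
            make_post("a1", "glivec glivec tasigna", month=1),
            make_post("a2", "tasigna", month=1),
            make_post("a3", "pcr wert bcr abl", month=2),
        ],
        forum_id="forum-a",
    )


@pytest.fixture(scope="session")
def synthetic_bundle():
    """Default synthetic study: corpus, ground truth, DTM and fitted model."""
    spec = SyntheticSpec(k=4, vocab_size=200, n_posts=1000,
                         dirichlet_alpha=0.1, seed=7)
    corpus, truth = generate_corpus(spec)
    dtm = build_dtm(corpus, stoplist=frozenset(), ngram_order=1, min_df=2)
    model = fit_nmf(dtm, k=4, seed=7)
    return spec, corpus, truth, dtm, model
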