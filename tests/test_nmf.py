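"""NMF fitting, topic sizes, relevance ranking and top-term summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forum_topics import (
    TopicModel,
    eligible_topics,
    fit_nmf,
    rank_topics,
    top_terms,
    topic_label,
    topic_sizes,
)
from forum_topics.nmf import nndsvd_init
from forum_topics.reference import CMLSUPPORT_UNIGRAM_SIZES


def _random_model(seed=0, k=4, m=12):
    rng = np.random.default_rng(seed)
    return TopicModel(
        doc_topic=rng.uniform(size=(25, k)),
        topic_term=rng.dirichlet(np.ones(m), size=k),
        k=k, seed=seed, n_iter=1,
        loss_trace=np.array([1.0]), converged=True,
        terms=tuple(f"t{i}" for i in range(m)),
    )


def test_rank_one_matrix_is_recovered_exactly():
    rng = np.random.default_rng(0)
    V = np.outer(rng.uniform(1, 2, size=15), rng.uniform(1, 2, size=10))
    model = fit_nmf(V, k=1, max_iter=2000, tol=1e-12)
    assert model.loss_trace[-1] < 1e-6 * np.linalg.norm(V)


def test_loss_trace_is_monotone_nonincreasing():
    rng = np.random.default_rng(42)
    V = rng.uniform(size=(30, 20))
    for init in ("nndsvda", "random"):
        model = fit_nmf(V, k=5, seed=1, max_iter=300, tol=0.0, init=init)
        assert np.all(np.diff(model.loss_trace) <= 1e-10)
        assert np.all(model.doc_topic >= 0)
        assert np.all(model.topic_term >= 0)


def test_matches_reference_nmf_with_shared_init():
    sklearn = pytest.importorskip("sklearn.decomposition")
    for seed, k in [(0, 2), (1, 5)]:
        rng = np.random.default_rng(seed)
        V = rng.uniform(size=(20, 30))
        W0, H0 = nndsvd_init(V, k)
        ours = fit_nmf(V, k=k, max_iter=4000, tol=1e-10)
        ref = sklearn.NMF(n_components=k, init="custom", solver="mu",
                          beta_loss="frobenius", tol=1e-10, max_iter=4000)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W = ref.fit_transform(V, W=W0.copy(), H=H0.copy())
        ref_err = np.linalg.norm(V - W @ ref.components_)
        assert ours.loss_trace[-1] == pytest.approx(ref_err, rel=0.01)


def test_topic_term_rows_are_distributions():
    rng = np.random.default_rng(3)
    model = fit_nmf(rng.uniform(size=(40, 25)), k=6)
    assert np.allclose(model.topic_term.sum(axis=1), 1.0)


def test_input_validation():
    rng = np.random.default_rng(0)
    V = rng.uniform(size=(10, 8))
    with pytest.raises(ValueError, match="k="):
        fit_nmf(V, k=9)
    V[3] = 0.0
    with pytest.raises(ValueError, match="all-zero"):
        fit_nmf(V, k=2)
    with pytest.raises(ValueError, match="nonnegative"):
        fit_nmf(-V, k=2)


def test_topic_sizes_normalization_and_symmetry():
    base = np.abs(np.random.default_rng(0).normal(size=20)) + 0.1
    one = TopicModel(doc_topic=base[:, None], topic_term=np.ones((1, 5)) / 5,
                     k=1, seed=0, n_iter=0, loss_trace=np.zeros(1), converged=True)
    assert topic_sizes(one).tolist() == [1.0]

    two = TopicModel(doc_topic=np.column_stack([base, base]),
                     topic_term=np.ones((2, 5)) / 5,
                     k=2, seed=0, n_iter=0, loss_trace=np.zeros(1), converged=True)
    assert np.allclose(topic_sizes(two), [0.5, 0.5])


def test_topic_sizes_match_column_sum_oracle(synthetic_bundle):
    *_, model = synthetic_bundle
    sizes = topic_sizes(model)
    W = model.doc_topic
    expected = [W[:, t].sum() / W.sum() for t in range(model.k)]
    assert np.allclose(sizes, expected)
    assert sizes.sum() == pytest.approx(1.0, abs=1e-9)


def test_published_sizes_rank_in_table_order():
    ranking = rank_topics(CMLSUPPORT_UNIGRAM_SIZES)
    assert [ranking[i] for i in range(10)] == list(range(10))


@pytest.mark.parametrize(
    "sizes,expected",
    [
        ([0.5], {0: 0}),
        ([0.3, 0.3, 0.4], {2: 0, 0: 1, 1: 2}),
        ([0.2, 0.2, 0.2], {0: 0, 1: 1, 2: 2}),  # ties broken by lower index
    ],
)
def test_rank_topics_ordering_and_ties(sizes, expected):
    assert rank_topics(sizes).rank == expected


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=12))
def test_rank_topics_is_a_size_sorted_bijection(sizes):
    ranking = rank_topics(sizes)
    ranks = sorted(ranking.rank.values())
    assert ranks == list(range(len(sizes)))
    ordered = ranking.order()
    for a, b in zip(ordered, ordered[1:]):
        assert sizes[a] >= sizes[b]


def test_top_terms_against_full_sort_oracle():
    model = _random_model(seed=5, k=3, m=40)
    for t in range(3):
        row = model.topic_term[t]
        oracle = sorted(range(40), key=lambda i: (-row[i], i))[:10]
        assert [term for term, _ in top_terms(model, t, n=10)] == [
            f"t{i}" for i in oracle
        ]
        weights = [w for _, w in top_terms(model, t, n=10)]
        assert weights == sorted(weights, reverse=True)


def test_top_terms_edge_cases():
    H = np.zeros((1, 4))
    H[0, 2] = 1.0
    model = TopicModel(doc_topic=np.ones((3, 1)), topic_term=H, k=1, seed=0,
                       n_iter=0, loss_trace=np.zeros(1), converged=True,
                       terms=("a", "b", "c", "d"))
    assert top_terms(model, 0, n=1) == [("c", 1.0)]
    assert len(top_terms(model, 0, n=99)) == 4  # truncates at vocabulary size
    with pytest.raises(IndexError):
        top_terms(model, 1)
    assert topic_label(model, 0) == "c"


def test_eligible_topics_cutoffs():
    ranking = rank_topics(CMLSUPPORT_UNIGRAM_SIZES)
    assert len(eligible_topics(ranking, cutoff=4)) == 5
    assert eligible_topics(ranking, cutoff=9) == set(range(10))
    assert eligible_topics(ranking, cutoff=0) == {0}  # the largest topic


def test_scale_invariance_of_sizes_and_ranks():
    rng = np.random.default_rng(8)
    V = rng.uniform(size=(30, 18))
    a = fit_nmf(V, k=4)
    b = fit_nmf(7.3 * V, k=4)
    assert np.allclose(topic_sizes(a), topic_sizes(b), atol=1e-6)
    assert rank_topics(topic_sizes(a)).rank == rank_topics(topic_sizes(b)).rank
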