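"""Synthetic month-stamped forum corpora with known topic structure.

The generator emulates the statistical skeleton the whole pipeline assumes:
documents are bags of tokens drawn from k latent topic-term distributions,
mixed per document by a Dirichlet draw. Posts are stamped with calendar
months; an optional linear trend moves one topic's expected monthly
prevalence up or down so temporal analyses have a known ground truth.
Everything is reproducible from a single seed, and the true topic-term
matrix and per-document mixtures are returned alongside the corpus so
recovery can be scored.

Surface vocabularies are synthetic syllable strings (the German-like
profile mixes in umlauts and ß to exercise unicode handling); no real
patient text is fabricated. Bigram structure can be induced by declaring
some vocabulary entries as fixed two-token collocations that expand to
adjacent tokens in the text.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corpus import Corpus, ForumPost, Month, add_months
from .cross_forum import topic_term_cosine
from .nmf import TopicModel
from .preprocessing import DEFAULT_STOPWORDS

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "SpecError",
    "generate_corpus",
    "prevalence_schedule",
    "inject_phrase",
    "recovery_score",
]


class SpecError(ValueError):
    """The synthetic specification is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus.

    ``dirichlet_alpha`` is the symmetric concentration of per-document
    topic mixtures (small alpha = near single-topic posts, as on themed
    forum boards). ``term_concentration`` shapes each topic's Dirichlet
    term distribution (small = sparse, well-separated topics);
    ``disjoint_topics`` instead gives every topic its own vocabulary block.
    ``trend`` is (topic_index, slope): the topic's expected prevalence
    moves linearly by ``slope`` per month from the uniform 1/k baseline,
    the remainder shared equally by the other topics.
    """

    k: int = 4
    vocab_size: int = 200
    n_posts: int = 1000
    doc_length: float = 40.0
    dirichlet_alpha: float = 0.1
    start_month: Month = (2020, 1)
    n_months: int = 12
    trend: tuple[int, float] | None = None
    language_profile: str = "en"
    seed: int = 0
    disjoint_topics: bool = False
    term_concentration: float = 0.05
    n_collocations: int = 0
    forum_id: str = "synthetic-forum"

    def validate(self) -> None:
        if self.k < 2:
            raise SpecError("k must be >= 2")
        if self.vocab_size < self.k:
            raise SpecError("vocab_size must be >= k")
        if self.n_posts < 1:
            raise SpecError("n_posts must be >= 1")
        if self.doc_length <= 0:
            raise SpecError("doc_length must be positive")
        if self.dirichlet_alpha <= 0:
            raise SpecError("dirichlet_alpha must be positive")
        if self.term_concentration <= 0:
            raise SpecError("term_concentration must be positive")
        if self.n_months < 1:
            raise SpecError("n_months must be >= 1")
        if self.language_profile not in ("de", "en"):
            raise SpecError("language_profile must be 'de' or 'en'")
        if self.n_collocations < 0 or self.n_collocations > self.vocab_size:
            raise SpecError("n_collocations must be in [0, vocab_size]")
        if self.trend is not None:
            topic, _ = self.trend
            if not 0 <= int(topic) < self.k:
                raise SpecError(f"trend topic {topic} out of range [0, {self.k})")
            prevalence_schedule(self)  # raises on infeasible slopes


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth returned with a generated corpus."""

    topic_term: np.ndarray       # (k, vocab) rows summing to 1
    doc_mixtures: np.ndarray     # (n_posts, k) rows summing to 1
    terms: tuple[str, ...]       # vocabulary entries (collocations contain a space)
    doc_months: tuple[Month, ...]
    prevalence: np.ndarray       # (n_months, k) expected monthly mixture means
    months: tuple[Month, ...]

    def realized_prevalence(self) -> np.ndarray:
        """Mean document mixture per month, (n_months, k); NaN if empty."""
        out = np.full_like(self.prevalence, np.nan)
        index = {m: j for j, m in enumerate(self.months)}
        for j, month in enumerate(self.months):
            rows = [i for i, m in enumerate(self.doc_months) if index[m] == j]
            if rows:
                out[j] = self.doc_mixtures[rows].mean(axis=0)
        return out


def prevalence_schedule(spec: SyntheticSpec) -> np.ndarray:
    """Expected per-month topic prevalences, (n_months, k) rows summing to 1."""
    schedule = np.full((spec.n_months, spec.k), 1.0 / spec.k)
    if spec.trend is not None:
        topic, slope = int(spec.trend[0]), float(spec.trend[1])
        months = np.arange(spec.n_months)
        p = 1.0 / spec.k + slope * months
        if np.any(p <= 0) or np.any(p >= 1):
            raise SpecError(
                f"trend slope {slope} drives topic {topic} prevalence out of "
                f"(0, 1) within {spec.n_months} months"
            )
        schedule[:, :] = ((1.0 - p) / (spec.k - 1))[:, None]
        schedule[:, topic] = p
    return schedule


# ---------------------------------------------------------------------------
# vocabulary synthesis

_CONSONANTS = "bcdfghklmnprstvwz"
_VOWELS = {"en": "aeiou", "de": "aeiouäöü"}


def _make_word(rng: np.random.Generator, profile: str) -> str:
    n_syll = int(rng.integers(2, 5))
    vowels = _VOWELS[profile]
    parts = []
    for _ in range(n_syll):
        parts.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        parts.append(vowels[rng.integers(len(vowels))])
    word = "".join(parts)
    if profile == "de" and rng.random() < 0.05:
        word += "ß"
    return word


def _make_vocabulary(rng: np.random.Generator, spec: SyntheticSpec) -> list[str]:
    words: set[str] = set()
    out: list[str] = []

    def fresh() -> str:
        while True:
            w = _make_word(rng, spec.language_profile)
            if w not in words and w not in DEFAULT_STOPWORDS:
                words.add(w)
                return w

    for _ in range(spec.n_collocations):
        out.append(f"{fresh()} {fresh()}")  # atomic two-token collocation
    for _ in range(spec.vocab_size - spec.n_collocations):
        out.append(fresh())
    return out


def _make_topic_term(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    V = spec.vocab_size
    H = np.zeros((spec.k, V))
    if spec.disjoint_topics:
        bounds = np.linspace(0, V, spec.k + 1).astype(int)
        for j in range(spec.k):
            lo, hi = bounds[j], bounds[j + 1]
            H[j, lo:hi] = rng.dirichlet(np.ones(hi - lo))
    else:
        for j in range(spec.k):
            H[j] = rng.dirichlet(np.full(V, spec.term_concentration))
    return H


# ---------------------------------------------------------------------------
# generation


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, SyntheticTruth]:
    """Draw a corpus and its ground truth from the spec, deterministically."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    terms = _make_vocabulary(rng, spec)
    topic_term = _make_topic_term(rng, spec)
    schedule = prevalence_schedule(spec)
    months = tuple(add_months(spec.start_month, j) for j in range(spec.n_months))

    month_idx = rng.integers(0, spec.n_months, size=spec.n_posts)
    lengths = rng.poisson(spec.doc_length, size=spec.n_posts)
    mixtures = np.zeros((spec.n_posts, spec.k))
    posts: list[ForumPost] = []
    alpha_scale = spec.dirichlet_alpha * spec.k
    width = max(6, len(str(spec.n_posts)))
    for i in range(spec.n_posts):
        m = int(month_idx[i])
        mix = rng.dirichlet(alpha_scale * schedule[m])
        mixtures[i] = mix
        n_tokens = int(lengths[i])
        draws: list[str] = []
        if n_tokens:
            topic_counts = rng.multinomial(n_tokens, mix)
            for j, c in enumerate(topic_counts):
                if c:
                    idx = rng.choice(spec.vocab_size, size=c, p=topic_term[j])
                    draws.extend(terms[t] for t in idx)
            perm = rng.permutation(len(draws))
            draws = [draws[p] for p in perm]
        tokens: list[str] = []
        for term in draws:
            tokens.extend(term.split(" "))  # collocations expand to adjacent tokens
        year, month = months[m]
        posts.append(
            ForumPost(
                post_id=f"p{i:0{width}d}",
                forum_id=spec.forum_id,
                timestamp=dt.date(year, month, int(rng.integers(1, 29))),
                language=spec.language_profile,
                text=" ".join(tokens),
            )
        )

    corpus = Corpus.from_posts(posts, forum_id=spec.forum_id)
    doc_month = {p.post_id: p.month for p in posts}
    truth = SyntheticTruth(
        topic_term=topic_term,
        doc_mixtures=np.array(
            [mixtures[int(p.post_id[1:])] for p in corpus.posts]
        ),
        terms=tuple(terms),
        doc_months=tuple(doc_month[p.post_id] for p in corpus.posts),
        prevalence=schedule,
        months=months,
    )
    return corpus, truth


def inject_phrase(
    corpus: Corpus, phrase: str, fraction: float, seed: int = 0
) -> tuple[Corpus, int]:
    """Append *phrase* to an exact fraction of posts, chosen at random.

    Returns the new corpus and the number of posts modified
    (``round(fraction * len(corpus))`` — exact by construction, for
    calibrating phrase-frequency probes).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    n_sel = int(round(fraction * len(corpus)))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(corpus), size=n_sel, replace=False).tolist())
    posts = [
        dc_replace(p, text=(p.text + " " + phrase).strip()) if i in chosen else p
        for i, p in enumerate(corpus.posts)
    ]
    return Corpus(forum_id=corpus.forum_id, posts=tuple(posts)), n_sel


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_score(
    model: TopicModel | np.ndarray,
    truth: np.ndarray,
    truth_terms: Sequence[str] | None = None,
) -> float:
    """Mean matched cosine between estimated and true topic-term rows.

    Topics are matched one-to-one by the assignment maximizing the mean
    cosine (Hungarian algorithm), so the score is invariant to topic
    permutation. If the model carries term names and ``truth_terms`` is
    given, the true matrix is re-indexed onto the model's vocabulary first
    (terms the model never saw are dropped from the comparison).
    """
    if isinstance(model, TopicModel):
        H = model.topic_term
        model_terms = model.terms
    else:
        H = np.asarray(model, dtype=np.float64)
        model_terms = None
    truth = np.asarray(truth, dtype=np.float64)
    if H.shape[0] != truth.shape[0]:
        raise ValueError(
            f"model has {H.shape[0]} topics but truth has {truth.shape[0]}"
        )
    if model_terms is not None and truth_terms is not None:
        index = {t: j for j, t in enumerate(truth_terms)}
        aligned = np.zeros((truth.shape[0], len(model_terms)))
        for j, term in enumerate(model_terms):
            if term in index:
                aligned[:, j] = truth[:, index[term]]
        truth = aligned
    elif H.shape[1] != truth.shape[1]:
        raise ValueError(
            "term axes differ and no vocabularies were provided for alignment"
        )
    cos = topic_term_cosine(H, truth)
    rows, cols = linear_sum_assignment(-cos)
    return float(cos[rows, cols].mean())
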