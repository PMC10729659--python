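"""Non-negative matrix factorization topic modeling.

Approximates the document-term matrix V (n docs x m terms) by W·H with
W >= 0 (n x k, the document-topic factor) and H >= 0 (k x m, the topic-term
factor), minimizing the Frobenius reconstruction error ||V - WH||_F via the
Lee–Seung multiplicative updates. Each update is non-increasing in the
objective, so the recorded loss trace is monotone.

Conventions:

* after fitting, each topic-term row of H is normalized to sum to 1 and the
  scale is absorbed into W, so H rows read as term distributions;
* a topic's **size** is its share of total document-topic mass (the W
  column sum over the total); sizes sum to 1 across a model's topics;
* topics are ranked by size descending into **relevance ranks** 0..k-1
  (0 = most relevant); by analyst convention ranks 0..4 are eligible for
  downstream category assignment;
* a topic's label is its top term (unigram models) or simply its top term
  string for bigram models, where the term itself is already a word pair.

Initialization is NNDSVD (deterministic, SVD-based, zeros filled with the
matrix mean) by default; a seeded uniform-random init is available.
"""

from __future__ import annotations

import json
import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite
from scipy.sparse.linalg import svds

from .preprocessing import DocumentTermMatrix

__all__ = [
    "TopicModel",
    "RelevanceRanking",
    "TopicSummary",
    "fit_nmf",
    "nndsvd_init",
    "random_init",
    "topic_sizes",
    "rank_topics",
    "top_terms",
    "eligible_topics",
    "topic_label",
    "summarize_topics",
    "save_topics_tsv",
    "save_top_terms_tsv",
    "save_wordcloud_json",
    "save_factors",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TopicModel:
    """Fitted factor pair with diagnostics.

    ``doc_topic`` is W (documents x k), ``topic_term`` is H (k x terms,
    rows summing to 1). ``terms`` and ``doc_ids`` carry the labels of the
    matrix axes when the model was fitted from a DocumentTermMatrix.
    """

    doc_topic: np.ndarray
    topic_term: np.ndarray
    k: int
    seed: int
    n_iter: int
    loss_trace: np.ndarray
    converged: bool
    terms: tuple[str, ...] | None = None
    doc_ids: tuple[str, ...] | None = None


@dataclass(frozen=True)
class RelevanceRanking:
    """Bijection topic_index -> relevance rank (0 = largest topic)."""

    rank: dict[int, int]

    def __getitem__(self, topic: int) -> int:
        return self.rank[topic]

    def order(self) -> list[int]:
        """Topic indices sorted by rank (most relevant first)."""
        return [t for t, _ in sorted(self.rank.items(), key=lambda kv: kv[1])]


@dataclass(frozen=True)
class TopicSummary:
    topic_index: int
    label: str
    size: float
    rank: int
    top_terms: tuple[tuple[str, float], ...]


# ---------------------------------------------------------------------------
# initialization


def _top_svd(V, k: int):
    """Leading-k SVD, descending singular values."""
    if sp.issparse(V) and k < min(V.shape) - 1:
        u, s, vt = svds(V.astype(np.float64), k=k, v0=np.ones(min(V.shape)))
        order = np.argsort(s)[::-1]
        return u[:, order], s[order], vt[order, :]
    dense = V.toarray() if sp.issparse(V) else np.asarray(V, dtype=np.float64)
    u, s, vt = np.linalg.svd(dense, full_matrices=False)
    return u[:, :k], s[:k], vt[:k, :]


def nndsvd_init(V, k: int, fill: str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """NNDSVD initialization (Boutsidis & Gallopoulos).

    Splits each leading singular pair into positive and negative parts and
    keeps the dominant section; the construction is invariant to the SVD's
    sign ambiguity, hence deterministic. Exact zeros would be fixed points
    of the multiplicative updates, so with ``fill="mean"`` they are replaced
    by sqrt(mean(V)/k) — the factor-scale analogue of the usual mean fill,
    chosen so the whole init scales with sqrt(c) when V is scaled by c and
    topic sizes stay exactly scale-invariant.
    """
    u, s, vt = _top_svd(V, k)
    n, m = V.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    # leading pair: Perron vector of a nonnegative matrix, safe to take |.|
    W[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    H[0, :] = np.sqrt(s[0]) * np.abs(vt[0, :])
    for j in range(1, k):
        x, y = u[:, j], vt[j, :]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        mp = np.linalg.norm(xp) * np.linalg.norm(yp)
        mn = np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn:
            u_j, v_j, sigma = xp, yp, mp
        else:
            u_j, v_j, sigma = xn, yn, mn
        if sigma > 0:
            factor = np.sqrt(s[j] * sigma)
            W[:, j] = factor * u_j / np.linalg.norm(u_j)
            H[j, :] = factor * v_j / np.linalg.norm(v_j)
    if fill == "mean":
        avg = float(V.sum() / (n * m))
        filler = np.sqrt(avg / k)
        W[W <= 0] = filler
        H[H <= 0] = filler
    return W, H


def random_init(V, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform init scaled to the matrix magnitude."""
    rng = np.random.default_rng(seed)
    n, m = V.shape
    avg = np.sqrt((V.sum() / (n * m)) / k)
    return (
        avg * rng.uniform(size=(n, k)) + _EPS,
        avg * rng.uniform(size=(k, m)) + _EPS,
    )


# ---------------------------------------------------------------------------
# fitting


def _frobenius(V, W: np.ndarray, H: np.ndarray, normV2: float) -> float:
    """||V - WH||_F without materializing WH densely."""
    cross = float(np.sum((V @ H.T) * W))
    val = normV2 - 2.0 * cross + float(np.sum((W.T @ W) * (H @ H.T)))
    return float(np.sqrt(max(val, 0.0)))


def fit_nmf(
    dtm: DocumentTermMatrix | np.ndarray | sp.spmatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    init: str = "nndsvda",
) -> TopicModel:
    """Factorize a document-term matrix into k nonnegative topics.

    Runs Lee–Seung multiplicative updates on the Frobenius objective until
    the relative loss change drops below ``tol`` or ``max_iter`` is
    reached. ``init`` is ``"nndsvda"`` (deterministic; ``seed`` recorded but
    unused) or ``"random"`` (seeded uniform).
    """
    if isinstance(dtm, DocumentTermMatrix):
        V = dtm.values
        terms: tuple[str, ...] | None = dtm.vocabulary.terms
        doc_ids: tuple[str, ...] | None = dtm.doc_ids
    else:
        V = dtm
        terms = doc_ids = None
    if not sp.issparse(V):
        V = np.asarray(V, dtype=np.float64)
        if V.ndim != 2:
            raise ValueError("input must be a 2-D matrix")
        if np.any(V < 0):
            raise ValueError("input matrix must be nonnegative")
    else:
        V = V.tocsr().astype(np.float64)
        if V.nnz and V.data.min() < 0:
            raise ValueError("input matrix must be nonnegative")

    n, m = V.shape
    if k < 1 or k > min(n, m):
        raise ValueError(f"k={k} must be in [1, min(n_docs={n}, n_terms={m})]")
    row_sums = np.asarray(V.sum(axis=1)).ravel()
    zero_rows = np.flatnonzero(row_sums == 0)
    if zero_rows.size:
        which = (
            [doc_ids[i] for i in zero_rows[:5]] if doc_ids is not None
            else zero_rows[:5].tolist()
        )
        raise ValueError(f"all-zero document row(s): {which}")

    if init in ("nndsvda", "nndsvd"):
        W, H = nndsvd_init(V, k, fill="mean" if init == "nndsvda" else "none")
    elif init == "random":
        W, H = random_init(V, k, seed)
    else:
        raise ValueError(f"unknown init {init!r}")
    W = np.maximum(W, _EPS)
    H = np.maximum(H, _EPS)

    normV2 = float(V.multiply(V).sum()) if sp.issparse(V) else float(np.sum(V * V))
    trace = [_frobenius(V, W, H, normV2)]
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        # H update: H <- H * (W^T V) / (W^T W H)
        numer = (V.T @ W).T if sp.issparse(V) else W.T @ V
        denom = (W.T @ W) @ H + _EPS
        H *= numer / denom
        # W update: W <- W * (V H^T) / (W H H^T)
        numer = V @ H.T
        denom = W @ (H @ H.T) + _EPS
        W *= numer / denom
        loss = _frobenius(V, W, H, normV2)
        trace.append(loss)
        n_iter = it
        prev = trace[-2]
        if abs(prev - loss) <= tol * max(prev, _EPS):
            converged = True
            break

    # normalize topic-term rows to distributions, absorb scale into W
    scale = H.sum(axis=1)
    for j in range(k):
        if scale[j] > 0:
            H[j, :] /= scale[j]
            W[:, j] *= scale[j]
        else:  # degenerate empty topic: uniform row, (near-)zero W column
            H[j, :] = 1.0 / m
    return TopicModel(
        doc_topic=W,
        topic_term=H,
        k=k,
        seed=seed,
        n_iter=n_iter,
        loss_trace=np.asarray(trace),
        converged=converged,
        terms=terms,
        doc_ids=doc_ids,
    )


# ---------------------------------------------------------------------------
# topic summaries


def topic_sizes(model: TopicModel) -> np.ndarray:
    """Per-topic share of total document-topic mass (sums to 1)."""
    column_mass = model.doc_topic.sum(axis=0)
    total = column_mass.sum()
    if total <= 0:
        raise ValueError("degenerate model: document-topic factor is all zero")
    return column_mass / total


def rank_topics(sizes: Sequence[float]) -> RelevanceRanking:
    """Relevance ranks 0..k-1 by size descending, ties to lower index."""
    sizes = np.asarray(sizes, dtype=np.float64)
    if np.any(sizes < 0):
        raise ValueError("sizes must be nonnegative")
    order = sorted(range(len(sizes)), key=lambda i: (-sizes[i], i))
    return RelevanceRanking(rank={topic: r for r, topic in enumerate(order)})


def top_terms(model: TopicModel, topic: int, n: int = 30) -> list[tuple[str, float]]:
    """The n heaviest terms of a topic, weight-descending, ties by vocab order."""
    if not 0 <= topic < model.k:
        raise IndexError(f"topic {topic} out of range [0, {model.k})")
    row = model.topic_term[topic]
    if model.terms is not None:
        names: Sequence[str] = model.terms
    else:
        names = [str(i) for i in range(row.size)]
    order = sorted(range(row.size), key=lambda i: (-row[i], i))[:n]
    return [(names[i], float(row[i])) for i in order]


def eligible_topics(ranking: RelevanceRanking, cutoff: int = 4) -> set[int]:
    """Topics with relevance rank <= cutoff (the 0..4 'relevant' band)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return {t for t, r in ranking.rank.items() if r <= cutoff}


def topic_label(model: TopicModel, topic: int, n_words: int = 1) -> str:
    """Label a topic by its heaviest term(s), e.g. 'glivec' or 'bcr abl'."""
    return " ".join(term for term, _ in top_terms(model, topic, n=n_words))


def summarize_topics(
    model: TopicModel, n_terms: int = 30, label_words: int = 1
) -> list[TopicSummary]:
    sizes = topic_sizes(model)
    ranking = rank_topics(sizes)
    return [
        TopicSummary(
            topic_index=t,
            label=topic_label(model, t, n_words=label_words),
            size=float(sizes[t]),
            rank=ranking[t],
            top_terms=tuple(top_terms(model, t, n=n_terms)),
        )
        for t in range(model.k)
    ]


# ---------------------------------------------------------------------------
# exports


def save_topics_tsv(
    summaries: Sequence[TopicSummary], path: str | Path, forum_id: str = ""
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["forum_id", "topic_index", "label", "size", "rank"])
        for s in summaries:
            writer.writerow([forum_id, s.topic_index, s.label, f"{s.size:.10f}", s.rank])


def save_top_terms_tsv(summaries: Sequence[TopicSummary], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["topic_index", "term", "weight", "position"])
        for s in summaries:
            for pos, (term, weight) in enumerate(s.top_terms, start=1):
                writer.writerow([s.topic_index, term, f"{weight:.10f}", pos])


def save_wordcloud_json(
    summaries: Sequence[TopicSummary], directory: str | Path
) -> None:
    """One term->weight JSON per topic, consumable by any cloud renderer."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in summaries:
        payload = {term: weight for term, weight in s.top_terms}
        (directory / f"topic_{s.topic_index:02d}.json").write_text(
            json.dumps(payload, ensure_ascii=False, indent=1, sort_keys=False),
            encoding="utf-8",
        )


def save_factors(model: TopicModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "doc_topic.mtx"), sp.coo_matrix(model.doc_topic))
    mmwrite(str(directory / "topic_term.mtx"), sp.coo_matrix(model.topic_term))
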