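"""Tokenization, n-gram extraction and document-term matrix construction.

The document-term matrix (DTM) is the input to topic modeling: rows are
documents, columns are terms, each cell counts how often the term occurs in
the document. Terms are either unigrams (single tokens) or bigrams
(adjacent two-token combinations, space-joined); the two orders are kept in
separate matrices and modeled separately.

Tokenization rules:

* text is lowercased and URLs are stripped first;
* tokens are runs of unicode letters (umlauts and ß intact) of length >= 2,
  split on any punctuation, digit or underscore — so ``treatment-free``
  yields two tokens and mixed alphanumerics like ``400mg`` are dropped;
* pure-digit tokens are retained only on request (default for bigram
  matrices, so dosage terms like ``400 mg`` survive as bigrams).

Stopwords are removed *before* n-gram formation, so no bigram ever contains
a stopword. A boilerplate stoplist (forum UI artifacts such as "deleted",
"thanks", "https", "www") ships as :data:`DEFAULT_STOPWORDS`; per-forum
additions are supplied by the caller, one term per line in a plain file.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

from .corpus import Corpus

__all__ = [
    "DEFAULT_STOPWORDS",
    "Vocabulary",
    "DocumentTermMatrix",
    "EmptyMatrixError",
    "tokenize",
    "remove_stopwords",
    "extract_ngrams",
    "build_dtm",
    "tfidf_transform",
    "load_stoplist",
    "save_vocabulary",
    "save_dtm",
]

#: boilerplate stoplist applied to every forum before modeling
DEFAULT_STOPWORDS = frozenset(
    {"deleted", "removed", "thanks", "thank", "sharing", "user",
     "https", "www", "reddit", "com"}
)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_SPLIT_RE = re.compile(r"[\W_]+", re.UNICODE)
_DIGITS_RE = re.compile(r"^\d+$", re.ASCII)


class EmptyMatrixError(ValueError):
    """No term survived filtering: the matrix would have zero columns."""


def tokenize(text: str, language: str = "en", keep_numbers: bool = False) -> list[str]:
    """Split raw post text into lowercase word tokens.

    ``language`` is accepted for interface symmetry (both German and
    English text pass through the same unicode-aware rules). With
    ``keep_numbers`` pure-digit tokens are retained (for dosage bigrams).
    """
    if not text:
        return []
    cleaned = _URL_RE.sub(" ", text).lower()
    tokens = []
    for raw in _SPLIT_RE.split(cleaned):
        # letters only (str.isalpha excludes unicode numerals like '²')
        if len(raw) >= 2 and raw.isalpha():
            tokens.append(raw)
        elif keep_numbers and raw and _DIGITS_RE.match(raw):
            tokens.append(raw)
    return tokens


def remove_stopwords(tokens: Sequence[str], stoplist: Iterable[str]) -> list[str]:
    """Order-preserving removal of stoplist terms (stoplist is lowercase)."""
    stopset = stoplist if isinstance(stoplist, (set, frozenset)) else frozenset(stoplist)
    return [t for t in tokens if t not in stopset]


def extract_ngrams(tokens: Sequence[str], n: int) -> list[str]:
    """Unigrams (the tokens themselves) or space-joined adjacent bigrams."""
    if n == 1:
        return list(tokens)
    if n == 2:
        return [f"{a} {b}" for a, b in zip(tokens, tokens[1:])]
    raise ValueError(f"ngram order must be 1 or 2, got {n}")


def load_stoplist(path: str | Path) -> frozenset[str]:
    """Read one stopword per line (blank lines and # comments ignored)."""
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.strip().lower()
        if term and not term.startswith("#"):
            terms.add(term)
    return frozenset(terms)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered distinct terms with positions and document frequencies."""

    terms: tuple[str, ...]
    doc_freq: tuple[int, ...]

    def __post_init__(self):
        if len(self.terms) != len(set(self.terms)):
            raise ValueError("vocabulary terms must be distinct")
        if len(self.doc_freq) != len(self.terms):
            raise ValueError("doc_freq length must match terms")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


@dataclass(frozen=True)
class DocumentTermMatrix:
    """Sparse nonnegative docs x terms matrix plus its vocabulary.

    ``weighting`` is ``"count"`` (raw integer counts) or ``"tfidf"``.
    ``doc_ids`` maps row -> post_id; documents that lost every token to
    filtering are excluded from the rows and listed in
    ``excluded_doc_ids``.
    """

    values: sp.csr_matrix
    vocabulary: Vocabulary
    ngram_order: int
    weighting: str
    doc_ids: tuple[str, ...]
    excluded_doc_ids: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


def build_dtm(
    corpus: Corpus,
    stoplist: Iterable[str] = DEFAULT_STOPWORDS,
    ngram_order: int = 1,
    min_df: int = 2,
    keep_numbers: bool | None = None,
) -> DocumentTermMatrix:
    """Count n-gram terms per post into a sparse document-term matrix.

    Vocabulary order is first appearance in the corpus; terms occurring in
    fewer than ``min_df`` documents are dropped. ``keep_numbers`` defaults
    to True for bigram matrices and False for unigrams.
    """
    if len(corpus) == 0:
        raise EmptyMatrixError("corpus is empty")
    if ngram_order not in (1, 2):
        raise ValueError(f"ngram order must be 1 or 2, got {ngram_order}")
    if keep_numbers is None:
        keep_numbers = ngram_order == 2
    stopset = frozenset(t.lower() for t in stoplist)

    doc_terms: list[tuple[str, list[str]]] = []
    first_seen: dict[str, int] = {}
    doc_freq: dict[str, int] = {}
    for post in corpus:
        tokens = remove_stopwords(
            tokenize(post.text, post.language, keep_numbers=keep_numbers), stopset
        )
        terms = extract_ngrams(tokens, ngram_order)
        doc_terms.append((post.post_id, terms))
        for term in set(terms):
            doc_freq[term] = doc_freq.get(term, 0) + 1
        for term in terms:
            if term not in first_seen:
                first_seen[term] = len(first_seen)

    retained = [t for t, _ in sorted(first_seen.items(), key=lambda kv: kv[1])
                if doc_freq[t] >= min_df]
    if not retained:
        raise EmptyMatrixError(
            f"no term reaches min_df={min_df}; the matrix would be empty"
        )
    index = {t: i for i, t in enumerate(retained)}

    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    doc_ids: list[str] = []
    excluded: list[str] = []
    for post_id, terms in doc_terms:
        counts: dict[int, int] = {}
        for term in terms:
            j = index.get(term)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if not counts:
            excluded.append(post_id)
            continue
        row = len(doc_ids)
        doc_ids.append(post_id)
        for j, c in sorted(counts.items()):
            rows.append(row)
            cols.append(j)
            data.append(c)

    values = sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), (rows, cols)),
        shape=(len(doc_ids), len(retained)),
    )
    vocabulary = Vocabulary(
        terms=tuple(retained),
        doc_freq=tuple(doc_freq[t] for t in retained),
    )
    return DocumentTermMatrix(
        values=values,
        vocabulary=vocabulary,
        ngram_order=ngram_order,
        weighting="count",
        doc_ids=tuple(doc_ids),
        excluded_doc_ids=tuple(excluded),
    )


def tfidf_transform(dtm: DocumentTermMatrix) -> DocumentTermMatrix:
    """Reweight counts as count(d,t) * ln(N / df(t)).

    Uses the plain unsmoothed inverse document frequency, so a term present
    in every document is zeroed out — the transform exists precisely to
    penalize corpus-wide terms.
    """
    if dtm.weighting != "count":
        raise ValueError(f"matrix is already {dtm.weighting}-weighted")
    n_docs = dtm.shape[0]
    # df over matrix rows: excluded documents hold no retained term, so the
    # vocabulary's corpus-wide doc_freq equals the per-row frequency.
    df = np.asarray(dtm.vocabulary.doc_freq, dtype=np.float64)
    idf = np.log(n_docs / df)
    values = sp.csr_matrix(dtm.values.multiply(idf[np.newaxis, :]))
    values.eliminate_zeros()
    return replace(dtm, values=values, weighting="tfidf")


# ---------------------------------------------------------------------------
# exports


def save_vocabulary(vocabulary: Vocabulary, path: str | Path) -> None:
    """Two-column TSV: term, doc_freq."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["term", "doc_freq"])
        for term, df in zip(vocabulary.terms, vocabulary.doc_freq):
            writer.writerow([term, df])


def save_dtm(dtm: DocumentTermMatrix, directory: str | Path, prefix: str = "dtm") -> None:
    """MatrixMarket matrix plus vocabulary TSV and doc-id list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / f"{prefix}.mtx"), dtm.values)
    save_vocabulary(dtm.vocabulary, directory / f"{prefix}_vocabulary.tsv")
    (directory / f"{prefix}_doc_ids.txt").write_text(
        "\n".join(dtm.doc_ids) + "\n", encoding="utf-8"
    )
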