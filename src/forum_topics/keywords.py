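"""Phrase-frequency probing.

Counts analyst-supplied words or phrases in a corpus — e.g. probing how
much of the discussion touches treatment-free remission ("treatment-free
remission", "therapy discontinuation", "TKI withdrawal"). Matching is
case-insensitive on tokenized text, so hyphen/space variants collapse
("treatment-free" tokenizes to the same two tokens as "treatment free");
multi-token phrases must appear as adjacent token runs.

Two share figures are reported, since "X% of the discourse" can mean
either: the share of posts containing at least one phrase occurrence, and
the occurrence count as a share of all tokens.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Corpus
from .preprocessing import remove_stopwords, tokenize

__all__ = ["PhraseStats", "PhraseReport", "phrase_frequency", "save_keywords_csv"]


@dataclass(frozen=True)
class PhraseStats:
    phrase: str
    instances: int          # total occurrences across the corpus
    posts: int              # posts containing >= 1 occurrence
    post_share_pct: float   # posts / total posts, in percent
    token_share_pct: float  # instances / total tokens, in percent


@dataclass(frozen=True)
class PhraseReport:
    total_posts: int
    total_tokens: int
    stats: tuple[PhraseStats, ...]
    empty_corpus: bool

    def __getitem__(self, phrase: str) -> PhraseStats:
        for s in self.stats:
            if s.phrase == phrase:
                return s
        raise KeyError(phrase)


def _count_runs(tokens: Sequence[str], needle: Sequence[str]) -> int:
    """Occurrences of needle as an adjacent run (overlaps counted)."""
    n = len(needle)
    if n == 0 or n > len(tokens):
        return 0
    first = needle[0]
    count = 0
    for i in range(len(tokens) - n + 1):
        if tokens[i] == first and list(tokens[i:i + n]) == list(needle):
            count += 1
    return count


def phrase_frequency(
    corpus: Corpus,
    phrases: Sequence[str],
    stoplist: Iterable[str] = frozenset(),
) -> PhraseReport:
    """Count each phrase's occurrences and its share of the corpus.

    ``stoplist`` is applied to the post tokens (and, symmetrically, to the
    phrase tokens) before matching, so phrase probes see the same token
    stream topic models do. An empty corpus yields zero counts with the
    ``empty_corpus`` flag raised rather than an error.
    """
    if not phrases:
        raise ValueError("phrases must be non-empty")
    stopset = frozenset(t.lower() for t in stoplist)
    needles = []
    for phrase in phrases:
        toks = remove_stopwords(tokenize(phrase, keep_numbers=True), stopset)
        if not toks:
            raise ValueError(f"phrase {phrase!r} has no matchable tokens")
        needles.append(toks)

    total_posts = len(corpus)
    total_tokens = 0
    instances = [0] * len(phrases)
    post_hits = [0] * len(phrases)
    for post in corpus:
        tokens = remove_stopwords(
            tokenize(post.text, post.language, keep_numbers=True), stopset
        )
        total_tokens += len(tokens)
        for j, needle in enumerate(needles):
            c = _count_runs(tokens, needle)
            instances[j] += c
            if c:
                post_hits[j] += 1

    stats = tuple(
        PhraseStats(
            phrase=phrase,
            instances=instances[j],
            posts=post_hits[j],
            post_share_pct=(100.0 * post_hits[j] / total_posts) if total_posts else 0.0,
            token_share_pct=(100.0 * instances[j] / total_tokens) if total_tokens else 0.0,
        )
        for j, phrase in enumerate(phrases)
    )
    return PhraseReport(
        total_posts=total_posts,
        total_tokens=total_tokens,
        stats=stats,
        empty_corpus=total_posts == 0,
    )


def save_keywords_csv(report: PhraseReport, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["phrase", "instances", "posts", "post_share_pct", "token_share_pct"]
        )
        for s in report.stats:
            writer.writerow(
                [s.phrase, s.instances, s.posts,
                 f"{s.post_share_pct:.6f}", f"{s.token_share_pct:.6f}"]
            )
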