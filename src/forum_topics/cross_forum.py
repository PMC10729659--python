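"""Matching topics across independently fitted forum models.

Each forum gets its own topic model, so "the same" topic appears under
different indices — and, across languages, under different surface labels
(German "leukämie" vs English "leukemia"). Matching is label-based: every
topic label is mapped through a synonym/translation table to a canonical
label, and topics whose canonical labels coincide in at least two forums
form a match. The editable table ships with exactly the translation pairs
needed for the three CML forums (leukämie→leukemia, arzt→doctor,
antwort/answer/reply→answer/reply); it is a config file, not machine
translation.

A secondary, language-blind diagnostic based on topic-term cosine
similarity is provided for models sharing a vocabulary; it never feeds the
headline label-based match count.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SynonymTable",
    "TopicOccurrence",
    "TopicMatch",
    "match_topics",
    "rank_spread",
    "topic_term_cosine",
    "save_matches_csv",
]


@dataclass(frozen=True)
class SynonymTable:
    """Case-insensitive surface label -> canonical label mapping."""

    mapping: Mapping[str, str]

    def canonical(self, label: str) -> str:
        key = label.strip().lower()
        return self.mapping.get(key, key)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SynonymTable":
        return cls({str(k).strip().lower(): str(v).strip().lower()
                    for k, v in mapping.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynonymTable":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"synonym file {path} must be a flat mapping")
        return cls.from_mapping(data)

    @classmethod
    def default(cls) -> "SynonymTable":
        """The packaged German→English translation table."""
        ref = resources.files("forum_topics").joinpath("data/synonyms.yaml")
        data = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return cls.from_mapping(data)


@dataclass(frozen=True)
class TopicOccurrence:
    forum_id: str
    ngram_order: int
    topic_index: int
    label: str
    rank: int


@dataclass(frozen=True)
class TopicMatch:
    """One topic present in >= 2 forums, with its per-forum ranks."""

    canonical_label: str
    occurrences: tuple[TopicOccurrence, ...]

    def best_rank(self) -> int:
        return min(o.rank for o in self.occurrences)

    def forums(self) -> set[str]:
        return {o.forum_id for o in self.occurrences}


LabeledRanking = Sequence[tuple[int, str, int]]  # (topic_index, label, rank)


def match_topics(
    rankings: Mapping[str, LabeledRanking],
    synonyms: SynonymTable | None = None,
    ngram_order: int = 1,
) -> list[TopicMatch]:
    """Group same-labeled topics across forums.

    ``rankings`` maps forum_id to (topic_index, label, rank) triples — the
    content of a fitted model's topics table. Labels are canonicalized via
    the synonym table; a canonical label seen in >= 2 distinct forums
    becomes a match. Output is sorted by best (lowest) rank, then label, so
    it is independent of forum insertion order.
    """
    if len(rankings) < 2:
        raise ValueError("need rankings from at least 2 forums")
    synonyms = synonyms or SynonymTable.default()

    groups: dict[str, list[TopicOccurrence]] = {}
    for forum_id in sorted(rankings):
        seen_in_forum: dict[str, int] = {}
        for topic_index, label, rank in rankings[forum_id]:
            if not label:
                raise ValueError(f"{forum_id}: topic {topic_index} has no label")
            canon = synonyms.canonical(label)
            if canon in seen_in_forum:
                warnings.warn(
                    f"{forum_id}: canonical label {canon!r} occurs more than "
                    "once; keeping both occurrences",
                    stacklevel=2,
                )
            seen_in_forum[canon] = topic_index
            groups.setdefault(canon, []).append(
                TopicOccurrence(
                    forum_id=forum_id,
                    ngram_order=ngram_order,
                    topic_index=int(topic_index),
                    label=str(label),
                    rank=int(rank),
                )
            )

    matches = [
        TopicMatch(canonical_label=canon, occurrences=tuple(occs))
        for canon, occs in groups.items()
        if len({o.forum_id for o in occs}) >= 2
    ]
    matches.sort(key=lambda m: (m.best_rank(), m.canonical_label))
    return matches


def rank_spread(match: TopicMatch) -> int:
    """Max minus min relevance rank across a match's occurrences."""
    if len(match.occurrences) < 2:
        raise ValueError("rank_spread needs a match with >= 2 occurrences")
    ranks = [o.rank for o in match.occurrences]
    return max(ranks) - min(ranks)


def topic_term_cosine(topic_term_a: np.ndarray, topic_term_b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between two models' topic-term rows.

    Diagnostic only — requires both models to share a vocabulary (columns
    aligned), which label-based matching does not.
    """
    a = np.asarray(topic_term_a, dtype=np.float64)
    b = np.asarray(topic_term_b, dtype=np.float64)
    if a.shape[1] != b.shape[1]:
        raise ValueError("topic-term matrices must share their term axis")
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    return (a / np.maximum(na, 1e-300)) @ (b / np.maximum(nb, 1e-300)).T


def save_matches_csv(matches: Sequence[TopicMatch], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["canonical_label", "ngram_order", "forum_id", "topic_index",
             "label", "rank", "spread"]
        )
        for match in matches:
            spread = rank_spread(match)
            for o in match.occurrences:
                writer.writerow(
                    [match.canonical_label, o.ngram_order, o.forum_id,
                     o.topic_index, o.label, o.rank, spread]
                )
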