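"""Published topic summaries for the three public CML patient forums.

These are the printed per-forum topic tables (label = top term(s), size =
share of document-topic mass, relevance rank 0-9) for the German forum
leukaemie-online.de, the English forum cmlsupport.org.uk, and the pooled
reddit communities (r/leukemia + r/CML), for both the unigram and the
bigram models. Sizes are the published four-decimal truncations.

They serve as fixed inputs for rank/relevance checks and for the
cross-forum matching of the three sources; fitting the models themselves
requires the original scraped corpora, which are not shipped.

Note: the leukaemie-online unigram table is stored exactly as published,
including one rank/size transposition (the 0.0407 topic ranked above the
0.0474 one) that contradicts size-descending ordering and is presumably a
typesetting slip; rank checks therefore use the cmlsupport table.
"""

from __future__ import annotations

from .cross_forum import LabeledRanking

__all__ = [
    "FORUM_TOPIC_TABLES",
    "CMLSUPPORT_UNIGRAM_SIZES",
    "published_rankings",
    "published_sizes",
]

# (topic_index, label, size, relevance rank), one tuple per printed row
FORUM_TOPIC_TABLES: dict[str, dict[int, list[tuple[int, str, float, int]]]] = {
    "leukaemie-online.de": {
        1: [
            (0, "leukämie", 0.2826, 0),
            (5, "cml", 0.1195, 1),
            (2, "glivec", 0.1148, 2),
            (4, "tasigna", 0.1021, 3),
            (6, "pcr", 0.0911, 4),
            (3, "studie", 0.0756, 5),
            (8, "arzt", 0.0651, 6),
            (1, "abl", 0.0604, 7),
            (9, "antwort", 0.0407, 8),
            (7, "mann", 0.0474, 9),
        ],
        2: [
            (0, "bcr abl", 0.2119, 0),
            (1, "400 mg", 0.1353, 1),
            (5, "nehme glivec", 0.1103, 2),
            (6, "cml patienten", 0.1026, 3),
            (2, "prof hochhaus", 0.1012, 4),
            (9, "nächste woche", 0.0781, 5),
            (7, "wünsche kraft", 0.0714, 6),
            (4, "schönen abend", 0.0647, 7),
            (8, "schönes wochenende", 0.0629, 8),
            (3, "org wiki", 0.0611, 9),
        ],
    },
    "cmlsupport.org.uk": {
        1: [
            (0, "time", 0.2419, 0),
            (4, "cml", 0.1643, 1),
            (2, "pcr", 0.1142, 2),
            (1, "dose", 0.0937, 3),
            (6, "imatinib", 0.0925, 4),
            (8, "months", 0.0847, 5),
            (7, "good", 0.0724, 6),
            (5, "vitamin", 0.0568, 7),
            (3, "news", 0.0475, 8),
            (9, "reply", 0.0317, 9),
        ],
        2: [
            (0, "bcr abl", 0.1473, 0),
            (4, "20 mg", 0.1226, 1),
            (5, "bone marrow", 0.1151, 2),
            (3, "let know", 0.1096, 3),
            (6, "ng ml", 0.1057, 4),
            (2, "log reduction", 0.1004, 5),
            (1, "good news", 0.0907, 6),
            (7, "support group", 0.0883, 7),
            (8, "nlm nih", 0.0737, 8),
            (9, "spaces live", 0.0462, 9),
        ],
    },
    "reddit": {
        1: [
            (0, "like", 0.3221, 0),
            (6, "blood", 0.0962, 1),
            (4, "transplant", 0.0954, 2),
            (1, "leukemia", 0.0821, 3),
            (2, "good", 0.0786, 4),
            (7, "know", 0.0708, 5),
            (3, "bone", 0.0702, 6),
            (8, "doctor", 0.0656, 7),
            (5, "hope", 0.0612, 8),
            (9, "help", 0.0572, 9),
        ],
        2: [
            (0, "bone marrow", 0.2023, 0),
            (1, "good luck", 0.1327, 1),
            (2, "stem cell", 0.1256, 2),
            (3, "post transplant", 0.1075, 3),
            (6, "years ago", 0.0892, 4),
            (5, "sounds like", 0.0842, 5),
            (4, "blood test", 0.0841, 6),
            (8, "second opinion", 0.0629, 7),
            (9, "ask doctor", 0.0621, 8),
            (7, "mind asking", 0.0490, 9),
        ],
    },
}


def published_rankings(ngram_order: int) -> dict[str, LabeledRanking]:
    """Per-forum (topic_index, label, rank) triples for cross-forum matching."""
    return {
        forum: [(idx, label, rank) for idx, label, _, rank in tables[ngram_order]]
        for forum, tables in FORUM_TOPIC_TABLES.items()
    }


def published_sizes(forum: str, ngram_order: int) -> list[float]:
    """Published topic sizes in printed table order."""
    return [size for _, _, size, _ in FORUM_TOPIC_TABLES[forum][ngram_order]]


#: the ten cmlsupport.org.uk unigram sizes in printed (rank 0..9) order
CMLSUPPORT_UNIGRAM_SIZES: list[float] = published_sizes("cmlsupport.org.uk", 1)
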