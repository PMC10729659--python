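"""Topic weights over calendar time.

Each document's document-topic row is normalized to sum to 1 (its topic
shares); the weight of topic t in month m is the mean share of t over the
documents posted in m. Documents — not tokens — are the averaging unit, so
a short post counts as much as a long one. Months inside the covered window
with no posts are gaps (NaN with coverage 0), never zeros: an empty month
carries no evidence about topic prevalence.

Because shares are per-document normalized, the weights of every covered
month sum to 1 across topics, and so does any period average. A x100
convenience column is included in exports for percentage-style reading.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Corpus, Month, month_range, parse_month
from .nmf import TopicModel
from .preprocessing import DocumentTermMatrix

__all__ = [
    "EvolutionSeries",
    "AlignmentError",
    "monthly_weights",
    "period_average",
    "extreme_topics",
    "month_slice",
    "fit_monthly_trend",
    "save_series_csv",
]


class AlignmentError(ValueError):
    """Document rows and corpus posts cannot be matched up."""


@dataclass(frozen=True)
class EvolutionSeries:
    """Topic x month weight matrix with per-month post coverage.

    ``weights[t, j]`` is topic t's mean document share in ``months[j]``;
    NaN where ``coverage[j] == 0``. ``months`` is strictly increasing.
    """

    months: tuple[Month, ...]
    weights: np.ndarray  # (k, n_months), NaN for uncovered months
    coverage: tuple[int, ...]
    topic_labels: tuple[str, ...] | None = None

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    def covered(self) -> np.ndarray:
        return np.asarray(self.coverage) > 0


def monthly_weights(
    model: TopicModel, corpus: Corpus, dtm: DocumentTermMatrix
) -> EvolutionSeries:
    """Average per-document topic shares by calendar month."""
    if model.doc_topic.shape[0] != len(dtm.doc_ids):
        raise AlignmentError(
            f"model has {model.doc_topic.shape[0]} document rows but the "
            f"matrix lists {len(dtm.doc_ids)} doc_ids"
        )
    month_of = {p.post_id: p.month for p in corpus}
    try:
        doc_months = [month_of[pid] for pid in dtm.doc_ids]
    except KeyError as exc:
        raise AlignmentError(f"doc_id {exc} not found in corpus") from exc

    months = tuple(month_range(min(doc_months), max(doc_months)))
    col = {m: j for j, m in enumerate(months)}
    k = model.k
    sums = np.zeros((k, len(months)))
    counts = np.zeros(len(months), dtype=int)
    skipped = 0
    for i, m in enumerate(doc_months):
        row = model.doc_topic[i]
        total = row.sum()
        if total <= 0:
            skipped += 1
            continue
        sums[:, col[m]] += row / total
        counts[col[m]] += 1
    if skipped:
        warnings.warn(
            f"{skipped} document(s) carry zero topic mass and were excluded "
            "from monthly averaging",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        weights = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    labels = None
    if model.terms is not None:
        from .nmf import topic_label

        labels = tuple(topic_label(model, t) for t in range(k))
    return EvolutionSeries(
        months=months,
        weights=weights,
        coverage=tuple(int(c) for c in counts),
        topic_labels=labels,
    )


def period_average(
    series: EvolutionSeries, start: str | Month, end: str | Month
) -> np.ndarray:
    """Per-topic mean weight over the covered months in [start, end]."""
    start_m, end_m = parse_month(start), parse_month(end)
    mask = np.array(
        [start_m <= m <= end_m and c > 0 for m, c in zip(series.months, series.coverage)]
    )
    if not mask.any():
        raise ValueError(
            f"no covered month in [{start_m}, {end_m}] "
            f"(series spans {series.months[0]}..{series.months[-1]})"
        )
    return series.weights[:, mask].mean(axis=1)


def extreme_topics(averages: Sequence[float]) -> tuple[int, int]:
    """(most relevant, least relevant) topic index; ties to lower index."""
    avg = np.asarray(averages, dtype=np.float64)
    if avg.size < 2:
        raise ValueError("need at least 2 topics to pick extremes")
    hi = int(np.argmax(avg))
    lo = int(np.argmin(avg))
    if np.allclose(avg, avg[0]):
        warnings.warn("all period averages equal; extremes are ambiguous", stacklevel=2)
        return (0, 0)
    return (hi, lo)


def month_slice(series: EvolutionSeries, month_of_year: int) -> EvolutionSeries:
    """Restrict the series to one calendar month (e.g. every January)."""
    if not 1 <= month_of_year <= 12:
        raise ValueError(f"month_of_year must be 1..12, got {month_of_year}")
    keep = [j for j, (_, m) in enumerate(series.months) if m == month_of_year]
    return EvolutionSeries(
        months=tuple(series.months[j] for j in keep),
        weights=series.weights[:, keep],
        coverage=tuple(series.coverage[j] for j in keep),
        topic_labels=series.topic_labels,
    )


def fit_monthly_trend(series: EvolutionSeries, topic: int) -> float:
    """Least-squares slope of one topic's weight over covered months.

    Months are indexed 0, 1, 2, ... from the series start, so the slope is
    change in weight per month. Only the sign is generally meaningful.
    """
    if not 0 <= topic < series.k:
        raise IndexError(f"topic {topic} out of range")
    covered = series.covered()
    if covered.sum() < 2:
        raise ValueError("need at least 2 covered months to fit a trend")
    x = np.flatnonzero(covered).astype(float)
    y = series.weights[topic, covered]
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def save_series_csv(
    series: EvolutionSeries, path: str | Path, forum_id: str = ""
) -> None:
    """Long-format CSV: forum, topic, label, year, month, weight, n_posts.

    Both the unit-sum share (``weight``) and a x100 convenience scale
    (``weight_x100``) are written; uncovered months get empty weights.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = series.topic_labels or tuple(str(t) for t in range(series.k))
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["forum_id", "topic_index", "label", "year", "month",
             "weight", "weight_x100", "n_posts"]
        )
        for t in range(series.k):
            for j, (year, month) in enumerate(series.months):
                w = series.weights[t, j]
                writer.writerow(
                    [
                        forum_id, t, labels[t], year, month,
                        "" if np.isnan(w) else f"{w:.10f}",
                        "" if np.isnan(w) else f"{100 * w:.8f}",
                        series.coverage[j],
                    ]
                )
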