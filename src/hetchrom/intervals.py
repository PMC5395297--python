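"""Genomic intervals and interval-set operations.

All coordinates are 0-based half-open, BED-style: an interval covers bases
``start .. end-1`` and two intervals that merely abut (``a.end == b.start``)
do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "intervals_overlap",
    "merge_union",
    "overlap_fraction",
    "subtract_overlapping",
    "upset_counts",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span with an optional score and factor labels.

    Parameters
    ----------
    chrom : str
        Chromosome / sequence name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    score : float, optional
        Peak-caller score or other per-interval statistic.
    labels : frozenset of str
        Factor names associated with the interval (used by peak-set unions).
    """

    chrom: str
    start: int
    end: int
    score: float | None = None
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        """'chrom:start-end' identifier, the convention used for repeats."""
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def with_labels(self, labels: Iterable[str]) -> "GenomicInterval":
        return replace(self, labels=frozenset(labels))


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.overlaps(b)


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for lst in out.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_union(
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Union of several factors' peak sets with per-region factor labels.

    A union region is a maximal run of covered bases, so book-ended
    intervals (end == start) merge into one region even though they do not
    overlap under the half-open overlap test. Each region carries the set
    of factors contributing at least one base to it.

    Parameters
    ----------
    peak_sets : mapping of factor name -> intervals

    Returns
    -------
    list of GenomicInterval
        Sorted merged regions; ``labels`` holds the contributing factors.
    """
    if not peak_sets:
        raise ValueError("merge_union requires at least one peak set")
    tagged: list[GenomicInterval] = []
    for factor, ivs in peak_sets.items():
        tagged.extend(iv.with_labels({factor}) for iv in ivs)
    out: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(tagged)):
        ivs = _by_chrom(tagged)[chrom]
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_labels: set[str] = set(ivs[0].labels)
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # book-ended runs are contiguous coverage
                cur_end = max(cur_end, iv.end)
                cur_labels |= iv.labels
            else:
                out.append(
                    GenomicInterval(chrom, cur_start, cur_end, labels=frozenset(cur_labels))
                )
                cur_start, cur_end, cur_labels = iv.start, iv.end, set(iv.labels)
        out.append(
            GenomicInterval(chrom, cur_start, cur_end, labels=frozenset(cur_labels))
        )
    return out


def upset_counts(union: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Count union regions per exact factor combination (UpSet-style).

    Returns a DataFrame with columns ``combination`` (sorted factor names
    joined by '+') and ``count``; the counts sum to ``len(union)``.
    """
    combos: dict[str, int] = {}
    for iv in union:
        key = "+".join(sorted(iv.labels))
        combos[key] = combos.get(key, 0) + 1
    df = pd.DataFrame(
        sorted(combos.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["combination", "count"],
    )
    return df


def overlap_fraction(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> tuple[int, float]:
    """Count intervals of `a` overlapping (>=1 bp) any interval of `b`.

    Returns ``(count, count / len(a))``. Each interval of `a` counts at most
    once however many `b` intervals it hits. Call with arguments swapped for
    the symmetric question.
    """
    if not a:
        return 0, float("nan")
    b_by_chrom = _by_chrom(b)
    count = 0
    for iv in a:
        hits = b_by_chrom.get(iv.chrom, [])
        # sorted scan; fine at the scales used here
        for other in hits:
            if other.start >= iv.end:
                break
            if iv.start < other.end:
                count += 1
                break
    return count, count / len(a)


def subtract_overlapping(
    intervals: Sequence[GenomicInterval], mask: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop every interval that overlaps (>=1 bp) any interval of `mask`."""
    mask_by_chrom = _by_chrom(mask)
    kept = []
    for iv in intervals:
        if not any(
            iv.start < m.end and m.start < iv.end
            for m in mask_by_chrom.get(iv.chrom, [])
        ):
            kept.append(iv)
    return kept
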