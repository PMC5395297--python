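"""Readers and writers for the on-disk formats.

BED and bedGraph are 0-based half-open. Repeat annotations are BED6 plus
two extra columns (family, class). Count matrices are TSV with a
``sample:condition:replicate`` header convention. FASTA goes through
Biopython.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import CountMatrix
from .intervals import GenomicInterval
from .peaks import CoverageTrack
from .repeats import RepeatElement

__all__ = [
    "read_bed",
    "write_bed",
    "read_repeats_bed",
    "write_repeats_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_broods",
    "write_broods",
]


def write_bed(path, intervals: Sequence[GenomicInterval]) -> None:
    """BED6-ish: chrom, start, end, name, score, strand ('.')."""
    rows = [
        (
            iv.chrom,
            iv.start,
            iv.end,
            "+".join(sorted(iv.labels)) or iv.name,
            0.0 if iv.score is None else iv.score,
            ".",
        )
        for iv in intervals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        score = float(row[4]) if len(row) > 4 else None
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), score=score))
    return out


def write_repeats_bed(path, elements: Sequence[RepeatElement]) -> None:
    """BED6 + family, class, transposase flag, full-length flag."""
    rows = [
        (
            e.interval.chrom,
            e.interval.start,
            e.interval.end,
            e.name,
            0,
            ".",
            e.family,
            e.class_label,
            int(e.has_transposase_orf),
            int(e.is_full_length),
        )
        for e in elements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_repeats_bed(path) -> list[RepeatElement]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        RepeatElement(
            GenomicInterval(str(r[0]), int(r[1]), int(r[2])),
            family=str(r[6]),
            class_label=str(r[7]),
            has_transposase_orf=bool(int(r[8])) if len(r) > 8 else False,
            is_full_length=bool(int(r[9])) if len(r) > 9 else False,
        )
        for r in df.itertuples(index=False)
    ]


def write_bedgraph(path, track: CoverageTrack) -> None:
    """Run-length-encoded bedGraph of a per-base track."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def read_bedgraph(path, chrom_lengths: Mapping[str, int] | None = None) -> CoverageTrack:
    """Expand a bedGraph into a per-base track.

    Without ``chrom_lengths`` each chromosome's length is the largest end
    coordinate seen; uncovered bases are 0.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    lengths = dict(chrom_lengths or df.groupby("chrom")["end"].max())
    data = {c: np.zeros(int(n)) for c, n in lengths.items()}
    for row in df.itertuples(index=False):
        data[row.chrom][row.start : row.end] = row.value
    return CoverageTrack(data)


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_counts(path, cm: CountMatrix) -> None:
    """TSV, columns named 'sample:condition:replicate'."""
    rep: dict[str, int] = {}
    cols = []
    for s in cm.counts.columns:
        cond = cm.conditions[s]
        rep[cond] = rep.get(cond, 0) + 1
        cols.append(f"{s}:{cond}:{rep[cond]}")
    out = cm.counts.copy()
    out.columns = cols
    out.to_csv(path, sep="\t", index_label="feature")


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples, conds = [], []
    for col in df.columns:
        parts = col.split(":")
        if len(parts) != 3:
            raise ValueError(f"count column {col!r} is not 'sample:condition:replicate'")
        samples.append(parts[0])
        conds.append(parts[1])
    df.columns = samples
    return CountMatrix(df, pd.Series(conds, index=samples))


def write_broods(path, broods: pd.DataFrame) -> None:
    broods.to_csv(path, sep="\t", index=False)


def read_broods(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "genotype" not in df.columns or "brood" not in df.columns:
        raise ValueError("brood table needs 'genotype' and 'brood' columns")
    return df
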