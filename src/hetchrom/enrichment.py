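"""ChIP-signal scoring over repeats, telomeres, and regulated sets.

Covers three related analyses: per-element signal relative to the genome
median with Mann-Whitney family-level enrichment calls; telomeric-read
counting (GCCTAA motifs in 36-bp reads) with replicate-vs-background
enrichment tests; and H3K9me3 response scoring in nuclear-RNAi mutants
(per-region mutant/wild-type log2 fold change with a one-sided set test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval
from .peaks import CoverageTrack
from .repeats import RepeatElement
from .smallrna import revcomp

__all__ = [
    "ElementSignal",
    "element_signal",
    "family_enrichment",
    "telomere_motif_count",
    "is_telomeric_read",
    "telomere_enrichment",
    "signal_response",
    "significance_stars",
    "control_repeats",
]

TELOMERE_MOTIF = "GCCTAA"


@dataclass(frozen=True)
class ElementSignal:
    """Mean coverage over one repeat element, relative to the genome median."""

    element: RepeatElement
    mean_signal: float
    log2fc_vs_genome_median: float


def genome_median(track: CoverageTrack) -> float:
    """Median of the per-base track values across all chromosomes."""
    return float(np.median(track.concat()))


def element_signal(
    track: CoverageTrack,
    elements: Sequence[RepeatElement],
    pseudocount: float = 1.0,
) -> list[ElementSignal]:
    """Per-element mean signal and log2 fold change vs the genome median.

    The genome median is computed once over all per-base track values;
    log2fc = log2((mean + pc) / (median + pc)). Elements outside the track
    raise.
    """
    med = genome_median(track)
    out = []
    for el in elements:
        m = track.mean(el.interval)
        out.append(
            ElementSignal(el, m, float(np.log2((m + pseudocount) / (med + pseudocount))))
        )
    return out


def _background_bin_means(
    track: CoverageTrack, bin_size: int, n_bins: int, seed: int
) -> np.ndarray:
    """Mean signal in a random sample of genome-wide bins of `bin_size`."""
    rng = np.random.default_rng(seed)
    per_chrom = {
        c: len(v) // bin_size for c, v in track.data.items() if len(v) >= bin_size
    }
    total = sum(per_chrom.values())
    if total == 0:
        raise ValueError("track shorter than one background bin")
    chroms = sorted(per_chrom)
    offsets = np.cumsum([0] + [per_chrom[c] for c in chroms])
    picks = rng.choice(total, size=min(n_bins, total), replace=False)
    means = np.empty(len(picks))
    for i, p in enumerate(picks):
        ci = np.searchsorted(offsets, p, side="right") - 1
        b = p - offsets[ci]
        arr = track.data[chroms[ci]]
        means[i] = arr[b * bin_size : (b + 1) * bin_size].mean()
    return means


def family_enrichment(
    signals: Sequence[ElementSignal],
    track: CoverageTrack,
    min_members: int = 10,
    fdr_threshold: float = 0.1,
    fold_threshold: float = 1.5,
    pseudocount: float = 1.0,
    n_background_bins: int = 100_000,
    bin_size: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Family-level binding enrichment relative to the genome median.

    Families with at least ``min_members`` elements are tested with a
    one-sided Mann-Whitney U (member mean signals greater than a sample of
    genome-wide background-bin mean signals at matching resolution —
    ``bin_size`` defaults to the median element width). FDR is
    Benjamini-Hochberg across families; a family is flagged enriched iff
    FDR < ``fdr_threshold`` AND its median fold change over the genome
    median exceeds ``fold_threshold``.

    Returns a DataFrame with columns family, n_members, median_fc, p_value,
    fdr, enriched.
    """
    med = genome_median(track)
    by_family: dict[str, list[ElementSignal]] = {}
    for s in signals:
        by_family.setdefault(s.element.family, []).append(s)
    tested = {f: m for f, m in by_family.items() if len(m) >= min_members}
    if not tested:
        raise ValueError(f"no family has >= {min_members} members")
    if bin_size is None:
        widths = [s.element.interval.width for s in signals]
        bin_size = max(1, int(np.median(widths)))
    background = _background_bin_means(track, bin_size, n_background_bins, seed)
    rows = []
    for fam in sorted(tested):
        members = tested[fam]
        vals = np.array([s.mean_signal for s in members])
        fc = (vals + pseudocount) / (med + pseudocount)
        p = stats.mannwhitneyu(vals, background, alternative="greater").pvalue
        rows.append(
            {
                "family": fam,
                "n_members": len(members),
                "median_fc": float(np.median(fc)),
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows).set_index("family")
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["enriched"] = (df["fdr"] < fdr_threshold) & (df["median_fc"] > fold_threshold)
    return df


def telomere_motif_count(
    read: str, trim_to: int = 36, motif: str = TELOMERE_MOTIF
) -> int:
    """Number of telomeric motifs in the first ``trim_to`` bases of a read.

    Occurrences are counted non-overlapping left-to-right on both strands
    (forward motif and its reverse complement) and the larger strand count
    is returned — a read derives from one strand, and GCCTAA cannot overlap
    itself, so per strand this equals the total occurrence count.
    """
    if not read:
        raise ValueError("empty read")
    seq = read.upper()[:trim_to]
    return max(seq.count(motif), seq.count(revcomp(motif)))


def is_telomeric_read(read: str, trim_to: int = 36, min_motifs: int = 5) -> bool:
    """Telomeric read: 5 or 6 GCCTAA motifs in the 36-bp trimmed read."""
    return telomere_motif_count(read, trim_to) >= min_motifs


def telomere_enrichment(
    factor_fracs: Sequence[float], input_fracs: Sequence[float]
) -> float:
    """One-sided Mann-Whitney U p-value: factor telomeric-read fractions
    greater than the background (input experiments') fractions.

    Typically two replicates per factor against a large panel of input
    libraries.
    """
    if len(factor_fracs) < 1 or len(input_fracs) < 2:
        raise ValueError("need >= 1 factor value and >= 2 background values")
    return float(
        stats.mannwhitneyu(factor_fracs, input_fracs, alternative="greater").pvalue
    )


def significance_stars(p: float) -> str:
    """Star coding used in the response figures: * p<0.1, ** p<0.05, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def signal_response(
    mutant_track: CoverageTrack,
    wt_track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    all_regions: Sequence[GenomicInterval],
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, float, str]:
    """Per-region mutant/wild-type log2 fold change plus a one-sided set test.

    Each region's average signal is computed in both tracks;
    log2FC = log2((mutant + pc) / (wt + pc)). The set of interest is then
    compared to the full reference set (all genes or all repeats) with a
    one-sided Mann-Whitney U asking whether the set's fold changes are
    REDUCED relative to the reference. Returns (per-region table, p, stars).
    """
    def lfcs(rs):
        return np.array(
            [
                np.log2(
                    (mutant_track.mean(r) + pseudocount)
                    / (wt_track.mean(r) + pseudocount)
                )
                for r in rs
            ]
        )

    set_lfc = lfcs(regions)
    ref_lfc = lfcs(all_regions)
    p = float(stats.mannwhitneyu(set_lfc, ref_lfc, alternative="less").pvalue)
    df = pd.DataFrame(
        {"region": [r.name for r in regions], "log2fc": set_lfc}
    ).set_index("region")
    return df, p, significance_stars(p)


def control_repeats(
    wt_track: CoverageTrack,
    factor_tracks: Mapping[str, CoverageTrack],
    upregulated_sets: Mapping[str, set[str]],
    elements: Sequence[RepeatElement],
    min_h3k9_fold: float = 1.5,
    max_factor_fold: float = 1.0,
) -> list[RepeatElement]:
    """Repeats usable as stable controls for H3K9me3 response analyses.

    A control repeat must (i) have wild-type H3K9me3 signal more than
    ``min_h3k9_fold`` times the genome average, (ii) have signal below
    ``max_factor_fold`` times the respective genome average for every
    heterochromatin-factor track, and (iii) not be upregulated in any
    mutant strain (sets of 'chrom:start-end' names). Exact conjunction of
    the three conditions.
    """
    wt_avg = float(np.mean(wt_track.concat()))
    factor_avg = {f: float(np.mean(t.concat())) for f, t in factor_tracks.items()}
    up_any = set().union(*upregulated_sets.values()) if upregulated_sets else set()
    out = []
    for el in elements:
        if wt_track.mean(el.interval) <= min_h3k9_fold * wt_avg:
            continue
        if any(
            t.mean(el.interval) >= max_factor_fold * factor_avg[f]
            for f, t in factor_tracks.items()
        ):
            continue
        if el.name in up_any:
            continue
        out.append(el)
    return out
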