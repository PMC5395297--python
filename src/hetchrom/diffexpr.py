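"""Differential expression of genes and repeats from count matrices.

Counts are normalized with the median-of-ratios method and tested
feature-by-feature with a negative-binomial Wald test (method-of-moments
dispersion pooled across conditions, no LFC shrinkage — reported LFCs are
plain normalized-ratio estimates). On top of the per-feature tests sit the
repeat-calling filter cascade: repeats are called upregulated at FDR < 0.01
and LFC > 0, dropped when they overlap a gene upregulated at permissive
thresholds (FDR < 0.05, LFC > 0) in the same mutant, and confirmed with
uniquely mapping reads (>10 unique reads and fold change > 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

__all__ = [
    "CountMatrix",
    "UpCall",
    "size_factors",
    "nb_test",
    "call_genes",
    "call_repeats",
    "confirm_unique",
    "set_overlaps",
    "annotation_enrichment",
    "fraction_expressed",
]


@dataclass
class CountMatrix:
    """Integer counts of features x samples with per-sample condition labels.

    ``counts`` is a features-by-samples DataFrame of nonnegative integers;
    ``conditions`` maps each sample (column) to its condition label.
    Repeats are named 'chromosome:start-end'.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.duplicated().any():
            raise ValueError("feature names must be unique")
        if list(self.conditions.index) != list(self.counts.columns):
            raise ValueError("conditions must be indexed by the sample columns")

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


@dataclass
class UpCall:
    """Outcome of the repeat up-call filter cascade for one feature.

    ``filtered_reason`` is None, "gene_overlap" (overlaps a permissively
    upregulated gene) or "oscillating"; ``confirmed_unique`` is True/False
    once assessed with uniquely mapping reads, or "not_assessable" when the
    element has too few unique reads.
    """

    feature: str
    called_up: bool
    filtered_reason: str | None = None
    confirmed_unique: bool | str | None = None

    def __post_init__(self):
        if self.called_up and self.filtered_reason is not None:
            raise ValueError("a called-up feature cannot carry a filter reason")


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, the factor is the median over features i of
    ``counts[i, j] / geometric_mean_i`` where the geometric mean is taken
    across samples, restricted to features with all-positive counts.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    pos = (df > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; filter features "
            "or add a pseudocount before computing size factors"
        )
    sub = df.loc[pos].astype(float)
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def nb_test(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    design: tuple[str, str] = ("wt", "mutant"),
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature negative-binomial Wald test, ``design[1]`` vs ``design[0]``.

    LFC is log2 of the ratio of normalized group means (pseudocount on both).
    Dispersion is a per-feature method-of-moments estimate pooled across the
    two conditions (floored at 1e-8); the Wald statistic uses the
    delta-method standard error of the log ratio and a t reference
    distribution with n1 + n2 - 2 degrees of freedom, which keeps the test
    calibrated at the small replicate numbers typical of these designs.
    Features with all-zero counts get p = 1 and LFC 0. FDR is
    Benjamini-Hochberg across all features.

    Returns a DataFrame indexed by feature with columns ``mean_expr``,
    ``lfc``, ``p_value``, ``fdr``.
    """
    ref_s, alt_s = cm.samples_of(design[0]), cm.samples_of(design[1])
    if len(ref_s) < 2 or len(alt_s) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if factors is None:
        factors = size_factors(cm)
    sf = factors.reindex(cm.counts.columns).to_numpy()
    norm = cm.counts.to_numpy(dtype=float) / sf[None, :]
    iref = [cm.counts.columns.get_loc(s) for s in ref_s]
    ialt = [cm.counts.columns.get_loc(s) for s in alt_s]
    n0, n1 = len(iref), len(ialt)

    m0 = norm[:, iref].mean(axis=1)
    m1 = norm[:, ialt].mean(axis=1)
    lfc = np.log2((m1 + pseudocount) / (m0 + pseudocount))

    # pooled method-of-moments dispersion: Var(K/s) = mu/s + alpha mu^2
    inv_s0 = np.mean(1.0 / sf[iref])
    inv_s1 = np.mean(1.0 / sf[ialt])
    v0 = norm[:, iref].var(axis=1, ddof=1)
    v1 = norm[:, ialt].var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a0 = (v0 - m0 * inv_s0) / m0**2
        a1 = (v1 - m1 * inv_s1) / m1**2
    w0, w1 = n0 - 1, n1 - 1
    for a in (a0, a1):
        a[~np.isfinite(a)] = 0.0
    alpha = (w0 * a0 + w1 * a1) / (w0 + w1)
    alpha = np.clip(alpha, 1e-8, None)

    # delta-method variance of log2(m1+pc) - log2(m0+pc) under the NB model
    var_mean0 = (m0 * inv_s0 + alpha * m0**2) / n0
    var_mean1 = (m1 * inv_s1 + alpha * m1**2) / n1
    se_log = np.sqrt(
        var_mean1 / (m1 + pseudocount) ** 2 + var_mean0 / (m0 + pseudocount) ** 2
    ) / np.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se_log
    df_t = n0 + n1 - 2
    p = 2 * stats.t.sf(np.abs(wald), df=df_t)

    allzero = (cm.counts.to_numpy() == 0).all(axis=1)
    degenerate = allzero | ((m0 == 0) & (m1 == 0)) | ~np.isfinite(p)
    p[degenerate] = 1.0
    lfc = np.where(allzero, 0.0, lfc)

    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"mean_expr": (m0 + m1) / 2, "lfc": lfc, "p_value": p, "fdr": fdr},
        index=cm.counts.index,
    )


def call_genes(
    results: pd.DataFrame,
    lfc_up: float = 1.0,
    lfc_down: float = -1.0,
    fdr: float = 0.01,
    oscillating: set[str] = frozenset(),
) -> tuple[set[str], set[str]]:
    """Up/down gene sets at FDR and LFC thresholds, minus oscillating genes.

    Genes whose wild-type expression oscillates during development are
    excluded from both sets (the list is supplied externally).
    """
    sig = results["fdr"] < fdr
    up = set(results.index[sig & (results["lfc"] > lfc_up)]) - set(oscillating)
    down = set(results.index[sig & (results["lfc"] < lfc_down)]) - set(oscillating)
    return up, down


def call_repeats(
    repeat_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    repeat_annotation: Mapping[str, GenomicInterval],
    gene_annotation: Mapping[str, GenomicInterval],
    repeat_fdr: float = 0.01,
    gene_fdr: float = 0.05,
    extend_gene_upstream: int = 0,
) -> list[UpCall]:
    """Repeat up-calls with the gene-overlap filter.

    A repeat passes the primary thresholds at FDR < ``repeat_fdr`` and
    LFC > 0. It is then filtered out (reason "gene_overlap") if its
    interval overlaps, by at least one base, any gene upregulated at the
    permissive thresholds FDR < ``gene_fdr`` and LFC > 0 in the same
    comparison. ``extend_gene_upstream`` optionally extends each gene
    interval upstream (toward lower coordinates) before the overlap test.
    Only repeats passing the primary thresholds are returned.
    """
    up_genes = gene_results.index[
        (gene_results["fdr"] < gene_fdr) & (gene_results["lfc"] > 0)
    ]
    gene_ivs = []
    for g in up_genes:
        iv = gene_annotation.get(g)
        if iv is None:
            raise ValueError(f"no annotation for upregulated gene {g}")
        gene_ivs.append(
            GenomicInterval(iv.chrom, max(0, iv.start - extend_gene_upstream), iv.end)
        )
    passing = repeat_results.index[
        (repeat_results["fdr"] < repeat_fdr) & (repeat_results["lfc"] > 0)
    ]
    calls = []
    for r in sorted(passing):
        iv = repeat_annotation.get(r)
        if iv is None:
            raise ValueError(f"no annotation for repeat {r}")
        hit = any(iv.overlaps(g) for g in gene_ivs)
        calls.append(
            UpCall(r, called_up=not hit, filtered_reason="gene_overlap" if hit else None)
        )
    return calls


def confirm_unique(
    mutant_unique: Sequence[float],
    wt_unique: Sequence[float],
    mutant_sf: Sequence[float] | None = None,
    wt_sf: Sequence[float] | None = None,
    min_reads: int = 10,
    min_fc: float = 1.5,
    pseudocount: float = 0.5,
) -> bool | str:
    """Confirm an up-called repeat with uniquely mapping (mapq > 10) reads.

    Requires strictly more than ``min_reads`` raw unique reads in the mutant
    to assess at all (otherwise "not_assessable"), then confirms when the
    normalized unique-read fold change (mutant over wild type, same size
    factors as the main analysis) exceeds ``min_fc``.
    """
    mu = np.asarray(mutant_unique, dtype=float)
    wu = np.asarray(wt_unique, dtype=float)
    if mu.sum() <= min_reads:
        return "not_assessable"
    msf = np.ones_like(mu) if mutant_sf is None else np.asarray(mutant_sf, dtype=float)
    wsf = np.ones_like(wu) if wt_sf is None else np.asarray(wt_sf, dtype=float)
    fc = ((mu / msf).mean() + pseudocount) / ((wu / wsf).mean() + pseudocount)
    return bool(fc > min_fc)


def set_overlaps(up_sets: Mapping[str, set]) -> pd.DataFrame:
    """Venn-style table: count of features per exact strain combination.

    Each feature in the union of the sets is assigned to the combination of
    strains that contain it; counts sum to the union size.
    """
    union: set = set().union(*up_sets.values()) if up_sets else set()
    combos: dict[str, int] = {}
    for f in union:
        key = "+".join(sorted(s for s, members in up_sets.items() if f in members))
        combos[key] = combos.get(key, 0) + 1
    return pd.DataFrame(
        sorted(combos.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["combination", "count"],
    )


def annotation_enrichment(
    up_set_size: int,
    flagged_in_up: int,
    genome_total: int,
    flagged_total: int,
) -> tuple[float, float]:
    """Fold enrichment of an annotation flag in an upregulated set.

    fold = (k/n) / (K/N) for k flagged among the n upregulated features,
    against K flagged among all N features. The companion p-value is the
    hypergeometric upper tail P(X >= k).
    """
    n, k, N, K = up_set_size, flagged_in_up, genome_total, flagged_total
    if not (0 < n <= N and 0 <= k <= n and 0 < K <= N):
        raise ValueError("invalid contingency counts")
    fold = (k / n) / (K / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return fold, p


def fraction_expressed(
    genes_with_bound_repeat: set, expressed: set
) -> tuple[int, float]:
    """How many genes carrying a factor-bound repeat are themselves expressed."""
    if not genes_with_bound_repeat:
        raise ValueError("empty gene set")
    k = len(genes_with_bound_repeat & expressed)
    return k, k / len(genes_with_bound_repeat)
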