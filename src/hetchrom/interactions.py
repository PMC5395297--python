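"""Genetic-interaction and phenotype statistics.

The fertility null model is multiplicative: if two genes do not interact,
the expected brood size of the double mutant is the product of the single
mutants' broods divided by the wild-type brood. Double mutants laying
significantly fewer progeny than this expectation show synthetic (synergistic)
sterility. Companion tests cover dead-embryo proportions, two-proportion
z tests, Fisher exact tests, and apoptotic-corpse comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest as _sm_proportions_ztest

__all__ = [
    "InteractionResult",
    "expected_multiplicative",
    "interaction_test",
    "dead_embryo_test",
    "proportions_ztest",
    "fisher_test",
    "apoptosis_test",
]


@dataclass(frozen=True)
class InteractionResult:
    """One-sided test of a double mutant against the multiplicative null."""

    expected_double: float
    observed_mean: float
    p_value: float
    test: str
    direction: str = "lower-than-expected"


def expected_multiplicative(wt_mean: float, a_mean: float, b_mean: float) -> float:
    """Expected double-mutant brood under no interaction: a * b / wt.

    Symmetric in the two single mutants; if one single equals wild type the
    expectation reduces to the other single's brood.
    """
    if wt_mean <= 0:
        raise ValueError("wild-type mean brood must be > 0")
    return a_mean * b_mean / wt_mean


def _group(broods: pd.DataFrame, genotype: str) -> np.ndarray:
    vals = broods.loc[broods["genotype"] == genotype, "brood"].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError(f"no animals with genotype {genotype!r}")
    return vals


def interaction_test(
    broods: pd.DataFrame,
    test: str = "t",
    genotypes: tuple[str, str, str, str] = ("wt", "a", "b", "double"),
    propagate_uncertainty: bool = False,
) -> InteractionResult:
    """One-sided test of double-mutant broods below the multiplicative null.

    ``broods`` has columns ``genotype`` and ``brood`` with the four groups
    named by ``genotypes`` (wild type, single A, single B, double).

    * ``test="t"``: one-sample one-sided t-test of the double-mutant broods
      against the plug-in expected value a_mean * b_mean / wt_mean. This
      treats the expectation as a known constant. With
      ``propagate_uncertainty=True`` the sampling noise of the wild-type
      and single-mutant means is propagated into the standard error by the
      delta method (Welch-Satterthwaite degrees of freedom), which keeps
      the test calibrated when the reference broods are themselves noisy.
    * ``test="mann_whitney"``: one-sided Mann-Whitney U comparing the
      double-mutant broods against single-A broods rescaled by
      b_mean / wt_mean (a sample-vs-sample realization of the same null).
    """
    wt, a, b, d = (_group(broods, g) for g in genotypes)
    if len(d) < 2:
        raise ValueError("need >= 2 double-mutant animals")
    expected = expected_multiplicative(wt.mean(), a.mean(), b.mean())
    observed = float(d.mean())

    if test == "t":
        if propagate_uncertainty:
            # delta-method variance of E = a_mean * b_mean / wt_mean
            comps = []
            for grp in (a, b, wt):
                comps.append(expected**2 * grp.var(ddof=1) / len(grp) / grp.mean() ** 2)
            comps.append(d.var(ddof=1) / len(d))
            se = float(np.sqrt(sum(comps)))
            ns = [len(a), len(b), len(wt), len(d)]
            dof = se**4 / sum(c**2 / (n - 1) for c, n in zip(comps, ns))
            tstat = (observed - expected) / se
            p = float(stats.t.cdf(tstat, df=dof))
        else:
            res = stats.ttest_1samp(d, popmean=expected, alternative="less")
            p = float(res.pvalue)
    elif test == "mann_whitney":
        reference = a * (b.mean() / wt.mean())
        p = float(stats.mannwhitneyu(d, reference, alternative="less").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return InteractionResult(expected, observed, p, test)


def dead_embryo_test(
    double_props: Sequence[float], single_props: Sequence[float]
) -> float:
    """One-sided Mann-Whitney U: double mutants' per-animal dead-embryo
    proportions greater than the single mutant's."""
    if len(double_props) < 2 or len(single_props) < 2:
        raise ValueError("need >= 2 animals per group")
    return float(
        stats.mannwhitneyu(double_props, single_props, alternative="greater").pvalue
    )


def proportions_ztest(
    k1: int, n1: int, k2: int, n2: int, tails: int = 2
) -> tuple[float, float]:
    """Pooled-variance two-proportion z test (two-tailed by default)."""
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    alternative = "two-sided" if tails == 2 else "larger"
    z, p = _sm_proportions_ztest([k1, k2], [n1, n2], alternative=alternative)
    return float(z), float(p)


def fisher_test(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def apoptosis_test(
    mutant_counts: Sequence[float], control_counts: Sequence[float]
) -> float:
    """Two-sided Mann-Whitney U on per-gonad apoptotic-cell counts.

    Ties are handled by the default tie-corrected procedure (exact
    enumeration when sample sizes are small and there are no ties, normal
    approximation with tie correction otherwise).
    """
    if len(mutant_counts) == 0 or len(control_counts) == 0:
        raise ValueError("both samples must be non-empty")
    return float(
        stats.mannwhitneyu(mutant_counts, control_counts, alternative="two-sided").pvalue
    )
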