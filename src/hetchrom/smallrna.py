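"""piRNA target prediction and 22G siRNA assignment.

piRNAs are 21-nt small RNAs that guide the Argonaute PRG-1 to partially
complementary sites on transcripts. A candidate 21-nt site is accepted when
the antisense alignment has a perfect seed (piRNA nt 2-8) with at most one
G:U wobble pair, and at most two mismatches plus one additional G:U pair
outside the seed. Targeting triggers synthesis of secondary 22G siRNAs,
which are counted as piRNA-dependent when they map (with <=1 mismatch)
within a 100 bp window centered on a predicted target site.

Sequences are stored in the DNA alphabet (U -> T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PiRNARecord",
    "TargetSite",
    "SmallRead",
    "revcomp",
    "pair_class",
    "find_targets",
    "assign_22g",
    "subsample_positions",
    "class_ratios",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

SEED_START, SEED_END = 1, 8  # piRNA nt 2-8, 0-based half-open


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PiRNARecord:
    """A 21-nt piRNA; ``source`` names its genomic locus (for self-hit exclusion)."""

    id: str
    sequence: str
    source: str | None = None

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) != 21:
            raise ValueError(f"piRNA {self.id} must be 21 nt, got {len(seq)}")
        if set(seq) - set("ACGT"):
            raise ValueError(f"piRNA {self.id} has non-ACGT(U) characters")


@dataclass(frozen=True)
class TargetSite:
    """A predicted piRNA target locus on a transcript's sense strand.

    ``position`` is the 0-based offset of the 21-nt site start. The pairing
    budget counters refer to the accepted alignment.
    """

    pirna_id: str
    feature_id: str
    position: int
    seed_gu: int
    outer_mismatches: int
    outer_gu: int

    @property
    def center(self) -> int:
        return self.position + 10

    def __post_init__(self):
        if self.seed_gu > 1 or self.outer_mismatches > 2 or self.outer_gu > 1:
            raise ValueError("target site exceeds the pairing budget")


@dataclass(frozen=True)
class SmallRead:
    """A mapped small-RNA read. 22G reads are 22 nt starting with G."""

    sequence: str
    feature: str
    start: int
    strand: str = "-"
    mismatches: int = 0

    @property
    def is_22g(self) -> bool:
        return len(self.sequence) == 22 and self.sequence.startswith("G")


def pair_class(pirna_base: str, target_base: str) -> str:
    """Classify an antisense base pair: 'match', 'gu', or 'mismatch'.

    ``target_base`` is on the transcript's sense strand (DNA alphabet), so
    Watson-Crick pairing means the two bases are complementary. G:U wobble:
    piRNA G opposite target T (= U in RNA), or piRNA T (= U) opposite
    target G.
    """
    p, t = pirna_base.upper(), target_base.upper()
    if t == p.translate(_COMP):
        return "match"
    if (p, t) in (("G", "T"), ("T", "G")):
        return "gu"
    return "mismatch"


def _site_counters(pirna_seq: str, window: str) -> tuple[int, int, int, int] | None:
    """Pairing counters for a 21-nt window, or None if the rule rejects it.

    The piRNA binds antiparallel: piRNA nt i (0-based from its 5' end)
    pairs with window base 20 - i.
    """
    seed_gu = seed_mm = outer_gu = outer_mm = 0
    for i in range(21):
        cls = pair_class(pirna_seq[i], window[20 - i])
        in_seed = SEED_START <= i < SEED_END
        if cls == "gu":
            if in_seed:
                seed_gu += 1
            else:
                outer_gu += 1
        elif cls == "mismatch":
            if in_seed:
                return None  # perfect seed required
            outer_mm += 1
        if seed_gu > 1 or outer_mm > 2 or outer_gu > 1:
            return None
    return seed_gu, seed_mm, outer_mm, outer_gu


def find_targets(
    pirna: PiRNARecord,
    transcript: str,
    feature_id: str,
    exclude_self: str | None = None,
) -> list[TargetSite]:
    """All 21-nt windows of a transcript satisfying the piRNA targeting rule.

    Every window of the transcript's sense strand is scanned with the piRNA
    antiparallel. Accepted iff the seed (piRNA nt 2-8) has zero mismatches
    and at most one G:U, and the remaining 14 positions (including nt 1)
    have at most two mismatches and at most one G:U. Self hits (the piRNA's
    own locus) are excluded by feature identifier.
    """
    if exclude_self is None:
        exclude_self = pirna.source
    if feature_id == exclude_self:
        return []
    transcript = transcript.upper().replace("U", "T")
    if len(transcript) < 21:
        return []
    sites = []
    for p in range(len(transcript) - 20):
        res = _site_counters(pirna.sequence, transcript[p : p + 21])
        if res is not None:
            seed_gu, _, outer_mm, outer_gu = res
            sites.append(
                TargetSite(pirna.id, feature_id, p, seed_gu, outer_mm, outer_gu)
            )
    return sites


def assign_22g(
    targets: Sequence[TargetSite],
    reads: Sequence[SmallRead],
    window: int = 100,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Flag reads as piRNA-dependent by proximity to a target site.

    A read is piRNA-dependent iff its mapped start lies within
    ``[center - window/2, center + window/2)`` of some target-site center
    on the same feature, and it mapped with at most ``max_mismatch``
    mismatches. Returns one row per read with columns ``feature``,
    ``start``, ``mismatches``, ``assigned``; the summary counts
    (``attrs["n_assigned"]``, ``attrs["n_features_hit"]``) count unique
    assigned reads and distinct target features hit.
    """
    half = window // 2
    centers: dict[str, np.ndarray] = {}
    for t in targets:
        centers.setdefault(t.feature_id, [])
    for t in targets:
        centers[t.feature_id].append(t.center)
    centers = {k: np.asarray(sorted(v)) for k, v in centers.items()}
    rows = []
    features_hit: set[str] = set()
    for r in reads:
        assigned = False
        if r.mismatches <= max_mismatch and r.feature in centers:
            c = centers[r.feature]
            # start in [center - half, center + half)  <=>  center in (start - half, start + half]
            lo = np.searchsorted(c, r.start - half, side="right")
            hi = np.searchsorted(c, r.start + half, side="right")
            assigned = hi > lo
        if assigned:
            features_hit.add(r.feature)
        rows.append(
            {
                "feature": r.feature,
                "start": r.start,
                "mismatches": r.mismatches,
                "assigned": assigned,
            }
        )
    df = pd.DataFrame(rows, columns=["feature", "start", "mismatches", "assigned"])
    df.attrs["n_assigned"] = int(df["assigned"].sum()) if len(df) else 0
    df.attrs["n_features_hit"] = len(features_hit)
    return df


def subsample_positions(
    datasets: Mapping[str, Iterable[tuple]],
    seed: int = 0,
) -> dict[str, list[tuple]]:
    """Depth-match datasets by subsampling unique positions without replacement.

    Each dataset is reduced to its set of unique (sequence, position)
    entries; the smallest set size across datasets is then drawn without
    replacement from every dataset. Deterministic given the seed.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    uniq = {name: sorted(set(vals)) for name, vals in datasets.items()}
    m = min(len(v) for v in uniq.values())
    rng = np.random.default_rng(seed)
    out = {}
    for name, vals in uniq.items():
        idx = rng.choice(len(vals), size=m, replace=False)
        out[name] = [vals[i] for i in sorted(idx)]
    return out


def class_ratios(
    mutant_counts: Mapping[str, float],
    wt_counts: Mapping[str, float],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-class log2(mutant / wt) abundance ratios on depth-matched counts.

    A class absent from both conditions is reported as NaN rather than 0.
    """
    classes = sorted(set(mutant_counts) | set(wt_counts))
    vals = {}
    for c in classes:
        m, w = mutant_counts.get(c, 0), wt_counts.get(c, 0)
        if m == 0 and w == 0:
            vals[c] = np.nan
        else:
            vals[c] = float(np.log2((m + pseudocount) / (w + pseudocount)))
    return pd.Series(vals, name="log2_ratio")
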