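"""Synthetic data generators for every pipeline stage.

Each generator is deterministic given its seed and returns, alongside the
data, a machine-readable ground-truth object so downstream stages can be
checked for parameter recovery. The generators emulate the statistical
structure the analysis assumes:

* a toy genome with a family-structured repeat annotation (Dfam-style);
* per-base coverage tracks with planted unimodal bumps over Poisson
  background noise;
* negative-binomial count matrices with planted log2 fold changes;
* 36-bp reads with planted tandem-GCCTAA telomeric reads (phase offsets
  0-5 so motif counting is exercised off-frame);
* 21-nt piRNAs with planted antisense target sites and 22G reads near
  those sites;
* brood-size tables under multiplicative or sub-multiplicative genetic
  interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .intervals import GenomicInterval
from .peaks import CoverageTrack
from .repeats import REPEAT_CLASSES, RepeatElement
from .smallrna import PiRNARecord, SmallRead, revcomp

__all__ = [
    "SyntheticGenomeSpec",
    "FamilySpec",
    "PlantedEffect",
    "PlantedBump",
    "make_genome",
    "make_coverage",
    "make_counts",
    "make_reads",
    "make_smallrna",
    "make_broods",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """One repeat family in the synthetic catalog.

    ``n_members`` instances are placed, with lengths drawn from a normal
    distribution around ``mean_length`` (sd = ``length_sd``, floored at 30
    bp). ``has_transposase`` marks every member as overlapping a predicted
    transposase ORF.
    """

    name: str
    class_label: str
    n_members: int
    mean_length: float = 300.0
    length_sd: float = 100.0
    has_transposase: bool = False

    def __post_init__(self):
        if self.class_label not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.class_label!r}")
        if self.n_members < 0:
            raise ValueError("n_members must be >= 0")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Specification of the toy genome and its repeat annotation.

    ``family_catalog`` member counts are exact: the annotation contains the
    sum of ``n_members`` elements unless ``repeat_density`` is 0, which
    forces an empty annotation. If the catalog's expected footprint exceeds
    what can be packed into the genome (or exceeds ``repeat_density`` when
    that is set above 0), generation fails rather than silently dropping
    elements.
    """

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    repeat_density: float | None = None
    family_catalog: tuple[FamilySpec, ...] = (
        FamilySpec("HELITRON_S1", "Helitron", 12, 250.0, 50.0),
        FamilySpec("MIRAGE_S1", "Cut and paste", 12, 400.0, 100.0, has_transposase=True),
        FamilySpec("LTR_S1", "LTR", 12, 350.0, 100.0),
        FamilySpec("LINE_S1", "LINE", 8, 500.0, 150.0),
        FamilySpec("SAT_S1", "Satellite", 6, 150.0, 30.0),
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need >= 1 chromosome of positive length")
        if self.repeat_density is not None and not (0 <= self.repeat_density <= 1):
            raise ValueError("repeat_density must be in [0, 1]")


@dataclass(frozen=True)
class PlantedEffect:
    """A feature with a nonzero true log2 fold change in one condition.

    Features not listed in any PlantedEffect have true_lfc = 0.
    """

    feature_id: str
    true_lfc: float
    condition: str = "mutant"


@dataclass(frozen=True)
class PlantedBump:
    """A unimodal coverage bump: Gaussian (sigma = width/4) or flat-top."""

    chrom: str
    center: int
    height: float
    width: int = 400
    shape: str = "gaussian"

    def __post_init__(self):
        if self.height < 0:
            raise ValueError("bump height must be >= 0")
        if self.shape not in ("gaussian", "flat_top"):
            raise ValueError(f"unknown bump shape {self.shape!r}")


def make_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], list[RepeatElement]]:
    """Random genome plus a non-overlapping family-structured repeat annotation.

    Returns ``(sequences, elements)`` where ``sequences`` maps chromosome
    name -> uppercase DNA string and ``elements`` is sorted by position.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    seqs = {c: "".join(rng.choice(_BASES, size=spec.chrom_length)) for c in chroms}

    if spec.repeat_density == 0:
        return seqs, []

    lengths: list[int] = []
    fams: list[FamilySpec] = []
    for fam in spec.family_catalog:
        for _ in range(fam.n_members):
            lengths.append(max(30, int(round(rng.normal(fam.mean_length, fam.length_sd)))))
            fams.append(fam)
    genome_len = spec.n_chromosomes * spec.chrom_length
    footprint = sum(lengths) / genome_len
    budget = spec.repeat_density if spec.repeat_density is not None else 0.8
    if footprint > budget:
        raise ValueError(
            f"repeat footprint {footprint:.2f} exceeds achievable packing "
            f"(budget {budget:.2f}); reduce catalog or enlarge genome"
        )

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    elements: list[RepeatElement] = []
    order = rng.permutation(len(lengths))  # long elements not always last
    for idx in order:
        length, fam = lengths[idx], fams[idx]
        placed = False
        for _ in range(1000):
            chrom = chroms[rng.integers(spec.n_chromosomes)]
            start = int(rng.integers(0, spec.chrom_length - length + 1))
            end = start + length
            if all(end <= s or e <= start for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                elements.append(
                    RepeatElement(
                        GenomicInterval(chrom, start, end),
                        family=fam.name,
                        class_label=fam.class_label,
                        has_transposase_orf=fam.has_transposase,
                        is_full_length=length >= fam.mean_length,
                    )
                )
                placed = True
                break
        if not placed:
            raise ValueError("could not place repeat elements; packing too dense")
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return seqs, elements


def make_coverage(
    chrom_lengths: Mapping[str, int],
    bumps: Sequence[PlantedBump] = (),
    baseline: float = 10.0,
    noise: str = "poisson",
    seed: int = 0,
) -> CoverageTrack:
    """Per-base coverage: baseline (+ Poisson noise) plus planted bumps.

    ``noise="poisson"`` draws each base from Poisson(baseline) before adding
    the bumps (a stand-in background model; real ChIP background is more
    structured). ``noise="none"`` gives the exact baseline. The result is
    nonnegative everywhere.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        if noise == "poisson":
            arr = rng.poisson(baseline, size=length).astype(float)
        elif noise == "none":
            arr = np.full(length, float(baseline))
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        data[chrom] = arr
    for b in bumps:
        if b.chrom not in data or not (0 <= b.center < len(data[b.chrom])):
            raise ValueError(f"bump center {b.chrom}:{b.center} outside genome")
        arr = data[b.chrom]
        x = np.arange(len(arr))
        if b.shape == "gaussian":
            sigma = b.width / 4
            arr += b.height * np.exp(-((x - b.center) ** 2) / (2 * sigma**2))
        else:  # flat_top: plateau of b.width with linear ramps of width//2
            half, ramp = b.width // 2, max(1, b.width // 2)
            lo, hi = max(0, b.center - half - ramp), min(len(arr), b.center + half + ramp + 1)
            d = np.abs(x[lo:hi] - b.center)
            arr[lo:hi] += b.height * np.clip((half + ramp - d) / ramp, 0, 1)
    return CoverageTrack(data)


def make_counts(
    n_features: int,
    n_samples_per_group: int,
    dispersion: float = 0.1,
    planted: Sequence[PlantedEffect] = (),
    base_mean: float | np.ndarray = 100.0,
    size_factors: Sequence[float] | None = None,
    conditions: tuple[str, str] = ("wt", "mutant"),
    feature_prefix: str = "feat",
    seed: int = 0,
) -> tuple[CountMatrix, dict]:
    """NB-distributed count matrix with planted log2 fold changes.

    Counts for feature i in sample j are drawn
    ``NB(mean = base_mean_i * sf_j * 2^(lfc_i * [j in mutant group]),
    var = mu + dispersion * mu^2)``; ``dispersion = 0`` gives Poisson.
    Returns the matrix and a truth dict with the per-sample size factors
    and per-feature true LFCs.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if n_samples_per_group < 1:
        raise ValueError("need >= 1 sample per group")
    rng = np.random.default_rng(seed)
    features = [f"{feature_prefix}_{i}" for i in range(n_features)]
    lfc = np.zeros(n_features)
    idx = {f: i for i, f in enumerate(features)}
    for eff in planted:
        if eff.feature_id not in idx:
            raise ValueError(f"planted effect on unknown feature {eff.feature_id}")
        lfc[idx[eff.feature_id]] = eff.true_lfc
    base = np.broadcast_to(np.asarray(base_mean, dtype=float), (n_features,))
    n_samples = 2 * n_samples_per_group
    sf = (
        np.ones(n_samples)
        if size_factors is None
        else np.asarray(size_factors, dtype=float)
    )
    if len(sf) != n_samples:
        raise ValueError("size_factors must have one entry per sample")
    group = np.repeat([0.0, 1.0], n_samples_per_group)
    mu = base[:, None] * sf[None, :] * 2.0 ** (lfc[:, None] * group[None, :])
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n_nb = 1.0 / dispersion
        counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
    samples = [
        f"{conditions[g]}_{r + 1}"
        for g in (0, 1)
        for r in range(n_samples_per_group)
    ]
    cond = [conditions[0]] * n_samples_per_group + [conditions[1]] * n_samples_per_group
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        conditions=pd.Series(cond, index=samples),
    )
    truth = {"size_factors": sf.copy(), "true_lfc": pd.Series(lfc, index=features)}
    return cm, truth


_TELO_MOTIF = "GCCTAA"


def make_reads(
    n_reads: int,
    read_length: int = 36,
    telomeric_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Short reads, a planted fraction of which are tandem telomeric repeats.

    Telomeric reads are tandem GCCTAA copies read at a random phase offset
    0-5, so a 36-bp telomeric read carries 5 or 6 complete motifs depending
    on frame. Half the telomeric reads are emitted as the reverse
    complement (TTAGGC repeats), as reads sample both strands. Returns
    ``(reads, is_telomeric)``.
    """
    if not (0 <= telomeric_fraction <= 1):
        raise ValueError("telomeric_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    is_telo = rng.random(n_reads) < telomeric_fraction
    tandem = _TELO_MOTIF * (read_length // len(_TELO_MOTIF) + 2)
    reads: list[str] = []
    for telo in is_telo:
        if telo:
            off = int(rng.integers(0, len(_TELO_MOTIF)))
            seq = tandem[off : off + read_length]
            if rng.random() < 0.5:
                seq = revcomp(seq)
        else:
            seq = "".join(rng.choice(_BASES, size=read_length))
        reads.append(seq)
    return reads, is_telo


def _mutate_non_pairing(base: str, rng: np.random.Generator) -> str:
    """A base that neither Watson-Crick pairs nor G:U wobbles as a target base."""
    from .smallrna import pair_class

    comp = revcomp(base)
    choices = [b for b in "ACGT" if pair_class(comp, b) == "mismatch"]
    return str(rng.choice(choices))


def make_smallrna(
    n_pirnas: int = 40,
    n_transcripts: int = 10,
    transcript_length: int = 2000,
    n_planted_targets: int = 20,
    planted_seed_mismatches: int = 0,
    n_22g: int = 100,
    g22_max_offset: int = 45,
    seed: int = 0,
) -> tuple[list[PiRNARecord], dict[str, str], list[SmallRead], dict]:
    """21-nt piRNAs, transcripts with planted antisense target sites, 22G reads.

    Planted sites are perfect reverse complements of the piRNA embedded in a
    transcript (so they satisfy the targeting rule by construction), unless
    ``planted_seed_mismatches`` > 0, in which case that many seed positions
    (piRNA nt 2-8) are mutated to non-pairing bases. 22G reads start within
    ``g22_max_offset`` bases of a planted site center; the truth dict
    records every planted site and each read's distance to its site.
    """
    rng = np.random.default_rng(seed)
    transcripts = {
        f"tx_{i}": "".join(rng.choice(_BASES, size=transcript_length))
        for i in range(n_transcripts)
    }
    pirnas = [
        PiRNARecord(
            id=f"pirna_{i}",
            sequence="T" + "".join(rng.choice(_BASES, size=20)),
            source=f"pirna_locus_{i}",
        )
        for i in range(n_pirnas)
    ]
    if n_planted_targets > n_pirnas:
        raise ValueError("cannot plant more targets than piRNAs")
    tx_ids = list(transcripts)
    planted: list[dict] = []
    seqs = {k: list(v) for k, v in transcripts.items()}
    # non-overlapping slots so plants do not clobber each other
    slots_per_tx = (transcript_length - 100) // 50
    slots = [(t, 50 + j * 50) for t in tx_ids for j in range(max(0, slots_per_tx - 1)) if 50 + j * 50 + 21 <= transcript_length]
    rng.shuffle(slots)
    for i in range(n_planted_targets):
        pir = pirnas[i]
        tx, pos = slots[i]
        site = list(revcomp(pir.sequence))
        if planted_seed_mismatches:
            # piRNA nt k (0-based) pairs with site offset 20-k
            seed_nts = rng.choice(np.arange(1, 8), size=planted_seed_mismatches, replace=False)
            for k in seed_nts:
                site[20 - int(k)] = _mutate_non_pairing(pir.sequence[int(k)], rng)
        seqs[tx][pos : pos + 21] = site
        planted.append({"pirna_id": pir.id, "feature_id": tx, "position": pos})
    transcripts = {k: "".join(v) for k, v in seqs.items()}

    reads: list[SmallRead] = []
    read_truth: list[dict] = []
    for _ in range(n_22g):
        near_site = bool(planted) and rng.random() < 0.7
        if near_site:
            site = planted[int(rng.integers(len(planted)))]
            center = site["position"] + 10
            start = int(np.clip(center + rng.integers(-g22_max_offset, g22_max_offset + 1),
                                0, transcript_length - 22))
            tx = site["feature_id"]
        else:
            tx = tx_ids[int(rng.integers(n_transcripts))]
            start = int(rng.integers(0, transcript_length - 22))
        mm = int(rng.integers(0, 2))
        seq = "G" + revcomp(transcripts[tx][start : start + 21])[1:]
        reads.append(SmallRead(sequence=seq, feature=tx, start=start, strand="-", mismatches=mm))
        read_truth.append({"feature": tx, "start": start, "planted_near_site": near_site})
    truth = {"planted_sites": planted, "reads": read_truth}
    return pirnas, transcripts, reads, truth


def make_broods(
    wt_mean: float = 250.0,
    a_effect: float = 0.6,
    b_effect: float = 0.6,
    interaction: str = "multiplicative",
    sub_fraction: float = 0.3,
    n_per_genotype: int = 12,
    noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Brood-size table under a multiplicative or sub-multiplicative model.

    Group means: wt = ``wt_mean``; singles = wt x effect; double =
    wt x a x b under "multiplicative", or ``sub_fraction`` of that under
    "sub_multiplicative" (synthetic sterility). Per-animal broods are
    normal around the group mean (sd = ``noise_sd``, default 10% of the
    group mean), clipped at 0 and rounded. Returns the table (columns
    genotype, animal, brood) and a truth dict of the group means.
    """
    if interaction not in ("multiplicative", "sub_multiplicative"):
        raise ValueError(f"unknown interaction model {interaction!r}")
    if wt_mean <= 0:
        raise ValueError("wt_mean must be > 0")
    rng = np.random.default_rng(seed)
    double = wt_mean * a_effect * b_effect
    if interaction == "sub_multiplicative":
        double *= sub_fraction
    means = {
        "wt": wt_mean,
        "a": wt_mean * a_effect,
        "b": wt_mean * b_effect,
        "double": double,
    }
    rows = []
    for gt, mu in means.items():
        sd = 0.1 * mu if noise_sd is None else noise_sd
        broods = np.clip(np.round(rng.normal(mu, sd, size=n_per_genotype)), 0, None)
        if sd == 0:
            broods = np.full(n_per_genotype, round(mu))
        for i, b in enumerate(broods):
            rows.append({"genotype": gt, "animal": f"{gt}_{i + 1}", "brood": int(b)})
    table = pd.DataFrame(rows)
    return table, {"group_means": means, "interaction": interaction}
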