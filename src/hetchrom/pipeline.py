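"""End-to-end synthetic demonstration pipeline and its configuration.

``run_demo`` generates a full synthetic fixture (genome, coverage, counts,
reads, small RNAs, broods), runs every analysis stage with the default
thresholds, checks each stage against the generator's ground truth, and
returns a nested report. Deterministic per seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, interactions, intervals, peaks, smallrna, synth
from .intervals import GenomicInterval

log = logging.getLogger("hetchrom")

__all__ = ["PipelineConfig", "StageError", "run_demo"]


@dataclass
class PipelineConfig:
    """All analysis thresholds, defaulting to the published values."""

    curvature_kernel_bp: int = 250
    curvature_threshold: float = -500.0
    peak_min_score: float = 100.0
    peak_min_width: int = 100
    family_fdr: float = 0.1
    family_fold: float = 1.5
    family_min_members: int = 10
    de_fdr: float = 0.01
    gene_filter_fdr: float = 0.05
    unique_min_reads: int = 10
    unique_min_fc: float = 1.5
    g22_window: int = 100
    g22_max_mismatch: int = 1
    telomere_min_motifs: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
        cfg = cls(**raw)
        for f in dataclasses.fields(cls):
            if getattr(cfg, f.name) is None:
                raise ValueError(f"missing config key: {f.name!r}")
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                log.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc

        return wrapper

    return deco


FACTORS = ("hpl-2", "lin-13", "lin-61", "let-418", "met-2")


@_stage("peaks")
def _demo_peaks(cfg: PipelineConfig, rng: np.random.Generator, chrom_lengths):
    """Plant factor-specific coverage bumps, refine, union, UpSet."""
    # co-binding design: bump centers shared by nested subsets of factors
    centers = {
        "chr1": list(range(5_000, 95_000, 6_000)),
        "chr2": list(range(8_000, 92_000, 9_000)),
    }
    design: dict[str, list[synth.PlantedBump]] = {f: [] for f in FACTORS}
    truth_counts: dict[str, int] = {}
    all_sites = [(c, x) for c, xs in centers.items() for x in xs]
    for i, (c, x) in enumerate(all_sites):
        k = (i % len(FACTORS)) + 1  # bound by the first k factors
        for f in FACTORS[:k]:
            design[f].append(synth.PlantedBump(c, x, height=400, width=400))
        key = "+".join(sorted(FACTORS[:k]))
        truth_counts[key] = truth_counts.get(key, 0) + 1
    # a double bump inside one broad peak for every factor
    for f in FACTORS:
        design[f].append(synth.PlantedBump("chr1", 97_000, 400, 300))
        design[f].append(synth.PlantedBump("chr1", 97_300, 400, 300))

    concave_sets: dict[str, list[GenomicInterval]] = {}
    split_ok = True
    for fi, f in enumerate(FACTORS):
        track = synth.make_coverage(
            chrom_lengths, design[f], baseline=10, seed=int(rng.integers(2**31))
        )
        d2 = peaks.smooth_second_derivative(track, cfg.curvature_kernel_bp)
        broad = [
            GenomicInterval(b.chrom, max(0, b.center - 1000),
                            min(chrom_lengths[b.chrom], b.center + 1000), score=500.0)
            for b in design[f][:-2]
        ]
        broad.append(GenomicInterval("chr1", 96_000, 98_300, score=500.0))
        regions = peaks.find_concave_regions(d2, broad, cfg.curvature_threshold)
        called = peaks.filter_peaks(
            [r.interval for r in regions], cfg.peak_min_score, cfg.peak_min_width, []
        )
        concave_sets[f] = called
        in_double = [p for p in called if p.chrom == "chr1" and p.start >= 96_000]
        split_ok &= len(in_double) == 2
        log.info("factor %s: %d broad -> %d concave peaks", f, len(broad), len(called))
    union = intervals.merge_union(concave_sets)
    upset = intervals.upset_counts(union)
    upset_match = (
        dict(zip(upset["combination"], upset["count"]))
        .get("+".join(sorted(FACTORS)), 0)
        >= truth_counts.get("+".join(sorted(FACTORS)), 0)
    )
    return {
        "n_union_regions": len(union),
        "upset": upset,
        "double_bump_split": bool(split_ok),
        "all5_combination_recovered": bool(upset_match),
    }


@_stage("family_enrichment")
def _demo_family(cfg: PipelineConfig, rng: np.random.Generator, chrom_lengths, elements):
    planted_family = "MIRAGE_S1"
    bumps = [
        synth.PlantedBump(
            e.interval.chrom,
            (e.interval.start + e.interval.end) // 2,
            height=20,
            width=e.interval.width,
            shape="flat_top",
        )
        for e in elements
        if e.family == planted_family
    ]
    track = synth.make_coverage(
        chrom_lengths, bumps, baseline=10, seed=int(rng.integers(2**31))
    )
    signals = enrichment.element_signal(track, elements)
    fam = enrichment.family_enrichment(
        track=track,
        signals=signals,
        min_members=cfg.family_min_members,
        fdr_threshold=cfg.family_fdr,
        fold_threshold=cfg.family_fold,
        n_background_bins=2000,
        seed=int(rng.integers(2**31)),
    )
    return {
        "table": fam,
        "planted_family": planted_family,
        "planted_recovered": bool(fam.loc[planted_family, "enriched"]),
        "false_families": int(fam["enriched"].sum()) - int(fam.loc[planted_family, "enriched"]),
    }


@_stage("diffexpr")
def _demo_de(cfg: PipelineConfig, rng: np.random.Generator, chrom_lengths, elements):
    rep_names = [e.name for e in elements]
    n_rep = len(rep_names)
    planted_idx = [i for i in range(0, n_rep, 7)]
    planted = [synth.PlantedEffect(f"feat_{i}", 3.0) for i in planted_idx]
    cm, truth = synth.make_counts(
        n_rep, 5, dispersion=0.05, planted=planted, seed=int(rng.integers(2**31))
    )
    cm.counts.index = rep_names
    truth["true_lfc"].index = rep_names
    rep_res = diffexpr.nb_test(cm)

    # genes: 20 intervals; gene 0 overlaps the first planted repeat
    gene_ivs = {}
    first_rep = elements[planted_idx[0]].interval
    gene_ivs["gene_0"] = GenomicInterval(
        first_rep.chrom, max(0, first_rep.start - 200), first_rep.end + 200
    )
    for i in range(1, 20):
        gene_ivs[f"gene_{i}"] = GenomicInterval(
            "chr2", 1_000 + i * 2_000, 1_000 + i * 2_000 + 1_500
        )
    gene_planted = [
        synth.PlantedEffect("gene_feat_0", 2.0),
        synth.PlantedEffect("gene_feat_1", 2.0),
    ]
    gcm, _ = synth.make_counts(
        20, 5, dispersion=0.05, planted=gene_planted,
        feature_prefix="gene_feat", seed=int(rng.integers(2**31)),
    )
    gcm.counts.index = list(gene_ivs)
    gene_res = diffexpr.nb_test(gcm)

    rep_ann = {e.name: e.interval for e in elements}
    calls = diffexpr.call_repeats(
        rep_res, gene_res, rep_ann, gene_ivs,
        repeat_fdr=cfg.de_fdr, gene_fdr=cfg.gene_filter_fdr,
    )
    up = [c.feature for c in calls if c.called_up]
    filtered = [c.feature for c in calls if c.filtered_reason == "gene_overlap"]
    truth_up = set(truth["true_lfc"].index[truth["true_lfc"] > 0])
    expected_filtered = {elements[planted_idx[0]].name}  # overlaps up gene_0
    # unique-read confirmation on the called set
    confirmed = 0
    for c in calls:
        if not c.called_up:
            continue
        c.confirmed_unique = diffexpr.confirm_unique(
            mutant_unique=[25, 30, 28], wt_unique=[3, 4, 2],
            min_reads=cfg.unique_min_reads, min_fc=cfg.unique_min_fc,
        )
        confirmed += c.confirmed_unique is True
    by_el = {e.name: e for e in elements}
    up_transposase = sum(by_el[f].has_transposase_orf for f in up)
    total_transposase = sum(e.has_transposase_orf for e in elements)
    fold, pval = diffexpr.annotation_enrichment(
        len(up), up_transposase, n_rep, max(1, total_transposase)
    )
    return {
        "n_repeats": n_rep,
        "n_planted_up": len(planted_idx),
        "n_called_up": len(up),
        "n_gene_overlap_filtered": len(filtered),
        "gene_overlap_filter_correct": set(filtered) == expected_filtered,
        "recovery_ok": set(up) | set(filtered) == truth_up,
        "n_confirmed_unique": confirmed,
        "transposase_fold": fold,
        "transposase_p": pval,
    }


@_stage("telomere")
def _demo_telomere(cfg: PipelineConfig, rng: np.random.Generator):
    def frac(telo_frac, seed):
        reads, _ = synth.make_reads(800, telomeric_fraction=telo_frac, seed=seed)
        return float(
            np.mean([enrichment.is_telomeric_read(r, min_motifs=cfg.telomere_min_motifs)
                     for r in reads])
        )

    factor_fracs = [frac(0.05, int(rng.integers(2**31))) for _ in range(2)]
    input_fracs = [frac(0.005, int(rng.integers(2**31))) for _ in range(20)]
    p = enrichment.telomere_enrichment(factor_fracs, input_fracs)
    return {
        "factor_fracs": factor_fracs,
        "background_mean": float(np.mean(input_fracs)),
        "p_value": p,
        "enriched": p < 0.05,
    }


@_stage("smallrna")
def _demo_smallrna(cfg: PipelineConfig, rng: np.random.Generator):
    pirnas, transcripts, reads, truth = synth.make_smallrna(seed=int(rng.integers(2**31)))
    sites = []
    for pir in pirnas:
        for tx, seq in transcripts.items():
            sites.extend(smallrna.find_targets(pir, seq, tx))
    found = {(s.pirna_id, s.feature_id, s.position) for s in sites}
    planted = {
        (p["pirna_id"], p["feature_id"], p["position"]) for p in truth["planted_sites"]
    }
    assign = smallrna.assign_22g(sites, reads, cfg.g22_window, cfg.g22_max_mismatch)
    sub = smallrna.subsample_positions(
        {
            "wt": [(r.sequence, r.start) for r in reads],
            "mutant": [(r.sequence, r.start) for r in reads[: len(reads) // 2]],
        },
        seed=int(rng.integers(2**31)),
    )
    ratios = smallrna.class_ratios(
        {"piRNA-dependent 22Gs": assign.attrs["n_assigned"] // 2},
        {"piRNA-dependent 22Gs": assign.attrs["n_assigned"]},
    )
    return {
        "n_planted_sites": len(planted),
        "planted_recovered": planted <= found,
        "n_sites_found": len(found),
        "n_22g_assigned": assign.attrs["n_assigned"],
        "n_target_features_hit": assign.attrs["n_features_hit"],
        "subsample_sizes": {k: len(v) for k, v in sub.items()},
        "halved_22g_log2_ratio": float(ratios["piRNA-dependent 22Gs"]),
    }


@_stage("interactions")
def _demo_interactions(cfg: PipelineConfig, rng: np.random.Generator):
    null_tab, _ = synth.make_broods(
        interaction="multiplicative", seed=int(rng.integers(2**31))
    )
    sub_tab, sub_truth = synth.make_broods(
        interaction="sub_multiplicative", sub_fraction=0.3, seed=int(rng.integers(2**31))
    )
    res_null = interactions.interaction_test(null_tab, propagate_uncertainty=True)
    res_sub = interactions.interaction_test(sub_tab, propagate_uncertainty=True)
    res_sub_mwu = interactions.interaction_test(sub_tab, test="mann_whitney")
    z, pz = interactions.proportions_ztest(30, 100, 10, 100)
    pf = interactions.fisher_test([[10, 2], [3, 11]])
    return {
        "null": res_null,
        "sub_multiplicative": res_sub,
        "sub_multiplicative_mwu_p": res_sub_mwu.p_value,
        "sub_detected": res_sub.p_value < 0.05,
        "expected_sub_double": sub_truth["group_means"]["double"],
        "proportions_z": z,
        "proportions_p": pz,
        "fisher_p": pf,
    }


@_stage("h3k9me3_response")
def _demo_response(cfg: PipelineConfig, rng: np.random.Generator, chrom_lengths, elements):
    seed = int(rng.integers(2**31))
    bumps = [
        synth.PlantedBump(
            e.interval.chrom, (e.interval.start + e.interval.end) // 2,
            height=30, width=e.interval.width, shape="flat_top",
        )
        for e in elements
    ]
    wt = synth.make_coverage(chrom_lengths, bumps, baseline=10, seed=seed)
    mutant = synth.make_coverage(chrom_lengths, bumps, baseline=10, seed=seed + 1)
    # plant a 50% loss of signal over the affected set in the mutant
    affected = [e.interval for e in elements if e.class_label == "Cut and paste"]
    for iv in affected:
        mutant.data[iv.chrom][iv.start : iv.end] *= 0.5
    table, p, stars = enrichment.signal_response(
        mutant, wt, affected, [e.interval for e in elements]
    )
    return {
        "n_regions": len(affected),
        "median_log2fc": float(table["log2fc"].median()),
        "p_value": p,
        "stars": stars,
    }


def run_demo(seed: int = 0, outdir=None, config: PipelineConfig | None = None) -> dict:
    """Run every stage on a fresh synthetic fixture; return a nested report.

    Writes ``report.md`` plus per-stage TSVs under ``outdir`` when given.
    Identical seeds produce identical reports.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    spec = synth.SyntheticGenomeSpec(seed=int(rng.integers(2**31)))
    genome, elements = make_genome_stage(spec)
    chrom_lengths = {c: len(s) for c, s in genome.items()}

    report = {
        "seed": seed,
        "n_repeats": len(elements),
        "peaks": _demo_peaks(cfg, rng, chrom_lengths),
        "family_enrichment": _demo_family(cfg, rng, chrom_lengths, elements),
        "diffexpr": _demo_de(cfg, rng, chrom_lengths, elements),
        "telomere": _demo_telomere(cfg, rng),
        "smallrna": _demo_smallrna(cfg, rng),
        "interactions": _demo_interactions(cfg, rng),
        "h3k9me3_response": _demo_response(cfg, rng, chrom_lengths, elements),
    }
    report["all_truth_checks_pass"] = all(
        [
            report["peaks"]["double_bump_split"],
            report["peaks"]["all5_combination_recovered"],
            report["family_enrichment"]["planted_recovered"],
            report["diffexpr"]["recovery_ok"],
            report["diffexpr"]["gene_overlap_filter_correct"],
            report["telomere"]["enriched"],
            report["smallrna"]["planted_recovered"],
            report["interactions"]["sub_detected"],
            report["h3k9me3_response"]["p_value"] < 0.05,
        ]
    )
    if outdir is not None:
        _write_report(Path(outdir), report)
    return report


@_stage("genome")
def make_genome_stage(spec):
    return synth.make_genome(spec)


def _fmt(val) -> str:
    if isinstance(val, float):
        return f"{val:.4g}"
    return str(val)


def _write_report(outdir: Path, report: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# Synthetic demonstration run", ""]
    for stage, res in report.items():
        if not isinstance(res, dict):
            lines.append(f"- {stage}: {_fmt(res)}")
            continue
        lines.append(f"\n## {stage}\n")
        for k, v in res.items():
            if isinstance(v, pd.DataFrame):
                v.to_csv(outdir / f"{stage}_{k}.tsv", sep="\t")
                lines.append(f"- {k}: written to {stage}_{k}.tsv")
            elif dataclasses.is_dataclass(v):
                lines.append(f"- {k}: {v}")
            else:
                lines.append(f"- {k}: {_fmt(v)}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
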