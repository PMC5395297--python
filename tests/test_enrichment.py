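"""Signal scoring: element/family enrichment, telomeric reads, response tests."""

import re

import numpy as np
import pytest
from scipy import stats

from hetchrom import synth
from hetchrom.enrichment import (
    control_repeats,
    element_signal,
    family_enrichment,
    genome_median,
    is_telomeric_read,
    significance_stars,
    signal_response,
    telomere_enrichment,
    telomere_motif_count,
)
from hetchrom.intervals import GenomicInterval
from hetchrom.peaks import CoverageTrack
from hetchrom.repeats import RepeatElement


def flat_family_track(elements, chrom_lengths, factor, baseline=10.0):
    """Flat baseline with `factor` x baseline plateaus over the elements."""
    data = {c: np.full(n, baseline) for c, n in chrom_lengths.items()}
    for e in elements:
        data[e.interval.chrom][e.interval.start : e.interval.end] = baseline * factor
    return CoverageTrack(data)


class TestElementSignal:
    def test_element_at_genome_median_has_zero_lfc(self):
        track = CoverageTrack({"c": np.full(10_000, 8.0)})
        el = RepeatElement(GenomicInterval("c", 100, 200), "F", "LTR")
        (sig,) = element_signal(track, [el], pseudocount=0.0)
        assert sig.log2fc_vs_genome_median == 0.0

    def test_fourfold_signal_gives_lfc_two(self):
        data = np.full(10_000, 5.0)
        data[100:200] = 20.0
        track = CoverageTrack({"c": data})
        el = RepeatElement(GenomicInterval("c", 100, 200), "F", "LTR")
        (sig,) = element_signal(track, [el], pseudocount=0.0)
        assert sig.log2fc_vs_genome_median == pytest.approx(2.0)

    def test_planted_threefold_family_recovered(self, toy_genome):
        genome, elements = toy_genome
        lengths = {c: len(s) for c, s in genome.items()}
        fam = [e for e in elements if e.family == "MIRAGE_S1"]
        track = flat_family_track(fam, lengths, factor=3.0)
        signals = element_signal(track, fam, pseudocount=0.0)
        lfcs = [s.log2fc_vs_genome_median for s in signals]
        assert abs(np.median(lfcs) - np.log2(3)) < 0.05

    def test_element_outside_track_rejected(self):
        track = CoverageTrack({"c": np.zeros(100)})
        el = RepeatElement(GenomicInterval("c", 50, 200), "F", "LTR")
        with pytest.raises(ValueError):
            element_signal(track, [el])

    def test_median_invariant_under_scaling(self):
        rng = np.random.default_rng(0)
        data = rng.poisson(10, 20_000).astype(float)
        track = CoverageTrack({"c": data})
        el = RepeatElement(GenomicInterval("c", 500, 800), "F", "LINE")
        a = element_signal(track, [el], pseudocount=0.0)[0].log2fc_vs_genome_median
        track5 = CoverageTrack({"c": 5 * data})
        b = element_signal(track5, [el], pseudocount=0.0)[0].log2fc_vs_genome_median
        assert a == pytest.approx(b, abs=1e-12)


def mwu_greater_oracle(x, y):
    """Tie-corrected normal-approximation rank-sum p, independent of scipy's path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    allv = np.concatenate([x, y])
    ranks = stats.rankdata(allv)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(allv, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12 * (n + 1 - tie_term))
    z = (u1 - mu - 0.5) / sigma
    return float(stats.norm.sf(z))


class TestFamilyEnrichment:
    def make_fixture(self, toy_genome, factor):
        genome, elements = toy_genome
        lengths = {c: len(s) for c, s in genome.items()}
        fam = [e for e in elements if e.family == "MIRAGE_S1"]
        track = flat_family_track(fam, lengths, factor=factor)
        signals = element_signal(track, elements)
        return track, signals

    def test_planted_family_enriched_and_p_matches_rank_sum_oracle(self, toy_genome):
        track, signals = self.make_fixture(toy_genome, factor=4.0)
        table = family_enrichment(
            signals, track, n_background_bins=3000, seed=1
        )
        assert bool(table.loc["MIRAGE_S1", "enriched"])
        # recompute the MWU on the same member/background samples
        med = genome_median(track)
        vals = [s.mean_signal for s in signals if s.element.family == "MIRAGE_S1"]
        from hetchrom.enrichment import _background_bin_means

        widths = [s.element.interval.width for s in signals]
        bg = _background_bin_means(track, int(np.median(widths)), 3000, seed=1)
        assert table.loc["MIRAGE_S1", "p_value"] == pytest.approx(
            mwu_greater_oracle(vals, bg), rel=1e-6
        )

    def test_family_at_genome_median_not_enriched(self, toy_genome):
        track, signals = self.make_fixture(toy_genome, factor=1.0)
        table = family_enrichment(signals, track, n_background_bins=3000, seed=0)
        assert not table["enriched"].any()
        assert (table["p_value"] > 0.2).all()

    def test_small_families_excluded(self, toy_genome):
        track, signals = self.make_fixture(toy_genome, factor=4.0)
        table = family_enrichment(signals, track, n_background_bins=1000, seed=0)
        assert "SAT_S1" not in table.index  # 6 members < 10
        assert "LINE_S1" not in table.index  # 8 members < 10

    def test_enrichment_flag_monotone_in_signal(self, toy_genome):
        flags = []
        for factor in (1.0, 2.0, 4.0, 8.0):
            track, signals = self.make_fixture(toy_genome, factor)
            table = family_enrichment(signals, track, n_background_bins=2000, seed=3)
            flags.append(bool(table.loc["MIRAGE_S1", "enriched"]))
        assert flags == sorted(flags)

    def test_null_pvalues_uniform(self):
        # family drawn from the background -> p uniform (KS over simulations)
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(500):
            fam = rng.normal(10, 2, size=15)
            bg = rng.normal(10, 2, size=60)
            pvals.append(mwu_greater_oracle(fam, bg))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTelomereMotifCount:
    def test_six_tandem_motifs(self):
        assert telomere_motif_count("GCCTAA" * 6) == 6

    def test_non_matching_read_is_zero(self):
        assert telomere_motif_count("ACGT" * 9) == 0

    def test_five_motifs_after_leading_ns_is_telomeric(self):
        read = "NNNNNN" + "GCCTAA" * 5
        assert telomere_motif_count(read) == 5
        assert is_telomeric_read(read)

    def test_trims_to_36_bases(self):
        assert telomere_motif_count("GCCTAA" * 10) == 6

    def test_reverse_complement_strand_counted(self):
        assert telomere_motif_count("TTAGGC" * 6) == 6

    def test_matches_regex_oracle_on_random_reads(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(2_000):
            read = "".join(rng.choice(bases, size=36))
            oracle = max(
                len(re.findall("GCCTAA", read)), len(re.findall("TTAGGC", read))
            )
            assert telomere_motif_count(read) == oracle

    def test_off_frame_synthetic_reads_counted(self):
        reads, _ = synth.make_reads(100, telomeric_fraction=1.0, seed=5)
        for r in reads:
            assert telomere_motif_count(r) in (5, 6)


class TestTelomereEnrichment:
    def test_factor_below_background_gives_large_p(self):
        p = telomere_enrichment([0.001, 0.002], [0.01] * 10 + [0.02] * 10)
        assert p > 0.5

    def test_factor_above_all_background_hits_minimal_p(self):
        bg = list(np.linspace(0.001, 0.01, 30))
        p = telomere_enrichment([0.5, 0.6], bg)
        # exact MWU enumeration: U = n1*n2, P = 1 / C(32, 2)
        from math import comb

        assert p == pytest.approx(1 / comb(32, 2), rel=1e-9)

    def test_uniform_under_null(self):
        rng = np.random.default_rng(1)
        pvals = [
            telomere_enrichment(rng.normal(size=2), rng.normal(size=30))
            for _ in range(500)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_input_requirements(self):
        with pytest.raises(ValueError):
            telomere_enrichment([], [0.1, 0.2])


class TestSignalResponse:
    @pytest.mark.parametrize(
        "p,expect", [(0.2, ""), (0.09, "*"), (0.04, "**"), (0.0005, "***")]
    )
    def test_star_coding(self, p, expect):
        assert significance_stars(p) == expect

    def test_identical_tracks_give_zero_lfc(self):
        rng = np.random.default_rng(0)
        data = rng.poisson(10, 50_000).astype(float)
        track = CoverageTrack({"c": data})
        regions = [GenomicInterval("c", i * 500, i * 500 + 300) for i in range(20)]
        allr = [GenomicInterval("c", i * 500, i * 500 + 300) for i in range(90)]
        table, p, _ = signal_response(track, track, regions, allr)
        assert np.allclose(table["log2fc"], 0.0)
        assert p > 0.3

    def test_halved_set_detected(self):
        rng = np.random.default_rng(1)
        wt = CoverageTrack({"c": rng.poisson(50, 100_000).astype(float)})
        mut = CoverageTrack({"c": wt.data["c"].copy()})
        regions = [GenomicInterval("c", i * 1000, i * 1000 + 500) for i in range(50)]
        allr = [GenomicInterval("c", i * 1000, i * 1000 + 500) for i in range(100)]
        for r in regions:
            mut.data["c"][r.start : r.end] *= 0.5
        table, p, stars = signal_response(mut, wt, regions, allr)
        assert np.median(table["log2fc"]) == pytest.approx(-1.0, abs=0.1)
        assert p < 0.001 and stars == "***"


class TestControlRepeats:
    def build(self):
        n = 30
        elements = [
            RepeatElement(GenomicInterval("c", i * 1000, i * 1000 + 400), "F", "LTR")
            for i in range(n)
        ]
        base = np.full(n * 1000, 10.0)
        wt = base.copy()
        factor = base.copy()
        planted_controls = set()
        for i, e in enumerate(elements):
            iv = e.interval
            if i < 10:  # planted controls: high H3K9me3, low factor signal
                wt[iv.start : iv.end] = 30.0
                factor[iv.start : iv.end] = 5.0
                planted_controls.add(e.name)
            elif i < 20:  # high H3K9me3 but factor-bound
                wt[iv.start : iv.end] = 30.0
                factor[iv.start : iv.end] = 12.0
            # else: low H3K9me3
        return (
            elements,
            CoverageTrack({"c": wt}),
            {"hpl-2": CoverageTrack({"c": factor})},
            planted_controls,
        )

    def test_planted_controls_exactly_recovered(self):
        elements, wt, factors, planted = self.build()
        got = {e.name for e in control_repeats(wt, factors, {}, elements)}
        assert got == planted

    def test_upregulated_elements_excluded(self):
        elements, wt, factors, planted = self.build()
        excluded = next(iter(planted))
        got = {
            e.name
            for e in control_repeats(wt, factors, {"hpl-2": {excluded}}, elements)
        }
        assert got == planted - {excluded}

    def test_factor_bound_at_1_2x_excluded(self):
        elements, wt, factors, planted = self.build()
        # raise one control's factor signal to 1.2x the factor genome average
        name = sorted(planted)[0]
        el = next(e for e in elements if e.name == name)
        favg = factors["hpl-2"].concat().mean()
        factors["hpl-2"].data["c"][el.interval.start : el.interval.end] = 1.2 * favg
        got = {e.name for e in control_repeats(wt, factors, {}, elements)}
        assert name not in got


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=50))
def test_motif_count_always_matches_regex_oracle(read):
    oracle = max(
        len(re.findall("GCCTAA", read[:36])), len(re.findall("TTAGGC", read[:36]))
    )
    assert telomere_motif_count(read) == oracle
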