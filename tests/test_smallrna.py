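"""piRNA targeting rule, 22G assignment, subsampling, class ratios."""

import numpy as np
import pytest
from scipy import stats

from hetchrom.smallrna import (
    PiRNARecord,
    SmallRead,
    TargetSite,
    assign_22g,
    class_ratios,
    find_targets,
    pair_class,
    revcomp,
    subsample_positions,
)

PIRNA = PiRNARecord("p1", "T" + "ACGTACGTACGTACGTACGT", source="locus_p1")


def embed(site, flank=60, seed=0):
    """Transcript with `site` at a known position, random non-pairing flanks."""
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return left + site + right, flank


def oracle_counters(pirna_seq, window):
    """Independent pairing formulation via the window's reverse complement."""
    rc = revcomp(window)
    seed_gu = outer_gu = outer_mm = 0
    for i in range(21):
        p, r = pirna_seq[i], rc[i]
        if p == r:
            cls = "match"
        elif (p, r) in (("G", "A"), ("T", "C")):
            cls = "gu"
        else:
            cls = "mismatch"
        in_seed = 1 <= i < 8
        if cls == "gu":
            seed_gu += in_seed
            outer_gu += not in_seed
        elif cls == "mismatch":
            if in_seed:
                return None
            outer_mm += 1
    if seed_gu > 1 or outer_mm > 2 or outer_gu > 1:
        return None
    return seed_gu, outer_mm, outer_gu


def oracle_find(pirna, transcript):
    out = []
    for p in range(len(transcript) - 20):
        res = oracle_counters(pirna.sequence, transcript[p : p + 21])
        if res is not None:
            out.append((p,) + res)
    return out


class TestPairClass:
    @pytest.mark.parametrize(
        "p,t,expect",
        [
            ("A", "T", "match"),
            ("C", "G", "match"),
            ("G", "C", "match"),
            ("T", "A", "match"),
            ("G", "T", "gu"),
            ("T", "G", "gu"),
            ("C", "A", "mismatch"),
            ("A", "A", "mismatch"),
            ("G", "G", "mismatch"),
        ],
    )
    def test_classification(self, p, t, expect):
        assert pair_class(p, t) == expect


class TestPiRNARecord:
    def test_length_enforced(self):
        with pytest.raises(ValueError):
            PiRNARecord("bad", "ACGT")

    def test_u_mapped_to_t(self):
        rec = PiRNARecord("r", "U" * 21)
        assert rec.sequence == "T" * 21


class TestFindTargets:
    def test_perfect_complement_single_site(self):
        tx, pos = embed(revcomp(PIRNA.sequence))
        sites = find_targets(PIRNA, tx, "tx1")
        exact = [s for s in sites if s.position == pos]
        assert len(exact) == 1
        s = exact[0]
        assert (s.seed_gu, s.outer_mismatches, s.outer_gu) == (0, 0, 0)

    def test_boundary_budget_accepted(self):
        # 1 seed G:U + 2 outer mismatches + 1 outer G:U is the exact limit
        site = list(revcomp(PIRNA.sequence))
        # seed G:U at piRNA nt 4 (0-based 3): piRNA base G pairs target T
        assert PIRNA.sequence[3] == "G"
        site[20 - 3] = "T"
        # outer G:U at piRNA nt 13 (0-based 12): piRNA T opposite target G
        assert PIRNA.sequence[12] == "T"
        site[20 - 12] = "G"
        # two outer mismatches at piRNA nt 15, 18 (0-based 14, 17)
        for k in (14, 17):
            comp = revcomp(PIRNA.sequence[k])
            bad = next(
                b for b in "ACGT" if pair_class(PIRNA.sequence[k], b) == "mismatch"
            )
            site[20 - k] = bad
        tx, pos = embed("".join(site))
        sites = [s for s in find_targets(PIRNA, tx, "tx1") if s.position == pos]
        assert len(sites) == 1
        s = sites[0]
        assert (s.seed_gu, s.outer_mismatches, s.outer_gu) == (1, 2, 1)

    def test_two_seed_mismatches_rejected(self):
        site = list(revcomp(PIRNA.sequence))
        for k in (2, 5):
            site[20 - k] = next(
                b for b in "ACGT" if pair_class(PIRNA.sequence[k], b) == "mismatch"
            )
        tx, pos = embed("".join(site))
        assert not [s for s in find_targets(PIRNA, tx, "tx1") if s.position == pos]

    def test_self_hits_excluded(self):
        tx, _ = embed(revcomp(PIRNA.sequence))
        assert find_targets(PIRNA, tx, "locus_p1") == []

    @pytest.mark.parametrize("seed", range(6))
    def test_fuzzed_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pir = PiRNARecord(f"p{seed}", "".join(rng.choice(list("ACGT"), size=21)))
        # enrich for near-complementary windows so accepts actually occur
        tx = "".join(rng.choice(list("ACGT"), size=300))
        mutated = list(revcomp(pir.sequence))
        for k in rng.choice(21, size=rng.integers(0, 4), replace=False):
            mutated[k] = str(rng.choice(list("ACGT")))
        tx = tx[:100] + "".join(mutated) + tx[100:]
        got = [
            (s.position, s.seed_gu, s.outer_mismatches, s.outer_gu)
            for s in find_targets(pir, tx, "tx")
        ]
        assert got == oracle_find(pir, tx)

    def test_revcomp_consistency(self):
        # the site set is invariant under revcomp of both strands
        rng = np.random.default_rng(3)
        pir = PiRNARecord("p", "".join(rng.choice(list("ACGT"), size=21)))
        tx, _ = embed(revcomp(pir.sequence), seed=4)
        fwd = {s.position for s in find_targets(pir, tx, "tx")}
        # scanning the reverse-complemented transcript with the
        # reverse-complemented piRNA finds the same duplexes at mirrored
        # coordinates
        rc_pir = PiRNARecord("p_rc", revcomp(pir.sequence))
        rc = {
            len(tx) - 21 - s.position
            for s in find_targets(rc_pir, revcomp(tx), "tx")
        }
        assert fwd == rc


class TestAssign22g:
    SITE = TargetSite("p1", "tx1", 100, 0, 0, 0)  # center 110

    def mkread(self, start, mm=0, feature="tx1"):
        return SmallRead("G" + "A" * 21, feature, start, mismatches=mm)

    @pytest.mark.parametrize(
        "start,mm,expect",
        [
            (110, 0, True),   # at the center
            (60, 0, True),    # left boundary: center - 50 inclusive
            (159, 1, True),   # right boundary - 1, one mismatch allowed
            (160, 0, False),  # right boundary excluded (half-open)
            (59, 0, False),   # 51 bp left of center
            (110, 2, False),  # too many mismatches
        ],
    )
    def test_window_and_mismatch_rules(self, start, mm, expect):
        df = assign_22g([self.SITE], [self.mkread(start, mm)])
        assert bool(df["assigned"].iloc[0]) is expect

    def test_other_feature_not_assigned(self):
        df = assign_22g([self.SITE], [self.mkread(110, feature="tx2")])
        assert not df["assigned"].iloc[0]

    def test_monotone_in_window_size(self, rng):
        sites = [
            TargetSite("p", "tx", int(rng.integers(50, 950)), 0, 0, 0)
            for _ in range(10)
        ]
        reads = [self.mkread(int(rng.integers(0, 1000)), feature="tx") for _ in range(200)]
        prev = None
        for w in (20, 60, 100, 200):
            assigned = assign_22g(sites, reads, window=w)["assigned"]
            if prev is not None:
                assert (assigned | ~prev).all()  # no assignment lost
            prev = assigned

    @pytest.mark.parametrize("seed", range(3))
    def test_fuzzed_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sites = [
            TargetSite("p", f"tx{int(rng.integers(3))}", int(rng.integers(0, 500)), 0, 0, 0)
            for _ in range(20)
        ]
        reads = [
            SmallRead(
                "G" + "A" * 21,
                f"tx{int(rng.integers(3))}",
                int(rng.integers(0, 600)),
                mismatches=int(rng.integers(0, 3)),
            )
            for _ in range(300)
        ]
        df = assign_22g(sites, reads)
        for read, got in zip(reads, df["assigned"]):
            oracle = read.mismatches <= 1 and any(
                t.feature_id == read.feature
                and t.center - 50 <= read.start < t.center + 50
                for t in sites
            )
            assert bool(got) == oracle


class TestSubsamplePositions:
    def test_sizes_match_smallest(self):
        ds = {
            "a": [(f"s{i}", i) for i in range(100)],
            "b": [(f"s{i}", i) for i in range(50)],
        }
        out = subsample_positions(ds, seed=0)
        assert {k: len(v) for k, v in out.items()} == {"a": 50, "b": 50}

    def test_equal_sizes_unchanged(self):
        ds = {"a": [("x", 1), ("y", 2)], "b": [("z", 3), ("w", 4)]}
        out = subsample_positions(ds, seed=1)
        assert sorted(out["a"]) == sorted(ds["a"])

    def test_duplicates_collapse_to_unique(self):
        ds = {"a": [("x", 1)] * 10 + [("y", 2)], "b": [("z", 1), ("w", 2)]}
        out = subsample_positions(ds, seed=0)
        assert len(out["a"]) == 2

    def test_determinism(self):
        ds = {"a": [(f"s{i}", i) for i in range(100)], "b": [(f"s{i}", i) for i in range(30)]}
        assert subsample_positions(ds, seed=5) == subsample_positions(ds, seed=5)

    def test_class_proportions_preserved_in_expectation(self):
        # items of two classes; subsampling is uniform, so class counts follow
        # the hypergeometric expectation (chi-square goodness of fit over seeds)
        ds = {
            "big": [("A", i) for i in range(600)] + [("B", i + 1000) for i in range(400)],
            "small": [("A", i) for i in range(100)],
        }
        fracs = []
        for s in range(100):
            out = subsample_positions(ds, seed=s)
            fracs.append(np.mean([seq == "A" for seq, _ in out["big"]]))
        counts = np.array([np.mean(fracs), 1 - np.mean(fracs)]) * 100 * 100
        chi2 = ((counts - np.array([60.0, 40.0]) * 100) ** 2 / (np.array([60.0, 40.0]) * 100)).sum()
        assert stats.chi2.sf(chi2, df=1) > 0.01


class TestClassRatios:
    def test_identical_counts_give_zero(self):
        r = class_ratios({"piRNAs": 100}, {"piRNAs": 100})
        assert r["piRNAs"] == 0.0

    def test_halved_class_near_minus_one(self):
        r = class_ratios({"22G": 500}, {"22G": 1000})
        assert r["22G"] == pytest.approx(-1.0, abs=0.01)

    def test_empty_class_is_nan(self):
        r = class_ratios({"x": 0}, {"x": 0})
        assert np.isnan(r["x"])
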