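import itertools

import numpy as np
import pytest

from dfprint.genomic_core import CutProfile, GenomicInterval
from dfprint.synthetic_data import SimSpec, simulate_pair, simulate_profile
from dfprint.wellington import Footprint, FootprintParams, wellington_score
from dfprint.wellington_bootstrap import (
    DfpCallSet,
    DfpScore,
    ShuffleConfig,
    bootstrap_score,
    differential_from_profiles,
    pool_profiles,
    shared_dhs_summary,
    shared_percentage,
    shuffle_profile,
)

from .conftest import random_profile


def make_profile(fwd, rev, start=0):
    iv = GenomicInterval("chrT", start, start + len(fwd))
    return CutProfile(iv, np.asarray(fwd), np.asarray(rev))


class TestPoolProfiles:
    def test_additive_identity(self, rng):
        p = random_profile(rng)
        z = CutProfile.zeros(p.interval)
        pooled = pool_profiles(p, z)
        np.testing.assert_array_equal(pooled.fwd, p.fwd)
        np.testing.assert_array_equal(pooled.rev, p.rev)

    def test_commutative(self, rng):
        a, b = random_profile(rng), random_profile(rng)
        ab, ba = pool_profiles(a, b), pool_profiles(b, a)
        np.testing.assert_array_equal(ab.fwd, ba.fwd)
        np.testing.assert_array_equal(ab.rev, ba.rev)

    def test_totals_add(self, rng):
        a, b = random_profile(rng), random_profile(rng)
        assert pool_profiles(a, b).total == a.total + b.total

    def test_mismatched_intervals_rejected(self, rng):
        a = random_profile(rng, start=100)
        b = random_profile(rng, start=200)
        with pytest.raises(ValueError, match="mismatched"):
            pool_profiles(a, b)


class TestShuffleProfile:
    def test_all_zero_stays_zero(self, rng):
        z = CutProfile.zeros(GenomicInterval("chrT", 0, 30))
        s = shuffle_profile(z, rng)
        assert s.total == 0

    def test_per_strand_multisets_preserved(self, rng):
        p = random_profile(rng, rate=2.0)
        s = shuffle_profile(p, rng)
        assert sorted(s.fwd) == sorted(p.fwd)
        assert sorted(s.rev) == sorted(p.rev)
        assert s.interval == p.interval

    def test_empirical_position_uniformity(self):
        # vector (4,0,0,0): after shuffling, the 4 lands at each position
        # with probability 1/4
        rng = np.random.default_rng(77)
        p = make_profile([4, 0, 0, 0], [0, 0, 0, 0])
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            s = shuffle_profile(p, rng)
            counts[np.argmax(s.fwd)] += 1
        freqs = counts / n
        np.testing.assert_allclose(freqs, 0.25, atol=0.02)


def exhaustive_dfp_score(locus, a, b, params):
    """Oracle: replace random shuffles by all distinct per-strand
    permutations of the comparator's window counts (equiprobable for a
    uniformly random permutation of a multiset)."""
    shoulder = params.shoulder_size
    fp_size = locus.best_size
    center = locus.interval.start + fp_size // 2 - a.interval.start
    half = fp_size // 2
    w_lo = center - half - shoulder
    w_hi = center - half + fp_size + shoulder

    pooled = pool_profiles(a, b)
    s_real = wellington_score(pooled, center, fp_size, shoulder)

    b_fwd = tuple(int(v) for v in b.fwd[w_lo:w_hi])
    b_rev = tuple(int(v) for v in b.rev[w_lo:w_hi])
    fwd_perms = sorted(set(itertools.permutations(b_fwd)))
    rev_perms = sorted(set(itertools.permutations(b_rev)))
    n_ge = n_tot = 0
    for pf in fwd_perms:
        for pr in rev_perms:
            shuf = CutProfile(b.interval, np.array(b.fwd), np.array(b.rev))
            shuf.fwd = b.fwd.copy()
            shuf.rev = b.rev.copy()
            shuf.fwd[w_lo:w_hi] = pf
            shuf.rev[w_lo:w_hi] = pr
            s_k = wellington_score(pool_profiles(a, shuf), center, fp_size, shoulder)
            n_tot += 1
            n_ge += s_k >= s_real - 1e-9
    return 100.0 * n_ge / n_tot


class TestBootstrapScore:
    shoulder = 2
    params = FootprintParams(footprint_sizes=(3,), shoulder_size=2, score_threshold=0)

    def locus(self, start=102):
        return Footprint(GenomicInterval("chrT", start, start + 3), 5.0, 3)

    def test_identical_strong_footprint_scores_non_differential(self):
        # comparator identical to primary -> pooled structure beats shuffles
        for seed in range(5):
            spec = SimSpec(
                region_length=400,
                depth=150,
                footprints=((200, 21, 1.0),),
                background=0.05,
                seed=seed,
            )
            prof, _ = simulate_profile(spec)
            from dfprint.wellington import scan_footprints

            fps = scan_footprints(prof)
            assert fps
            d = bootstrap_score(
                fps[0],
                prof,
                prof,
                FootprintParams(),
                ShuffleConfig(seed=seed),
                rng=np.random.default_rng(seed),
            )
            assert d.score < 10

    def test_all_zero_comparator_ties_to_100_and_flags(self):
        a = make_profile([3, 3, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 3, 3], start=100)
        b = CutProfile.zeros(a.interval)
        locus = Footprint(GenomicInterval("chrT", 102, 105), 1.0, 3)
        d = bootstrap_score(locus, a, b, self.params, ShuffleConfig(seed=0))
        assert d.score == 100.0
        assert d.low_coverage

    def test_exhaustive_permutation_oracle_small_window(self):
        # b fwd window (0,0,4,0,...): few distinct arrangements
        a = make_profile([5, 5, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 5, 5], start=100)
        b = make_profile([0, 0, 4, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0, 0], start=100)
        locus = self.locus()
        cfg = ShuffleConfig(n_shuffles=2000, seed=3)
        d = bootstrap_score(locus, a, b, self.params, cfg, rng=np.random.default_rng(3))
        exact = exhaustive_dfp_score(locus, a, b, self.params)
        assert d.score == pytest.approx(exact, abs=3.0)

    def test_score_granularity(self):
        a = make_profile([5, 5, 1, 0, 0, 0, 0], [0, 0, 0, 1, 0, 5, 5], start=100)
        b = make_profile([1, 0, 2, 0, 0, 1, 0], [0, 1, 0, 0, 2, 0, 1], start=100)
        cfg = ShuffleConfig(n_shuffles=1000, seed=5)
        d = bootstrap_score(self.locus(), a, b, self.params, cfg)
        # with n = 1000, score is a multiple of 0.1
        assert round(d.score * 10) == pytest.approx(d.score * 10, abs=1e-9)
        assert 0 <= d.score <= 100

    def test_seed_determinism(self):
        a = make_profile([5, 5, 1, 0, 0, 0, 0], [0, 0, 0, 1, 0, 5, 5], start=100)
        b = make_profile([1, 0, 2, 0, 0, 1, 0], [0, 1, 0, 0, 2, 0, 1], start=100)
        cfg = ShuffleConfig(n_shuffles=500, seed=11)
        d1 = bootstrap_score(self.locus(), a, b, self.params, cfg,
                             rng=np.random.default_rng(11))
        d2 = bootstrap_score(self.locus(), a, b, self.params, cfg,
                             rng=np.random.default_rng(11))
        assert d1.score == d2.score


def _pair_fixture(seed_a, seed_b, n_each=6, width=25):
    centers = [200 + 300 * i for i in range(3 * n_each)]
    shared = [(c, width) for c in centers[0::3]]
    a_only = [(c, width) for c in centers[1::3]]
    b_only = [(c, width) for c in centers[2::3]]
    L = 200 + 300 * 3 * n_each + 200
    sa = SimSpec(region_length=L, depth=100, background=0.01, seed=seed_a, imbalance=8.0)
    sb = SimSpec(region_length=L, depth=100, background=0.01, seed=seed_b, imbalance=8.0)
    return simulate_pair(sa, sb, shared, a_only, b_only)


class TestDifferentialFootprints:
    def test_self_comparison_empty(self):
        for seed in range(3):
            pa, _, _ = _pair_fixture(40 + seed, 50 + seed, n_each=4)
            calls = differential_from_profiles([pa], [pa], cfg=ShuffleConfig(seed=seed))
            assert calls.over_in_A == [] and calls.over_in_B == []

    def test_recovers_condition_specific_plants(self):
        pa, pb, labels = _pair_fixture(60, 61)
        calls = differential_from_profiles([pa], [pb], cfg=ShuffleConfig(seed=8))
        hitA = lambda iv: any(iv.overlaps(d.locus.interval) for d in calls.over_in_A)
        hitB = lambda iv: any(iv.overlaps(d.locus.interval) for d in calls.over_in_B)
        a_only = [iv for iv, l in labels if l == "A-only"]
        b_only = [iv for iv, l in labels if l == "B-only"]
        shared = [iv for iv, l in labels if l == "shared"]
        assert sum(hitA(iv) for iv in a_only) >= len(a_only) - 1
        assert sum(hitB(iv) for iv in b_only) >= len(b_only) - 1
        assert sum(hitA(iv) or hitB(iv) for iv in shared) <= 1

    def test_deterministic_given_seed(self):
        pa, pb, _ = _pair_fixture(70, 71, n_each=3)
        c1 = differential_from_profiles([pa], [pb], cfg=ShuffleConfig(seed=4))
        c2 = differential_from_profiles([pa], [pb], cfg=ShuffleConfig(seed=4))
        assert [(d.locus.interval, d.score) for d in c1.over_in_A] == [
            (d.locus.interval, d.score) for d in c2.over_in_A
        ]
        assert [(d.locus.interval, d.score) for d in c1.over_in_B] == [
            (d.locus.interval, d.score) for d in c2.over_in_B
        ]

    def test_monotone_in_comparator_occupancy(self):
        """Median DFP score grows as the comparator's occupancy drops."""
        centers = [(200 + 300 * i, 21) for i in range(8)]
        L = 200 + 300 * 8 + 200
        medians = []
        for occ_b in (1.0, 0.5, 0.0):
            scores = []
            for seed in range(4):
                sa = SimSpec(region_length=L, depth=100, background=0.01, seed=seed)
                fps_a = tuple((c, w, 1.0) for c, w in centers)
                fps_b = tuple((c, w, occ_b) for c, w in centers)
                from dataclasses import replace

                pa, _ = simulate_profile(replace(sa, footprints=fps_a))
                pb, _ = simulate_profile(
                    replace(sa, footprints=fps_b, seed=seed + 100)
                )
                from dfprint.wellington import scan_footprints

                for i, fp in enumerate(scan_footprints(pa)):
                    d = bootstrap_score(
                        fp, pa, pb, FootprintParams(),
                        ShuffleConfig(n_shuffles=200, seed=seed),
                        rng=np.random.default_rng([seed, i]),
                    )
                    scores.append(d.score)
            medians.append(np.median(scores))
        assert medians[0] <= medians[1] <= medians[2]


class TestSharedDhsSummary:
    def test_percentage_rule_on_published_counts(self):
        assert shared_percentage(10600, 14772) == 71.8
        assert shared_percentage(330, 335) == 98.5

    def test_zero_over_footprinted_is_na(self):
        assert shared_percentage(0, 0) is None

    def test_summary_counts_on_toy_sets(self):
        dhs_a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        dhs_b = [GenomicInterval("chr1", 50, 150)]
        fp = Footprint(GenomicInterval("chr1", 60, 80), 12.0, 21)
        calls = DfpCallSet(over_in_A=[DfpScore(fp, 50.0, "over_in_A")])
        s = shared_dhs_summary(dhs_a, dhs_b, calls)
        assert s.n_dhs_a == 2 and s.n_dhs_b == 1
        assert s.n_shared == 1
        assert s.n_over_a == 1 and s.n_over_a_shared == 1
        assert s.pct_over_a_shared == 100.0
        assert s.n_over_b == 0 and s.pct_over_b_shared is None
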