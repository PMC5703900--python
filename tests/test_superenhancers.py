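"""Stitching, ranking, slope-1 cutoff, SE/TE partition, activity matrix."""

import numpy as np
import pytest

from enhancerscape.intervals import GenomicInterval, overlaps_any
from enhancerscape.superenhancers import (
    activity_matrix,
    call_se_te,
    flag_se,
    score_region,
    se_cutoff,
    stitch,
)

from conftest import track_from_counts


def gi(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestStitch:
    def test_gap_within_stitch_distance_merges(self):
        out = stitch([gi(0, 500), gi(10_000, 10_500)])  # gap 9500 <= 12500
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (0, 10_500)
        assert out[0].constituent_ids == [0, 1]

    def test_gap_beyond_stitch_distance_splits(self):
        out = stitch([gi(0, 500), gi(14_000, 14_500)])  # gap 13500 > 12500
        assert [o.interval for o in out] == [gi(0, 500), gi(14_000, 14_500)]

    def test_single_ce_is_itself(self):
        out = stitch([gi(100, 400)])
        assert len(out) == 1 and out[0].constituent_ids == [0]

    def test_transitive_merging(self):
        ces = [gi(0, 500), gi(10_000, 10_500), gi(20_000, 20_500)]
        out = stitch(ces)
        assert len(out) == 1
        assert out[0].constituent_ids == [0, 1, 2]

    def test_chromosomes_never_stitch_together(self):
        out = stitch([gi(0, 500, "chr1"), gi(600, 1_000, "chr2")])
        assert len(out) == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            stitch([gi(10_000, 10_500), gi(0, 500)])

    def test_idempotent(self):
        ces = [gi(0, 500), gi(5_000, 5_500), gi(40_000, 40_500)]
        once = stitch(ces)
        again = stitch([o.interval for o in once])
        assert [o.interval for o in again] == [o.interval for o in once]


class TestScoreRegion:
    def test_input_subtraction(self):
        # sample 10 rpm, input 4 rpm over the region -> 6
        sample = track_from_counts({"chr1": [10, 0, 0, 0]}, total_mapped=1_000_000)
        inp = track_from_counts({"chr1": [4, 0, 0, 0]}, total_mapped=1_000_000)
        assert score_region(sample, inp, gi(0, 25)) == pytest.approx(6.0)

    def test_floor_at_zero_when_input_dominates(self):
        sample = track_from_counts({"chr1": [2, 0]}, total_mapped=1_000_000)
        inp = track_from_counts({"chr1": [9, 0]}, total_mapped=1_000_000)
        assert score_region(sample, inp, gi(0, 25)) == 0.0

    def test_zero_count_region(self):
        sample = track_from_counts({"chr1": [0, 0]}, total_mapped=1_000)
        inp = track_from_counts({"chr1": [0, 0]}, total_mapped=1_000)
        assert score_region(sample, inp, gi(0, 50)) == 0.0

    def test_length_normalized_variant(self):
        sample = track_from_counts({"chr1": [10, 10, 0, 0]}, total_mapped=1_000_000)
        inp = track_from_counts({"chr1": [0, 0, 0, 0]}, total_mapped=1_000_000)
        plain = score_region(sample, inp, gi(0, 50))
        dens = score_region(sample, inp, gi(0, 50), length_normalized=True)
        assert dens == pytest.approx(plain / 0.05)

    def test_empty_region_rejected(self):
        sample = track_from_counts({"chr1": [1]})
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)


class TestSeCutoff:
    def test_one_outlier_is_the_single_se(self):
        thr = se_cutoff([1, 1, 1, 1, 100])
        assert thr == 1.0
        flags = flag_se([1, 1, 1, 1, 100])
        assert flags.sum() == 1 and flags[np.argmax([1, 1, 1, 1, 100])]

    def test_all_equal_gives_zero_ses(self):
        assert se_cutoff([5, 5, 5, 5]) == 5.0
        assert flag_se([5, 5, 5, 5]).sum() == 0

    def test_all_zero_gives_zero_ses(self):
        assert se_cutoff([0, 0, 0]) == 0.0
        assert flag_se([0.0, 0.0, 0.0]).sum() == 0

    def test_fewer_than_two_signals_error(self):
        with pytest.raises(ValueError):
            se_cutoff([1.0])

    def test_negative_signal_error(self):
        with pytest.raises(ValueError):
            se_cutoff([1.0, -0.5])

    def test_planted_outliers_separate_from_lognormal_background(self):
        # 200 LogNormal(0, 0.25) background signals + 10 planted at 50x the
        # background median: the planted ten must sit above the cutoff in
        # >= 95 of 100 seeded trials
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            bg = rng.lognormal(0.0, 0.25, size=200)
            planted = np.full(10, 50.0 * np.median(bg))
            signals = np.concatenate([bg, planted])
            thr = se_cutoff(signals)
            wins += bool((planted > thr).all())
        assert wins >= 95

    def test_raising_a_signal_never_demotes_it(self):
        # monotonicity under the cutoff rule, checked over 1000 random
        # perturbations of a fixed signal set
        rng = np.random.default_rng(42)
        base = rng.lognormal(0.0, 1.0, size=50)
        base_flags = flag_se(base)
        for _ in range(1000):
            i = int(rng.integers(50))
            bumped = base.copy()
            bumped[i] *= 1.0 + rng.uniform(0.0, 5.0)
            new_flags = flag_se(bumped)
            if base_flags[i]:
                assert new_flags[i]


def _uniform_tracks(n_bins=4000, lam=5, spikes=(), seed=0, total=None):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=n_bins)
    for b0, b1, val in spikes:
        counts[b0:b1] = val
    return track_from_counts({"chr1": counts}, total_mapped=total or int(counts.sum()))


class TestCallSeTe:
    def _setup(self, rep2_has_cluster=True):
        # two spiked regions: a broad cluster (bins 100..140) and a small
        # isolated site (bins 2000..2008), on a Poisson background
        cluster = (100, 140, 200)
        iso = (2000, 2008, 60)
        spikes1 = [cluster, iso]
        spikes2 = [cluster, iso] if rep2_has_cluster else [iso]
        tracks = {
            ("ESC", 1): _uniform_tracks(spikes=spikes1, seed=1),
            ("ESC", 2): _uniform_tracks(spikes=spikes2, seed=2),
        }
        inputs = {"ESC": _uniform_tracks(seed=3)}
        ces = [gi(2500, 3500), gi(50_000, 50_200)]
        per_cond = {"ESC": ces}
        return tracks, inputs, per_cond, ces

    def test_se_requires_both_replicates(self):
        # region strongly enriched in rep1 only -> not SE for the condition
        ces = [gi(2500, 3500), gi(50_000, 50_200)]
        tracks = {
            ("ESC", 1): _uniform_tracks(spikes=[(100, 140, 300)], seed=1),
            ("ESC", 2): _uniform_tracks(seed=2),
        }
        inputs = {"ESC": _uniform_tracks(seed=3)}
        res = call_se_te(tracks, inputs, {"ESC": [gi(2500, 3500)]}, ces)
        assert res.per_condition_se["ESC"] == []

    def test_union_and_te_partition(self):
        # strong region in both replicates becomes SE; every CE is either
        # TE or overlaps the SE union, never both
        tracks = {
            ("ESC", 1): _uniform_tracks(spikes=[(100, 140, 300)], seed=1),
            ("ESC", 2): _uniform_tracks(spikes=[(100, 140, 300)], seed=2),
        }
        inputs = {"ESC": _uniform_tracks(seed=3)}
        background_ces = [gi(s, s + 200) for s in (40_000, 55_000, 70_000, 85_000)]
        ces = [gi(2500, 3500), gi(2500 * 25, 2508 * 25)] + background_ces
        per_cond = {"ESC": [gi(2500, 3500)] + background_ces}
        res = call_se_te(tracks, inputs, per_cond, ces)
        assert res.global_se  # the spiked stitched region is SE
        for ce in ces:
            in_se = overlaps_any(ce, res.global_se)
            in_te = ce in res.te
            assert in_se != in_te

    def test_missing_replicate_error(self):
        tracks = {("ESC", 1): _uniform_tracks(seed=1)}
        inputs = {"ESC": _uniform_tracks(seed=3)}
        with pytest.raises(ValueError, match="missing replicate"):
            call_se_te(tracks, inputs, {"ESC": [gi(0, 200)]}, [gi(0, 200)])

    def test_no_ces_no_ses(self):
        tracks = {
            ("ESC", 1): _uniform_tracks(seed=1),
            ("ESC", 2): _uniform_tracks(seed=2),
        }
        inputs = {"ESC": _uniform_tracks(seed=3)}
        res = call_se_te(tracks, inputs, {"ESC": []}, [])
        assert res.global_se == [] and res.te == []


class TestActivityMatrix:
    def test_membership_patterns(self):
        e1, e2, e3 = gi(0, 100), gi(1_000, 1_100), gi(2_000, 2_100)
        per_cond = {
            "ESC": [gi(0, 100), gi(1_000, 1_100), gi(2_000, 2_100)],
            "Eo-": [gi(0, 100), gi(1_000, 1_100), gi(2_000, 2_100)],
            "Eo+": [gi(2_000, 2_100)],
        }
        m = activity_matrix([e1, e2, e3], per_cond)
        assert m.loc[str(e1)].tolist() == [True, True, False]
        assert m.loc[str(e3)].tolist() == [True, True, True]

    def test_one_bp_overlap_counts(self):
        e = gi(0, 100)
        m = activity_matrix([e], {"ESC": [gi(99, 300)], "Eo+": [gi(100, 300)]})
        assert m.loc[str(e), "ESC"]
        assert not m.loc[str(e), "Eo+"]

    def test_only_one_condition(self):
        e = gi(500, 700)
        m = activity_matrix([e], {"ESC": [], "Eo-": [], "Eo+": [gi(600, 650)]})
        assert m.loc[str(e)].tolist() == [False, False, True]
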