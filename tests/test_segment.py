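"""CBS change-point detection, sliding windows, segment filtering, calibration."""

import numpy as np
import pandas as pd
import pytest

from strainmask import (
    Segment,
    SegmentFilter,
    calibrate_virtual_chromosome,
    cbs_segment,
    filter_segments,
    max_arc_statistic,
    sliding_window_scan,
)
from strainmask.config import VIRTUAL_CHROM
from strainmask.normalize import RatioTrack

from conftest import make_linear_design


def brute_force_max_arc(x):
    """Independent O(n^2) oracle: plain loops, plain means."""
    n = len(x)
    best, bi, bj = -1.0, 0, 1
    for i in range(n):
        for j in range(i + 1, n + 1):
            if j - i == n:
                continue
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            stat = abs(np.mean(arc) - np.mean(rest)) / np.sqrt(1 / len(arc) + 1 / len(rest))
            if stat > best:
                best, bi, bj = stat, i, j
    return best, bi, bj


def track_from_m(m):
    return RatioTrack(
        pd.DataFrame({"probe_id": [f"P{i:06d}" for i in range(len(m))], "M": m, "A": 10.0}),
    )


class TestMaxArcStatistic:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        x = rng.normal(0, 1, n)
        # optionally add up to 2 change points
        for _ in range(int(rng.integers(0, 3))):
            lo = int(rng.integers(0, n - 1))
            hi = int(rng.integers(lo + 1, n))
            x[lo:hi] += rng.choice([-2.0, 2.0])
        stat, i, j = max_arc_statistic(x)
        b_stat, b_i, b_j = brute_force_max_arc(x)
        assert stat == pytest.approx(b_stat)
        assert (i, j) == (b_i, b_j)

    def test_tie_breaks_to_earliest_arc(self):
        x = np.array([1.0, 0.0, 0.0, 1.0])  # symmetric: several equal-stat arcs
        _, i, j = max_arc_statistic(x)
        b_stat, b_i, b_j = brute_force_max_arc(x)
        assert (i, j) == (b_i, b_j)


class TestCbsSegment:
    def test_constant_signal_is_single_segment(self):
        segs = cbs_segment(np.full(60, 1.3), n_perm=200, seed=0, chrom="c")
        assert len(segs) == 1
        assert segs[0].start_index == 0 and segs[0].end_index == 60
        assert segs[0].mean_M == pytest.approx(1.3)

    def test_clean_step_found_with_boundary_within_one_probe(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(2, 0.1, 30)])
        segs = cbs_segment(x, alpha=0.05, n_perm=2000, seed=0, chrom="c")
        assert len(segs) == 2
        assert abs(segs[0].end_index - 30) <= 1

    def test_segment_means_conserve_chromosome_mean(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.3, 50), rng.normal(-1.5, 0.3, 40), rng.normal(0.5, 0.3, 60)])
        segs = cbs_segment(x, n_perm=1000, seed=0)
        weighted = sum(s.mean_M * s.n_probes for s in segs) / len(x)
        assert weighted == pytest.approx(x.mean())
        # segments tile the chromosome without overlap
        assert segs[0].start_index == 0 and segs[-1].end_index == len(x)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_index == b.start_index

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 80)
        s1 = cbs_segment(x, n_perm=500, seed=42)
        s2 = cbs_segment(x, n_perm=500, seed=42)
        assert s1 == s2

    def test_coarse_permutation_resolution_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            cbs_segment(np.zeros(10), n_perm=50)

    def test_strong_segment_p_value_reaches_genome_wide_cutoff(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.25, 60), rng.normal(-1, 0.25, 40), rng.normal(0, 0.25, 60)])
        segs = cbs_segment(x, n_perm=2000, seed=0)
        deleted = min(segs, key=lambda s: s.mean_M)
        assert deleted.p_value <= 7.4e-7


class TestSlidingWindows:
    def test_all_zero_track_gives_zero_window_means(self):
        design = make_linear_design(100)
        scan = sliding_window_scan(track_from_m(np.zeros(100)), design, window=30)
        assert scan.n_tests == 71
        assert np.allclose(scan.windows["mean_M"], 0.0)

    def test_windows_never_span_chromosomes_and_short_chromosomes_drop(self):
        d1 = make_linear_design(40, chrom="Sctg_00").table
        d2 = make_linear_design(10, chrom="Sctg_01").table
        d2["probe_id"] = ["Q%05d" % i for i in range(10)]
        from strainmask.arrayio import ArrayDesign

        design = ArrayDesign(pd.concat([d1, d2], ignore_index=True))
        m = np.zeros(50)
        track = RatioTrack(pd.DataFrame({"probe_id": design.table["probe_id"], "M": m, "A": 10.0}))
        scan = sliding_window_scan(track, design, window=30)
        assert scan.n_tests == 11  # only the 40-probe chromosome contributes
        assert set(scan.windows["chrom"]) == {"Sctg_00"}

    def test_embedded_low_block_dominates_minimum_window(self):
        rng = np.random.default_rng(5)
        m = rng.normal(0, 0.2, 300)
        m[100:140] = rng.normal(-2, 0.2, 40)
        design = make_linear_design(300)
        scan = sliding_window_scan(track_from_m(m), design, window=30)
        k = scan.windows["mean_M"].idxmin()
        row = scan.windows.loc[k]
        assert row["mean_M"] <= -1.5
        assert row["start_index"] < 140 and row["end_index"] > 100  # overlaps block


class TestSegmentFilter:
    @pytest.mark.parametrize(
        "n,mean,p,expected",
        [
            (29, -2.0, 1e-9, False),  # below min probes
            (30, -0.9, 1e-9, False),  # below min |mean|
            (40, -1.2, 1e-9, True),
            (40, -1.2, 1e-5, False),  # p above Bonferroni cutoff
        ],
    )
    def test_acceptance_rules(self, n, mean, p, expected):
        seg = Segment("c", 0, n, mean_M=mean, p_value=p)
        assert SegmentFilter().accepts(seg) is expected

    def test_bonferroni_construction_stores_alpha_and_n_tests(self):
        f = SegmentFilter.from_bonferroni(0.05, 68240)
        assert f.p_cutoff == pytest.approx(0.05 / 68240)
        assert f.alpha == 0.05 and f.n_tests == 68240


class TestVirtualCalibration:
    def _design_with_virtual(self, n_virtual, m_virtual, seed=0):
        rng = np.random.default_rng(seed)
        base = make_linear_design(60).table
        virt = pd.DataFrame(
            {
                "probe_id": [f"V{i:05d}" for i in range(n_virtual)],
                "seq_id": [f"VS{i // 4:05d}" for i in range(n_virtual)],
                "region": "CDS",
                "chrom": VIRTUAL_CHROM,
                "position": np.arange(n_virtual) * 10,
                "families": "",
            }
        )
        from strainmask.arrayio import ArrayDesign

        design = ArrayDesign(pd.concat([base, virt], ignore_index=True))
        m = np.concatenate([rng.normal(0, 0.3, 60), m_virtual])
        track = RatioTrack(pd.DataFrame({"probe_id": design.table["probe_id"], "M": m, "A": 10.0}))
        return design, track

    def test_null_virtual_probes_pass_reference_filter(self):
        rng = np.random.default_rng(6)
        design, track = self._design_with_virtual(200, rng.normal(0, 0.3, 200))
        report = calibrate_virtual_chromosome(track, design, [SegmentFilter()], n_perm=500, seed=0)
        assert report.achieved_zero
        assert report.false_positives[0][1] == 0

    def test_seeded_block_rejects_lax_filter_and_selection_is_first_zero(self):
        rng = np.random.default_rng(7)
        m_virt = rng.normal(0, 0.2, 200)
        m_virt[50:90] = rng.normal(-2, 0.2, 40)
        design, track = self._design_with_virtual(200, m_virt)
        lax = SegmentFilter(min_probes=30, min_abs_mean=1.0, p_cutoff=7.4e-7)
        strict = SegmentFilter(min_probes=60, min_abs_mean=2.5, p_cutoff=7.4e-7)
        report = calibrate_virtual_chromosome(track, design, [lax, strict], n_perm=2000, seed=0)
        fp = dict((id(f), n) for f, n in report.false_positives)
        assert fp[id(lax)] >= 1  # the planted block trips the published settings
        assert report.chosen == strict and report.achieved_zero

    def test_no_candidate_achieving_zero_warns_and_returns_most_stringent(self):
        rng = np.random.default_rng(8)
        m_virt = rng.normal(0, 0.2, 200)
        m_virt[50:90] = rng.normal(-3, 0.2, 40)
        design, track = self._design_with_virtual(200, m_virt)
        lax = SegmentFilter(min_probes=10, min_abs_mean=0.5, p_cutoff=1e-3)
        with pytest.warns(UserWarning, match="no candidate"):
            report = calibrate_virtual_chromosome(track, design, [lax], n_perm=500, seed=0)
        assert not report.achieved_zero


def test_filter_segments_keeps_only_passing():
    segs = [
        Segment("c", 0, 40, -1.2, 1e-9),
        Segment("c", 40, 69, -2.0, 1e-9),
        Segment("c", 69, 99, 0.2, 1e-9),
    ]
    assert filter_segments(segs, SegmentFilter()) == [segs[0]]
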