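"""Loop filtering, anchor windows and loop-weighted target scoring."""

import numpy as np
import pytest

from bafkit.intervals import (
    GenomicInterval,
    PromoterAnnotation,
    SignalTrack,
    make_tss_window,
    overlaps,
    window_signal,
)
from bafkit.loops import (
    Loop,
    anchor_window,
    assign_loops_to_promoter,
    cumulative_target_score,
    distal_score,
    filter_loops,
)


def loop(a1, a2, score=1.0, fdr=0.01, chrom="chr1"):
    return Loop(GenomicInterval(chrom, *a1), GenomicInterval(chrom, *a2), score, fdr)


class TestFilterLoops:
    def test_subthreshold_fdr_retained(self):
        assert filter_loops([loop((0, 100), (5000, 5100), fdr=0.049)])

    def test_boundary_fdr_dropped(self):
        # "less than 0.05" is strict: FDR exactly 0.05 fails
        assert filter_loops([loop((0, 100), (5000, 5100), fdr=0.05)]) == []

    def test_empty_input(self):
        assert filter_loops([]) == []


class TestAnchorWindow:
    def test_centered_on_midpoint(self):
        w = anchor_window(GenomicInterval("chr1", 50_000, 50_500))
        assert (w.start, w.end) == (48_250, 52_250)

    def test_width_is_4kb_when_unclipped(self):
        w = anchor_window(GenomicInterval("chr1", 123_000, 124_700))
        assert w.width == 4000

    def test_clipped_at_zero(self):
        w = anchor_window(GenomicInterval("chr1", 500, 1500))
        assert (w.start, w.end) == (0, 3000)


class TestAssignment:
    p = PromoterAnnotation("g1", "chr1", 10_000)

    def test_proximal_anchor1_assigns_anchor2_distal(self):
        l = loop((9500, 10_500), (50_000, 51_000))
        ((_, distal),) = assign_loops_to_promoter(self.p, [l])
        assert distal == l.anchor2

    def test_proximal_anchor2_assigns_anchor1_distal(self):
        l = loop((50_000, 51_000), (9500, 10_500))
        ((_, distal),) = assign_loops_to_promoter(self.p, [l])
        assert distal == l.anchor1

    def test_neither_anchor_overlapping_not_assigned(self):
        l = loop((30_000, 31_000), (50_000, 51_000))
        assert assign_loops_to_promoter(self.p, [l]) == []

    def test_both_anchors_proximal_excluded(self):
        l = loop((8500, 9000), (10_500, 11_000))
        assert assign_loops_to_promoter(self.p, [l]) == []


class TestDistalScore:
    def test_hand_computed_single_loop(self):
        # constant 3.0/bp over the whole distal 4 kb window, loop score 2.0
        track = SignalTrack([(GenomicInterval("chr1", 40_000, 60_000), 3.0)])
        l = loop((9500, 10_500), (49_750, 50_250), score=2.0)
        assert distal_score([(l, l.anchor2)], track) == pytest.approx(24_000.0)

    def test_zero_loop_score_contributes_nothing(self):
        track = SignalTrack([(GenomicInterval("chr1", 40_000, 60_000), 3.0)])
        l = loop((9500, 10_500), (49_750, 50_250), score=0.0)
        assert distal_score([(l, l.anchor2)], track) == 0.0

    def test_no_loops_scores_zero(self):
        track = SignalTrack([(GenomicInterval("chr1", 0, 1000), 1.0)])
        assert distal_score([], track) == 0.0


class TestCumulativeScore:
    p = PromoterAnnotation("g1", "chr1", 10_000)

    def test_empty_tracks_score_zero(self):
        tracks = {"fusion": SignalTrack(), "H2AK119ub": SignalTrack()}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = cumulative_target_score(self.p, [], tracks)
        assert ts.total == 0.0

    def test_missing_track_is_an_error(self):
        with pytest.raises(ValueError, match="H2AK119ub"):
            cumulative_target_score(self.p, [], {"fusion": SignalTrack()})

    def test_fusion_only_signal_equals_fusion_component(self):
        fusion = SignalTrack([(GenomicInterval("chr1", 9000, 11_000), 2.0)])
        tracks = {"fusion": fusion, "H2AK119ub": SignalTrack([
            (GenomicInterval("chr1", 0, 10), 0.0)])}
        ts = cumulative_target_score(self.p, [], tracks)
        assert ts.total == pytest.approx(ts.per_track["fusion"][0]) == 4000.0

    def test_two_loops_sum_of_hand_computations(self):
        fusion = SignalTrack([
            (GenomicInterval("chr1", 9000, 11_000), 2.0),     # promoter: 4000
            (GenomicInterval("chr1", 49_500, 50_500), 5.0),   # enhancer A: 5000
            (GenomicInterval("chr1", 79_500, 80_500), 1.0),   # enhancer B: 1000
        ])
        ub = SignalTrack([(GenomicInterval("chr1", 49_500, 50_500), 3.0)])
        loops = [
            loop((9500, 10_500), (49_750, 50_250), score=2.0),
            loop((9500, 10_500), (79_750, 80_250), score=4.0),
        ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = cumulative_target_score(self.p, loops, {"fusion": fusion,
                                                         "H2AK119ub": ub})
        assert ts.promoter_component == pytest.approx(4000.0)
        # fusion distal: 2·5000 + 4·1000; ub distal: 2·3000
        assert ts.distal_component == pytest.approx(14_000.0 + 6000.0)
        assert ts.total == ts.promoter_component + ts.distal_component

    def test_linear_in_track_scaling(self):
        fusion = SignalTrack([
            (GenomicInterval("chr1", 9000, 11_000), 2.0),
            (GenomicInterval("chr1", 49_500, 50_500), 5.0),
        ])
        ub = SignalTrack([(GenomicInterval("chr1", 49_600, 50_400), 1.5)])
        loops = [loop((9500, 10_500), (49_750, 50_250), score=2.0)]
        base = cumulative_target_score(self.p, loops, {"fusion": fusion, "H2AK119ub": ub})
        scaled = cumulative_target_score(
            self.p, loops, {"fusion": fusion.scale(3.0), "H2AK119ub": ub.scale(3.0)}
        )
        assert scaled.total == pytest.approx(3.0 * base.total)

    def test_agreement_with_naive_promoters_by_loops_oracle(self):
        rng = np.random.default_rng(17)
        promoters = [
            PromoterAnnotation(f"g{i}", "chr1", int(t))
            for i, t in enumerate(sorted(rng.integers(10_000, 2_000_000, 50)))
        ]
        loops = []
        for _ in range(200):
            a = int(rng.integers(5000, 2_000_000))
            b = int(rng.integers(5000, 2_000_000))
            loops.append(loop((a, a + 1000), (b, b + 1000),
                              score=float(rng.random() * 3),
                              fdr=float(rng.random() * 0.1)))
        runs, pos = [], 0
        while pos < 2_100_000:
            w = int(rng.integers(500, 3000))
            runs.append((GenomicInterval("chr1", pos, pos + w),
                         float(rng.random() * 4)))
            pos += w + int(rng.integers(0, 2000))
        track = SignalTrack(runs)
        tracks = {"fusion": track, "H2AK119ub": track.scale(0.5)}
        hi = filter_loops(loops)
        for p in promoters:
            ts = cumulative_target_score(p, hi, tracks)
            # naive oracle: scan every loop against every promoter window
            w = make_tss_window(p, 2000)
            prom = sum(window_signal(t, w) for t in tracks.values())
            dist = 0.0
            for l in hi:
                h1, h2 = overlaps(l.anchor1, w), overlaps(l.anchor2, w)
                if h1 == h2:
                    continue
                distal = l.anchor2 if h1 else l.anchor1
                aw = anchor_window(distal)
                dist += l.loop_score * sum(
                    window_signal(t, aw) for t in tracks.values()
                )
            assert ts.promoter_component == pytest.approx(prom, rel=1e-9)
            assert ts.distal_component == pytest.approx(dist, rel=1e-9)

    def test_removing_a_loop_subtracts_exactly_its_term(self):
        fusion = SignalTrack([
            (GenomicInterval("chr1", 9000, 11_000), 2.0),
            (GenomicInterval("chr1", 49_500, 50_500), 5.0),
            (GenomicInterval("chr1", 79_500, 80_500), 1.0),
        ])
        ub = SignalTrack([(GenomicInterval("chr1", 0, 10), 0.0)])
        l1 = loop((9500, 10_500), (49_750, 50_250), score=2.0)
        l2 = loop((9500, 10_500), (79_750, 80_250), score=4.0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            both = cumulative_target_score(self.p, [l1, l2],
                                           {"fusion": fusion, "H2AK119ub": ub})
            one = cumulative_target_score(self.p, [l1],
                                          {"fusion": fusion, "H2AK119ub": ub})
            term = distal_score([(l2, l2.anchor2)], fusion)
        assert both.distal_component - one.distal_component == pytest.approx(term)
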