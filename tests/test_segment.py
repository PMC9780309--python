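"""Inter/intra counting, smoothing, thresholding with bridging, edge
alignment, the error functional and event annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proxinet import segment as sg
from proxinet.errors import BoundaryError, ConfigError, UnknownBadgeError
from proxinet.types import BinaryStateSequence, ContactEvent, PeriodSegment

from conftest import S

SPAN = (S, S + 1200)


def states_of(i, j, on_slots, all_slots):
    sl = np.array(sorted(all_slots))
    return BinaryStateSequence(i, j, sl,
                               np.isin(sl, list(on_slots)).astype(int))


class TestCounting:
    CLASSES = {"0001": 1, "0002": 1, "0003": 2, "1004": 1}

    def test_full_bin_intra_dyad_counts_two_states(self):
        # a 10-s bin holds two 5-s slots
        seqs = {("0001", "0002"): states_of("0001", "0002",
                                            {S, S + 5}, {S, S + 5})}
        curves = sg.count_inter_intra(seqs, self.CLASSES, SPAN)
        assert curves[1].intra[0] == 2
        assert curves[1].inter[0] == 0

    def test_cross_class_counts_on_both_curves(self):
        seqs = {("0001", "0003"): states_of("0001", "0003", {S}, {S})}
        curves = sg.count_inter_intra(seqs, self.CLASSES, SPAN)
        assert curves[1].inter[0] == 1 and curves[2].inter[0] == 1
        assert curves[1].intra[0] == 0

    def test_adult_dyads_excluded(self):
        seqs = {("0001", "1004"): states_of("0001", "1004", {S}, {S})}
        curves = sg.count_inter_intra(seqs, self.CLASSES, SPAN)
        assert curves[1].intra[0] == 0 and curves[1].inter[0] == 0

    def test_unmapped_participant_rejected(self):
        seqs = {("0001", "0999"): states_of("0001", "0999", {S}, {S})}
        with pytest.raises(UnknownBadgeError):
            sg.count_inter_intra(seqs, self.CLASSES, SPAN)

    def test_counts_match_brute_tally(self):
        rng = np.random.default_rng(1)
        dyads = [("0001", "0002"), ("0001", "0003"), ("0002", "0003")]
        seqs = {}
        for d in dyads:
            slots = S + 5 * np.sort(rng.choice(240, 100, replace=False))
            on = set(slots[rng.random(100) < 0.4].tolist())
            seqs[d] = states_of(*d, on, slots)
        curves = sg.count_inter_intra(seqs, self.CLASSES, SPAN)
        for c in (1, 2):
            inter = np.zeros(120)
            intra = np.zeros(120)
            for (i, j), sq in seqs.items():
                ci, cj = self.CLASSES[i], self.CLASSES[j]
                for t, v in zip(sq.slots, sq.states):
                    if not v:
                        continue
                    b = (t - S) // 10
                    if ci == cj == c:
                        intra[b] += 1
                    elif c in (ci, cj) and ci != cj:
                        inter[b] += 1
            assert np.array_equal(curves[c].inter, inter)
            assert np.array_equal(curves[c].intra, intra)


class TestSmoothingAndRatio:
    def test_constant_series_unchanged(self):
        cv = sg.ActivityCurve(1, np.arange(50), np.full(50, 3.0),
                              np.full(50, 7.0))
        sg.smooth_counts(cv)
        assert cv.smoothed_inter == pytest.approx(np.full(50, 3.0))

    def test_impulse_becomes_normalised_kernel(self):
        x = np.zeros(101)
        x[50] = 1.0
        cv = sg.ActivityCurve(1, np.arange(101), x, x.copy())
        sg.smooth_counts(cv, sigma_bins=3)
        assert cv.smoothed_inter.sum() == pytest.approx(1.0)
        assert cv.smoothed_inter[50] == cv.smoothed_inter.max()

    def test_zero_intra_defaults_to_twice_threshold(self):
        cv = sg.ActivityCurve(1, np.arange(10), np.zeros(10), np.zeros(10))
        params = sg.SegmentationParams(ratio_threshold=0.15)
        ratio = sg.compute_ratio(cv, params)
        assert ratio == pytest.approx(np.full(10, 0.30))

    def test_ratio_is_elementwise_division(self):
        rng = np.random.default_rng(0)
        inter = rng.uniform(0, 5, 40)
        intra = rng.uniform(1, 30, 40)
        cv = sg.ActivityCurve(1, np.arange(40), inter, intra)
        cv.smoothed_inter, cv.smoothed_intra = inter, intra
        ratio = sg.compute_ratio(cv, sg.SegmentationParams())
        assert ratio == pytest.approx(inter / intra)
        assert sg.compute_ratio(
            sg.ActivityCurve(1, np.arange(1), np.array([3.0]),
                             np.array([30.0])),
            sg.SegmentationParams())[0] == pytest.approx(0.1)


def brute_bridge(labels, gap_bins):
    """Fixpoint absorption oracle: C-runs inside F first, then F in C."""
    lab = list(labels)

    def runs():
        out, s = [], 0
        for k in range(1, len(lab) + 1):
            if k == len(lab) or lab[k] != lab[s]:
                out.append((lab[s], s, k))
                s = k
        return out

    for minority in "CF":
        changed = True
        while changed:
            changed = False
            rs = runs()
            for k, (v, s, e) in enumerate(rs):
                if v == minority and 0 < k < len(rs) - 1 and e - s < gap_bins:
                    lab[s:e] = ["F" if minority == "C" else "C"] * (e - s)
                    changed = True
                    break
    return np.array(lab)


class TestSegmentPeriods:
    def test_all_low_ratio_single_class_segment(self):
        params = sg.SegmentationParams()
        segs = sg.segment_periods(np.zeros(120), params, SPAN, 1)
        assert segs == [PeriodSegment(1, *SPAN, "C")]

    def test_short_class_interruption_bridged(self):
        # F(1200 s), C(300 s), F(1200 s) with gap 600 -> one F block
        ratio = np.concatenate([np.full(120, 1.0), np.zeros(30),
                                np.full(120, 1.0)])
        span = (S, S + 2700)
        segs = sg.segment_periods(ratio, sg.SegmentationParams(), span, 3)
        assert segs == [PeriodSegment(3, S, S + 2700, "F")]

    def test_segments_tile_span(self):
        rng = np.random.default_rng(2)
        ratio = rng.uniform(0, 0.4, 120)
        segs = sg.segment_periods(ratio, sg.SegmentationParams(), SPAN, 1)
        assert segs[0].start == SPAN[0] and segs[-1].end == SPAN[1]
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start and a.label != b.label

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from("FC"), min_size=1, max_size=50),
           st.integers(1, 10))
    def test_bridging_equals_fixpoint_oracle(self, labels, gap_bins):
        got = sg.bridge_labels(np.array(labels), gap_bins)
        assert np.array_equal(got, brute_bridge(labels, gap_bins))


class TestAlignEdges:
    def test_first_in_last_out_clipped_to_second(self):
        a = [PeriodSegment(1, 0, 5400, "C"),
             PeriodSegment(1, 5400, 9000, "F"),
             PeriodSegment(1, 9000, 10000, "C")]
        b = [PeriodSegment(2, 0, 6000, "C"),
             PeriodSegment(2, 6000, 9600, "F"),
             PeriodSegment(2, 9600, 10000, "C")]
        out = sg.align_edges({1: a, 2: b})
        f1 = [(s.start, s.end) for s in out[1] if s.label == "F"]
        f2 = [(s.start, s.end) for s in out[2] if s.label == "F"]
        assert f1 == [(6000, 9000)] and f2 == [(6000, 9000)]

    def test_lone_class_free_time_relabelled(self):
        a = [PeriodSegment(1, 0, 500, "F"), PeriodSegment(1, 500, 1000, "C")]
        b = [PeriodSegment(2, 0, 1000, "C")]
        out = sg.align_edges({1: a, 2: b})
        assert all(s.label == "C" for s in out[1])

    def test_every_retained_free_instant_shared(self):
        """Interval-overlap oracle on random segmentations."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            segs = {}
            for c in range(1, 5):
                cuts = np.sort(rng.choice(np.arange(10, 1000, 10), 6,
                                          replace=False))
                bounds = [0, *cuts.tolist(), 1000]
                labels = ["C", "F"] * 4
                rng.shuffle(labels)
                segs[c] = [PeriodSegment(c, a, b, l) for a, b, l in
                           zip(bounds, bounds[1:], labels)]
            out = sg.align_edges(segs)
            for c, slist in out.items():
                for s in (x for x in slist if x.label == "F"):
                    for t in range(s.start, s.end, 10):
                        n_out = sum(
                            any(o.label == "F" and o.start <= t < o.end
                                for o in out[c2])
                            for c2 in out)
                        assert n_out >= 2

    def test_output_tiles_each_class(self):
        a = [PeriodSegment(1, 0, 400, "F"), PeriodSegment(1, 400, 1000, "C")]
        b = [PeriodSegment(2, 0, 300, "F"), PeriodSegment(2, 300, 1000, "C")]
        out = sg.align_edges({1: a, 2: b})
        for slist in out.values():
            assert slist[0].start == 0 and slist[-1].end == 1000
            for x, y in zip(slist, slist[1:]):
                assert x.end == y.start


class TestErrorFunctional:
    def test_worked_example(self):
        true = [PeriodSegment(1, 0, 100, "F")]
        pred = [PeriodSegment(1, 10, 110, "F")]
        assert sg.segmentation_error(pred, true) == 20.0

    def test_zero_iff_identical(self):
        segs = [PeriodSegment(1, 0, 100, "F"), PeriodSegment(1, 100, 200, "C")]
        assert sg.segmentation_error(segs, segs) == 0.0

    def test_symmetric(self):
        a = [PeriodSegment(1, 0, 100, "F")]
        b = [PeriodSegment(1, 50, 250, "F")]
        assert sg.segmentation_error(a, b) == sg.segmentation_error(b, a)

    def test_unmatched_periods_penalised_in_full(self):
        a = [PeriodSegment(1, 0, 100, "F")]
        assert sg.segmentation_error(a, []) == 100.0

    def test_equals_slotwise_symmetric_difference(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            def rand_segs():
                cuts = np.sort(rng.choice(np.arange(1, 200), 5,
                                          replace=False))
                bounds = [0, *cuts.tolist(), 200]
                lab = rng.permutation(["F", "C", "F", "C", "F", "C"])
                return [PeriodSegment(1, a, b, l)
                        for a, b, l in zip(bounds, bounds[1:], lab)]
            p, t = rand_segs(), rand_segs()

            def fset(segs):
                return {x for s in segs if s.label == "F"
                        for x in range(s.start, s.end)}
            want = len(fset(p) ^ fset(t))
            assert sg.segmentation_error(p, t) == want


class TestGridSearch:
    def _curves(self):
        bins = np.arange(S, S + 1200, 10)
        inter = np.where((bins >= S + 400) & (bins < S + 800), 10.0, 0.0)
        intra = np.full(len(bins), 10.0)
        cv = sg.ActivityCurve(1, bins, inter, intra)
        return {1: cv}

    def test_single_cell_grid_returned(self):
        truth = {1: [PeriodSegment(1, S, S + 400, "C"),
                     PeriodSegment(1, S + 400, S + 800, "F"),
                     PeriodSegment(1, S + 800, S + 1200, "C")]}
        best, surface = sg.grid_search(self._curves(), truth, [0.2], [300],
                                       (S, S + 1200), align=False)
        assert best.ratio_threshold == 0.2 and best.gap_threshold_s == 300
        assert len(surface) == 1

    def test_surface_minimum_consistent_with_returned_params(self):
        truth = {1: [PeriodSegment(1, S, S + 400, "C"),
                     PeriodSegment(1, S + 400, S + 800, "F"),
                     PeriodSegment(1, S + 800, S + 1200, "C")]}
        best, surface = sg.grid_search(self._curves(), truth,
                                       [0.1, 0.3, 0.5], [100, 300],
                                       (S, S + 1200), align=False)
        row = surface[(surface.ratio == best.ratio_threshold)
                      & (surface.gap_s == best.gap_threshold_s)]
        assert row.error_s.iloc[0] == surface.error_s.min()

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            sg.grid_search(self._curves(), {}, [], [300], (S, S + 1200))


class TestAnnotation:
    SEGS = {
        1: [PeriodSegment(1, S, S + 40, "F"), PeriodSegment(1, S + 40, S + 100, "C")],
        2: [PeriodSegment(2, S, S + 40, "F"), PeriodSegment(2, S + 40, S + 100, "C")],
    }
    CLASSES = {"0001": 1, "0002": 1, "0003": 2}

    def test_worked_example_fcfc1(self):
        # theta = (10, i, j, 40), same class, F at start and C at the end
        ev = ContactEvent(S + 10, "0001", "0002", 40)
        recs, summary = sg.annotate_events([ev], self.SEGS, self.CLASSES)
        assert recs[0].labels == "FCFC" and recs[0].same_class == 1
        assert recs[0].label_type == "FCFC1"

    def test_cross_class_free_time_ffff0(self):
        ev = ContactEvent(S + 5, "0001", "0003", 20)
        recs, _ = sg.annotate_events([ev], self.SEGS, self.CLASSES)
        assert recs[0].label_type == "FFFF0"

    def test_boundary_belongs_to_later_segment(self):
        ev = ContactEvent(S + 10, "0001", "0002", 30)  # ends exactly at S+40
        recs, _ = sg.annotate_events([ev], self.SEGS, self.CLASSES)
        assert recs[0].labels == "FCFC"

    def test_event_outside_span_rejected(self):
        ev = ContactEvent(S + 90, "0001", "0002", 50)
        with pytest.raises(BoundaryError):
            sg.annotate_events([ev], self.SEGS, self.CLASSES)

    def test_summary_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        events = [ContactEvent(S + 5 * int(rng.integers(0, 8)),
                               *rng.choice(["0001", "0002", "0003"], 2,
                                           replace=False),
                               5 * int(rng.integers(1, 6)))
                  for _ in range(30)]
        recs, summary = sg.annotate_events(events, self.SEGS, self.CLASSES)
        assert summary["count"].sum() == 30
        assert summary.count_pct.sum() == pytest.approx(100, abs=0.1)
        assert summary.duration_pct.sum() == pytest.approx(100, abs=0.1)
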