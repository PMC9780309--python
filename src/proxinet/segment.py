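"""Free-time / class-time segmentation from the inter/intra ratio.

During class time children interact almost exclusively with classmates;
out in the shared yard they mix across classes.  Counting, per class
and per 10-s bin, the active interaction states children have with
peers of other classes (inter) and with classmates (intra), smoothing
both counts with a Gaussian kernel (sigma = 3 bins), and taking their
ratio yields a signal that is low in the classroom and high in the
yard.  Bins above a ratio threshold are free-time candidates; short
fluctuation runs below a gap threshold are bridged; and a final
alignment keeps only free time shared by at least two classes (a single
class on the move does not make a yard session).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import BoundaryError, ConfigError, UnknownBadgeError
from .netstats import annotation_summary
from .types import (BinaryStateSequence, ContactEvent, PeriodSegment,
                    TnetRecord, badge_kind)


@dataclass
class SegmentationParams:
    """Hyperparameters of the segmentation.

    ``ratio_threshold`` splits free- from class-time bins; runs of the
    opposite label shorter than ``gap_threshold_s`` are bridged;
    ``sigma_bins`` is the Gaussian smoothing width and ``bin_s`` the
    counting resolution.
    """

    ratio_threshold: float = 0.15
    gap_threshold_s: int = 600
    sigma_bins: float = 3.0
    bin_s: int = 10

    def __post_init__(self):
        if min(self.ratio_threshold, self.gap_threshold_s,
               self.sigma_bins, self.bin_s) <= 0:
            raise ConfigError("all segmentation parameters must be positive")


@dataclass
class ActivityCurve:
    """Per-class inter/intra interaction counts on a shared 10-s grid."""

    class_id: int
    bins: np.ndarray
    inter: np.ndarray
    intra: np.ndarray
    smoothed_inter: np.ndarray | None = None
    smoothed_intra: np.ndarray | None = None
    ratio: np.ndarray | None = None


def count_inter_intra(state_seqs: Mapping[tuple[str, str], BinaryStateSequence],
                      class_map: Mapping[str, int],
                      span: tuple[int, int],
                      bin_s: int = 10) -> dict[int, ActivityCurve]:
    """Tally active child-dyad states per class and 10-s bin.

    Each active 5-s state counts once; a cross-class state contributes
    to the *inter* series of both members' classes, a same-class state
    to that class's *intra* series.  Adults are excluded (the signal is
    about the children's mixing).
    """
    start, end = span
    bins = np.arange(start, end, bin_s)
    classes = sorted(set(class_map.values()))
    inter = {c: np.zeros(len(bins)) for c in classes}
    intra = {c: np.zeros(len(bins)) for c in classes}
    for (i, j), seq in state_seqs.items():
        for d in (i, j):
            if d not in class_map:
                raise UnknownBadgeError(f"participant {d} missing from class map")
        if badge_kind(i) != "child" or badge_kind(j) != "child":
            continue
        on = seq.slots[seq.states == 1]
        on = on[(on >= start) & (on < end)]
        if not len(on):
            continue
        idx = (on - start) // bin_s
        c_i, c_j = class_map[i], class_map[j]
        if c_i == c_j:
            np.add.at(intra[c_i], idx, 1)
        else:
            np.add.at(inter[c_i], idx, 1)
            np.add.at(inter[c_j], idx, 1)
    return {c: ActivityCurve(c, bins, inter[c], intra[c]) for c in classes}


def smooth_counts(curve: ActivityCurve,
                  sigma_bins: float = 3.0) -> ActivityCurve:
    """Gaussian-smooth both count series (normalised kernel, reflected
    boundaries, total count conserved away from the edges)."""
    curve.smoothed_inter = gaussian_filter1d(curve.inter.astype(float),
                                             sigma_bins, mode="reflect")
    curve.smoothed_intra = gaussian_filter1d(curve.intra.astype(float),
                                             sigma_bins, mode="reflect")
    return curve


def compute_ratio(curve: ActivityCurve,
                  params: SegmentationParams) -> np.ndarray:
    """Inter/intra ratio per bin; zero-division bins default to twice
    the ratio threshold (no intra activity reads as 'out')."""
    if curve.smoothed_inter is None:
        smooth_counts(curve, params.sigma_bins)
    num, den = curve.smoothed_inter, curve.smoothed_intra
    ratio = np.full(len(num), 2.0 * params.ratio_threshold)
    nz = den > 0
    ratio[nz] = num[nz] / den[nz]
    curve.ratio = ratio
    return ratio


def bridge_labels(labels: np.ndarray, gap_bins: int) -> np.ndarray:
    """Absorb sub-gap runs of the opposite label, C-runs inside F first.

    A maximal run strictly shorter than ``gap_bins`` sandwiched between
    two runs of the other label is rewritten; within a phase the result
    is order-independent (absorbing one run never changes whether
    another qualifies).
    """
    out = labels.copy()
    for minority in ("C", "F"):
        runs = _runs(out)
        for k, (lab, s, e) in enumerate(runs):
            if (lab == minority and 0 < k < len(runs) - 1
                    and (e - s) < gap_bins):
                out[s:e] = "F" if minority == "C" else "C"
    return out


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    runs = []
    s = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[s]:
            runs.append((labels[s], s, k))
            s = k
    return runs


def segment_periods(ratio: np.ndarray, params: SegmentationParams,
                    span: tuple[int, int],
                    class_id: int = 0) -> list[PeriodSegment]:
    """Threshold the ratio and bridge fluctuations into a tiling of the
    half-day: bins at or above the threshold are free-time candidates,
    sub-gap runs of either label are absorbed by their neighbours."""
    start, end = span
    labels = np.where(ratio >= params.ratio_threshold, "F", "C")
    gap_bins = params.gap_threshold_s // params.bin_s
    labels = bridge_labels(labels, gap_bins)
    segs = []
    for lab, s, e in _runs(labels):
        seg_end = end if e == len(labels) else start + e * params.bin_s
        segs.append(PeriodSegment(class_id, start + s * params.bin_s,
                                  seg_end, lab))
    return segs


# ---------------------------------------------------------------------------
# alignment correction

def _free_intervals(segments: Iterable[PeriodSegment]) -> list[tuple[int, int]]:
    return sorted((s.start, s.end) for s in segments if s.label == "F")


def align_edges(segments_by_class: Mapping[int, Sequence[PeriodSegment]]
                ) -> dict[int, list[PeriodSegment]]:
    """Keep only free time shared by at least two classes.

    Every class's detected free time is intersected with the set of
    instants where at least two classes were detected free
    (simultaneously, against the unaligned input, so the correction is
    order-independent).  This clips the first class into the yard to
    the second arrival and the last one out to the second departure,
    and relabels lone-class free periods as class time.
    """
    events: list[tuple[int, int]] = []
    for segs in segments_by_class.values():
        for s, e in _free_intervals(segs):
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    shared: list[tuple[int, int]] = []
    depth, open_t = 0, None
    for t, d in events:
        depth += d
        if depth >= 2 and open_t is None:
            open_t = t
        elif depth < 2 and open_t is not None:
            if t > open_t:
                shared.append((open_t, t))
            open_t = None
    out = {}
    for c, segs in segments_by_class.items():
        span = (min(s.start for s in segs), max(s.end for s in segs))
        free = _intersect(_free_intervals(segs), shared)
        out[c] = _tile(span, free, c)
    return out


def _intersect(a: list[tuple[int, int]],
               b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    res, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        lo, hi = max(a[i][0], b[j][0]), min(a[i][1], b[j][1])
        if lo < hi:
            res.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return res


def _tile(span: tuple[int, int], free: list[tuple[int, int]],
          class_id: int) -> list[PeriodSegment]:
    segs, cur = [], span[0]
    for s, e in free:
        if s > cur:
            segs.append(PeriodSegment(class_id, cur, s, "C"))
        segs.append(PeriodSegment(class_id, s, e, "F"))
        cur = e
    if cur < span[1]:
        segs.append(PeriodSegment(class_id, cur, span[1], "C"))
    return segs


# ---------------------------------------------------------------------------
# error functional and grid search

def segmentation_error(pred: Sequence[PeriodSegment],
                       true: Sequence[PeriodSegment]) -> float:
    """Free-time identification error in seconds.

    For a matched pair of free periods the contribution is
    tau_pred + tau_true − 2·tau_overlap; unmatched periods contribute
    their whole duration.  Summed over periods this equals the measure
    of the symmetric difference of the two free-time sets, which is how
    it is computed (exactly, interval-wise): symmetric, non-negative,
    and zero iff the free-time sets coincide.
    """
    a, b = _free_intervals(pred), _free_intervals(true)
    inter = sum(e - s for s, e in _intersect(a, b))
    len_a = sum(e - s for s, e in a)
    len_b = sum(e - s for s, e in b)
    return float(len_a + len_b - 2 * inter)


def grid_search(curves: Mapping[int, ActivityCurve],
                truth: Mapping[int, Sequence[PeriodSegment]],
                ratio_grid: Sequence[float], gap_grid: Sequence[int],
                span: tuple[int, int],
                sigma_bins: float = 3.0, bin_s: int = 10,
                align: bool = True) -> tuple[SegmentationParams, pd.DataFrame]:
    """Exhaustive search of (ratio, gap) minimising total error.

    Ties break deterministically to the smaller gap, then the smaller
    ratio.  Returns the winning parameters and the full error surface.
    """
    if not len(ratio_grid) or not len(gap_grid):
        raise ConfigError("ratio and gap grids must be non-empty")
    rows = []
    best: tuple[float, int, float] | None = None
    for gap in sorted(gap_grid):
        for ratio in sorted(ratio_grid):
            params = SegmentationParams(ratio, gap, sigma_bins, bin_s)
            segs = {c: segment_periods(compute_ratio(cv, params), params,
                                       span, c)
                    for c, cv in curves.items()}
            if align:
                segs = align_edges(segs)
            err = sum(segmentation_error(segs[c], truth[c]) for c in segs)
            rows.append((gap, ratio, err))
            if best is None or err < best[0]:
                best = (err, gap, ratio)
    surface = pd.DataFrame(rows, columns=["gap_s", "ratio", "error_s"])
    params = SegmentationParams(best[2], best[1], sigma_bins, bin_s)
    return params, surface


# ---------------------------------------------------------------------------
# event annotation

def _label_at(segments: Sequence[PeriodSegment], t: int) -> str:
    """Label of the segment containing t (half-open [start, end); the
    exact span end belongs to the last segment)."""
    last = segments[-1]
    if t == last.end:
        return last.label
    for seg in segments:
        if seg.start <= t < seg.end:
            return seg.label
    raise BoundaryError(f"time {t} outside the segmented span "
                        f"[{segments[0].start}, {last.end}]")


def annotate_events(events: Sequence[ContactEvent],
                    segments_by_class: Mapping[int, Sequence[PeriodSegment]],
                    class_map: Mapping[str, int],
                    method: str = "unrec"
                    ) -> tuple[list[TnetRecord], pd.DataFrame]:
    """Attach the SSSSX label to every event.

    The four state symbols are i's state at the start and end of the
    event, then j's (an end exactly on a segment boundary belongs to
    the later segment); X flags classmates.  Returns the tnet records
    and the per-label summary table.
    """
    records = []
    for ev in events:
        for d in (ev.i, ev.j):
            if d not in class_map:
                raise UnknownBadgeError(f"participant {d} missing from class map")
        c_i, c_j = class_map[ev.i], class_map[ev.j]
        labels = (_label_at(segments_by_class[c_i], ev.t)
                  + _label_at(segments_by_class[c_i], ev.t + ev.delta)
                  + _label_at(segments_by_class[c_j], ev.t)
                  + _label_at(segments_by_class[c_j], ev.t + ev.delta))
        records.append(TnetRecord(ev, labels, int(c_i == c_j), method))
    return records, annotation_summary(records)
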