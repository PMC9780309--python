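"""The four artifact corrections, applied in fixed order.

Issue 1 repairs silent badges (received but never heard by peers) and
deaf badges (heard by peers but own log empty) by mirroring the
surviving direction.  Issue 2 finds unworn badges parked near the
charging hub from the class RX's signal: 3-minute windows stepped by
1 minute whose mean RSSI is at least −62 dBm with standard deviation at
most 2.5.  Issue 3 finds piles of unworn badges far from the hub with
the stricter −55 dBm / 1.5 signature on each badge's own log.  Issue 4
trims bursts of unrealistically strong (> −45 dBm) signals at the edges
of each badge's data clip, produced while badges were gathered during
equipment or retrieval.

Flagged windows are unioned into intervals, bridged when closer than
2 minutes, padded with a 30-s safety margin, and removed
bidirectionally (the badge's own records and its appearances in every
peer's log).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import (HalfDaySequence, InactiveInterval, SLOT_S, SessionWindow)

logger = logging.getLogger(__name__)

#: Issue-2 thresholds (RX view of an unworn badge on the hub)
RX_MEAN_DBM, RX_STD = -62.0, 2.5
#: Issue-3 thresholds (badge-to-badge view of a pile, more restrictive
#: to protect genuine close face-to-face contacts)
PROX_MEAN_DBM, PROX_STD = -55.0, 1.5
#: Issue-4 strong-signal threshold
STRONG_DBM = -45
WINDOW_S, STEP_S = 180, 60
BRIDGE_S, MARGIN_S = 120, 30
EDGE_WINDOW_S, EDGE_OFFSET_S = 60, 20


def completeness_floor(window_s: int = WINDOW_S, period_s: int = SLOT_S) -> int:
    """Minimum signal count for a window to be trusted: 80% of the
    expected ``window_s / period_s`` beacons, rounded up (29 for a
    3-minute window at the 5-s period)."""
    return math.ceil(0.8 * window_s / period_s)


@dataclass
class WindowStat:
    """Summary of one observer's view of one source badge over a
    sliding window [t_start, t_end)."""

    source: str
    observer: str
    t_start: int
    t_end: int
    n_signals: int
    mean_rssi: float
    std_rssi: float
    complete: bool


def sliding_window_stats(observer_seq: HalfDaySequence, source_did: str,
                         window_s: int = WINDOW_S, step_s: int = STEP_S
                         ) -> list[WindowStat]:
    """Mean/STD of RSSI from ``source_did`` in each sliding window.

    Windows are anchored at the session start; STD is the population
    standard deviation.  Windows holding fewer than 80% of the expected
    signals are marked incomplete (excluded from flagging: the RX had
    lost contact with the badge, e.g. the child was out in the yard).
    """
    win = observer_seq.window
    df = observer_seq.data
    sel = df[df.did == source_did]
    t = sel.t.values
    r = sel.rssi.values.astype(float)
    floor = completeness_floor(window_s)
    out = []
    for start in range(win.start, win.end - window_s + 1, step_s):
        m = (t >= start) & (t < start + window_s)
        n = int(m.sum())
        if n:
            mean = float(r[m].mean())
            std = float(r[m].std())  # population (divide by n)
        else:
            mean, std = float("nan"), float("nan")
        out.append(WindowStat(source_did, observer_seq.owner, start,
                              start + window_s, n, mean, std,
                              complete=n >= floor))
    return out


def _flagged_windows_to_intervals(stats: Iterable[WindowStat], did: str,
                                  mean_thr: float, std_thr: float,
                                  cause: str) -> list[InactiveInterval]:
    """Union the spans of flagged complete windows into intervals."""
    spans = [(w.t_start, w.t_end) for w in stats
             if w.complete and w.mean_rssi >= mean_thr and w.std_rssi <= std_thr]
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [InactiveInterval(did, s, e, cause) for s, e in merged]


def detect_unworn_rx(rx_seq: HalfDaySequence, prox_did: str,
                     mean_thr: float = RX_MEAN_DBM, std_thr: float = RX_STD,
                     window_s: int = WINDOW_S, step_s: int = STEP_S
                     ) -> list[InactiveInterval]:
    """Issue 2: flag windows where the class RX hears ``prox_did``
    strongly (mean >= −62 dBm) and stably (STD <= 2.5)."""
    stats = sliding_window_stats(rx_seq, prox_did, window_s, step_s)
    return _flagged_windows_to_intervals(stats, prox_did, mean_thr, std_thr,
                                         "issue2")


def detect_unworn_prox(prox_seq: HalfDaySequence,
                       mean_thr: float = PROX_MEAN_DBM,
                       std_thr: float = PROX_STD,
                       window_s: int = WINDOW_S, step_s: int = STEP_S
                       ) -> list[InactiveInterval]:
    """Issue 3: flag windows where the badge's own log shows the
    pile signature (mean >= −55 dBm, STD <= 1.5) against any peer."""
    flagged: list[InactiveInterval] = []
    for peer in sorted(prox_seq.data.did.unique()):
        stats = sliding_window_stats(prox_seq, peer, window_s, step_s)
        flagged.extend(_flagged_windows_to_intervals(
            stats, prox_seq.owner, mean_thr, std_thr, "issue3"))
    # union across peers
    merged: list[list[int]] = []
    for iv in sorted(flagged, key=lambda x: (x.start, x.end)):
        if merged and iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [InactiveInterval(prox_seq.owner, s, e, "issue3") for s, e in merged]


def consolidate_intervals(intervals: Iterable[InactiveInterval],
                          window: SessionWindow,
                          bridge_s: int = BRIDGE_S,
                          margin_s: int = MARGIN_S) -> list[InactiveInterval]:
    """Bridge and pad flagged intervals (per badge).

    Intervals separated by less than ``bridge_s`` are concatenated
    (transitively), then each is extended by the ``margin_s`` safety
    margin on both ends and clipped to the session window.  The margin
    is applied once, as part of deletion; the output is non-overlapping.
    """
    by_badge: dict[tuple[str, str], list[InactiveInterval]] = {}
    for iv in intervals:
        by_badge.setdefault((iv.did, iv.cause), []).append(iv)
    out: list[InactiveInterval] = []
    for (did, cause), ivs in sorted(by_badge.items()):
        merged: list[list[int]] = []
        for iv in sorted(ivs, key=lambda x: (x.start, x.end)):
            if merged and iv.start - merged[-1][1] < bridge_s:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        padded = [[max(window.start, s - margin_s), min(window.end, e + margin_s)]
                  for s, e in merged]
        # margins may make neighbours touch; keep the output disjoint
        final: list[list[int]] = []
        for s, e in padded:
            if final and s <= final[-1][1]:
                final[-1][1] = max(final[-1][1], e)
            else:
                final.append([s, e])
        out.extend(InactiveInterval(did, s, e, cause) for s, e in final)
    return out


def trim_edge_bursts(prox_seq: HalfDaySequence,
                     strong_dbm: int = STRONG_DBM,
                     window_s: int = EDGE_WINDOW_S,
                     offset_s: int = EDGE_OFFSET_S
                     ) -> list[InactiveInterval]:
    """Issue 4: find gathered-badge bursts at the clip edges.

    Forward pass: within one minute of the first timestamp t0, every
    record above −45 dBm updates the strong-signal time t_s; past the
    window, t_s only advances when a new strong record arrives within
    20 s of the previous t_s.  The head burst is [t0, t_s] (kept empty
    when no strong record occurs inside the initial window — the badge
    was already in use).  The backward pass mirrors this from the last
    timestamp.
    """
    df = prox_seq.data
    if not len(df):
        return []
    t = df.t.values
    r = df.rssi.values
    out = []

    def _scan(times: np.ndarray, rssis: np.ndarray, forward: bool):
        t0 = times[0]
        t_s = None
        for ti, ri in zip(times, rssis):
            if ri <= strong_dbm:
                continue
            dist = (ti - t0) if forward else (t0 - ti)
            if dist < window_s:
                t_s = ti
            elif t_s is not None and abs(ti - t_s) <= offset_s:
                t_s = ti
            elif t_s is not None and abs(ti - t_s) > offset_s:
                # beyond the continuation step: burst already closed
                break
        return t_s

    order = np.argsort(t, kind="mergesort")
    head = _scan(t[order], r[order], forward=True)
    if head is not None:
        out.append(InactiveInterval(prox_seq.owner, int(t[order][0]),
                                    int(head) + 1, "issue4"))
    rev = order[::-1]
    tail = _scan(t[rev], r[rev], forward=False)
    if tail is not None:
        out.append(InactiveInterval(prox_seq.owner, int(tail),
                                    int(t[rev][0]) + 1, "issue4"))
    return out


def apply_removals(sequences: Mapping[str, HalfDaySequence],
                   intervals: Iterable[InactiveInterval]
                   ) -> dict[str, HalfDaySequence]:
    """Delete each badge's flagged intervals bidirectionally: its own
    received records inside the interval, and every appearance of the
    badge as observed DID in other sequences."""
    intervals = list(intervals)
    out = {}
    for owner, seq in sequences.items():
        df = seq.data
        drop = np.zeros(len(df), dtype=bool)
        for iv in intervals:
            inside = (df.t.values >= iv.start) & (df.t.values < iv.end)
            if owner == iv.did:
                drop |= inside
            drop |= inside & (df.did.values == iv.did)
        out[owner] = seq.with_data(df[~drop]) if drop.any() else seq.copy()
    return out


# ---------------------------------------------------------------------------
# Issue 1

def repair_silent_deaf(prox_seqs: Mapping[str, HalfDaySequence]
                       ) -> tuple[dict[str, HalfDaySequence], dict[str, str]]:
    """Repair silent and deaf badges by mirroring the intact direction.

    A silent badge receives but never appears in any peer's log: its
    received sequence is copied with sender/receiver reversed into the
    corresponding peers' files.  A deaf badge appears in peers' logs but
    recorded nothing: its log is rebuilt from every peer record of it,
    reversed.  A badge with neither emissions nor receptions is beyond
    repair and is flagged and left empty.

    Returns the repaired sequences and a {did: diagnosis} report.
    """
    appearances: dict[str, list[pd.DataFrame]] = {d: [] for d in prox_seqs}
    for owner, seq in prox_seqs.items():
        for did, sub in seq.data.groupby("did"):
            if did in appearances:
                appearances[did].append(
                    sub.assign(did=owner)[["did", "t", "rssi"]])
    diagnosis: dict[str, str] = {}
    out = {d: s.copy() for d, s in prox_seqs.items()}
    for did, seq in prox_seqs.items():
        heard = bool(appearances[did])
        receives = len(seq.data) > 0
        if receives and not heard:
            diagnosis[did] = "silent"
        elif heard and not receives:
            diagnosis[did] = "deaf"
        elif not heard and not receives:
            diagnosis[did] = "unrecoverable"
            logger.warning("badge %s neither emitted nor received; left empty",
                           did)
    for did, diag in diagnosis.items():
        if diag == "silent":
            # mirror the silent badge's receptions into the senders' logs
            for sender, sub in prox_seqs[did].data.groupby("did"):
                if sender in out:
                    tgt = out[sender]
                    add = sub.assign(did=did)[["did", "t", "rssi"]]
                    out[sender] = tgt.with_data(
                        pd.concat([tgt.data, add], ignore_index=True))
        elif diag == "deaf":
            mirrored = pd.concat(appearances[did], ignore_index=True)
            out[did] = out[did].with_data(mirrored)
    return out, diagnosis


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PreprocessReport:
    """Fig-2-style decomposition of what each stage removed."""

    repaired: dict[str, str] = field(default_factory=dict)
    intervals: list[InactiveInterval] = field(default_factory=list)
    records_before: int = 0
    records_after: int = 0
    #: RX sequences after the same bidirectional removals
    rx_sequences: dict[int, HalfDaySequence] = field(default_factory=dict)

    def by_cause(self, cause: str) -> list[InactiveInterval]:
        return [iv for iv in self.intervals if iv.cause == cause]

    def removed_seconds(self, cause: str | None = None) -> int:
        return sum(iv.end - iv.start for iv in self.intervals
                   if cause is None or iv.cause == cause)


def preprocess_half_day(prox_seqs: Mapping[str, HalfDaySequence],
                        rx_seqs: Mapping[int, HalfDaySequence],
                        rx_mean=RX_MEAN_DBM, rx_std=RX_STD,
                        prox_mean=PROX_MEAN_DBM, prox_std=PROX_STD,
                        strong_dbm: int = STRONG_DBM
                        ) -> tuple[dict[str, HalfDaySequence], PreprocessReport]:
    """Run Issues 1 → 2 → 3 → 4 in order, each on the previous output.

    ``rx_seqs`` maps class id → that class's RX sequence; a class with
    no RX skips Issue 2 with a logged warning (Issue 3 still covers
    badges the RX cannot see).
    """
    report = PreprocessReport(
        records_before=sum(len(s) for s in prox_seqs.values()))
    window = next(iter(prox_seqs.values())).window if prox_seqs else None

    # Issue 1
    seqs, report.repaired = repair_silent_deaf(prox_seqs)

    # Issue 2 (needs the class RX)
    flagged: list[InactiveInterval] = []
    for did, seq in sorted(seqs.items()):
        rx = rx_seqs.get(seq.class_id)
        if rx is None:
            logger.warning("class %s has no RX; skipping Issue 2 for %s",
                           seq.class_id, did)
            continue
        flagged.extend(detect_unworn_rx(rx, did, rx_mean, rx_std))
    issue2 = consolidate_intervals(flagged, window) if window else []
    seqs = apply_removals(seqs, issue2)
    rx_out = apply_removals({r.owner: r for r in rx_seqs.values()}, issue2)
    report.intervals.extend(issue2)

    # Issue 3
    flagged = []
    for did, seq in sorted(seqs.items()):
        flagged.extend(detect_unworn_prox(seq, prox_mean, prox_std))
    issue3 = consolidate_intervals(flagged, window) if window else []
    seqs = apply_removals(seqs, issue3)
    rx_out = apply_removals(rx_out, issue3)
    report.intervals.extend(issue3)

    # Issue 4
    trims: list[InactiveInterval] = []
    for did, seq in sorted(seqs.items()):
        trims.extend(trim_edge_bursts(seq, strong_dbm))
    seqs = apply_removals(seqs, trims)
    rx_out = apply_removals(rx_out, trims)
    report.intervals.extend(trims)

    report.records_after = sum(len(s) for s in seqs.values())
    report.rx_sequences = {rx_seqs[c].class_id: rx_out[rx_seqs[c].owner]
                           for c in rx_seqs}
    return seqs, report
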