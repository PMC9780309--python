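"""Deployment simulator: roster, schedules, latent contact events,
beacon emission with state-dependent RSSI, packet loss, and the four
artifact classes, exporting signal files together with a ground-truth
bundle.

The generator emulates what the badges measure, not why: a latent
on/off contact process per eligible dyad (heavy-tailed durations and
inter-event gaps), room co-location driven by the class schedule, and
per-slot directed packet exchange whose RSSI regime depends on the
dyad's state.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RssiRegime, SimulationConfig
from .errors import IdSpaceError, ScheduleError
from .types import (BinaryStateSequence, ContactEvent, HalfDaySequence,
                    InactiveInterval, PeriodSegment, SLOT_S, SESSION_CLOCK,
                    SessionWindow, badge_kind, canonical_dyad, session_window)

__all__ = [
    "Roster", "TruthBundle", "simulate_population", "simulate_schedule",
    "simulate_events", "emit_signals", "inject_artifacts",
    "simulate_deployment", "truth_state_sequences", "gt1_table",
]


@dataclass
class Roster:
    """Badge assignment: children 0xxx, adults 1xxx, RX badges 200c
    (one per class) plus optional gym RXs 2010/2011."""

    children: dict[str, int]
    adults: dict[str, int]
    rx: dict[int, str]
    gym_rx: tuple[str, ...] = ()

    @property
    def class_map(self) -> dict[str, int]:
        return {**self.children, **self.adults}

    def members(self, class_id: int) -> list[str]:
        return sorted(d for d, c in self.class_map.items() if c == class_id)

    def prox_badges(self) -> list[str]:
        return sorted(self.class_map)

    def all_badges(self) -> list[str]:
        return self.prox_badges() + sorted(self.rx.values()) + list(self.gym_rx)


@dataclass
class TruthBundle:
    """Simulator ground truth: true events, per-slot dyad states, true
    schedules and injected artifact intervals, mutually consistent
    (events are exactly the maximal runs of active slots)."""

    roster: Roster
    schedule: dict[tuple[int, str], dict[int, list[PeriodSegment]]]
    events: dict[tuple[int, str], list[ContactEvent]] = field(default_factory=dict)
    states: dict[tuple[int, str], dict[tuple[str, str], np.ndarray]] = field(default_factory=dict)
    artifacts: dict[tuple[int, str], list[InactiveInterval]] = field(default_factory=dict)
    #: mixing lulls: classes regroup apart in the yard (still free time,
    #: but no cross-class co-location); (classes, start, end) per half-day
    lulls: dict[tuple[int, str], list[tuple[frozenset, int, int]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# population

def simulate_population(config: SimulationConfig,
                        seed: int | None = None) -> Roster:
    """Draw a roster under the DID coding scheme (seeded, reproducible)."""
    if config.n_classes > 7:
        raise IdSpaceError("the 200x RX scheme supports at most 7 classes")
    n_children = sum(config.class_sizes)
    if n_children > 999 or config.n_adults > 999:
        raise IdSpaceError("4-digit DID space exhausted")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    child_codes = rng.choice(np.arange(1, 1000), size=n_children, replace=False)
    adult_codes = rng.choice(np.arange(1, 1000), size=config.n_adults, replace=False)
    children, k = {}, 0
    for cls, size in enumerate(config.class_sizes, start=1):
        for _ in range(size):
            children[f"0{child_codes[k]:03d}"] = cls
            k += 1
    adults = {f"1{adult_codes[k]:03d}": (k % config.n_classes) + 1
              for k in range(config.n_adults)}
    rx = {c: f"200{c}" for c in range(1, config.n_classes + 1)}
    gym = ("2010", "2011") if config.gym_rx else ()
    return Roster(children, adults, rx, gym)


# ---------------------------------------------------------------------------
# schedule

@dataclass
class _Block:
    """A yard session realised on one half-day: per-class jittered
    bounds plus the optional absolute lull window."""

    classes: tuple[int, ...]
    bounds: dict[int, tuple[int, int]]
    lull: tuple[int, int] | None
    mixing: float = 1.0


def _snap(x: float, grid: int = SLOT_S) -> int:
    return int(round(x / grid)) * grid


def _realise_blocks(config: SimulationConfig, win: SessionWindow,
                    rng: np.random.Generator) -> list[_Block]:
    morning_len = SESSION_CLOCK["M"][1] - SESSION_CLOCK["M"][0]
    scale = (win.end - win.start) / morning_len
    blocks = []
    for blk in config.free_blocks:
        b0 = win.start + _snap(blk.start_s * scale, 60)
        b1 = win.start + _snap(blk.end_s * scale, 60)
        bounds = {}
        for c in blk.classes:
            j0 = _snap(rng.uniform(0, config.schedule_jitter_s))
            j1 = _snap(rng.uniform(0, config.schedule_jitter_s))
            bounds[c] = (b0 + j0, b1 - j1)
        lull = None
        if blk.lull is not None:
            lull = (win.start + _snap(blk.lull[0] * scale, 30),
                    win.start + _snap(blk.lull[1] * scale, 30))
        blocks.append(_Block(blk.classes, bounds, lull, blk.mixing))
    return blocks


def _segments_from_blocks(blocks: list[_Block], win: SessionWindow,
                          n_classes: int) -> dict[int, list[PeriodSegment]]:
    out = {}
    for c in range(1, n_classes + 1):
        free = sorted(b.bounds[c] for b in blocks if c in b.classes)
        for (s0, e0), (s1, e1) in zip(free, free[1:]):
            if s1 < e0:
                raise ScheduleError(f"class {c} has overlapping free blocks")
        segs, cur = [], win.start
        for s, e in free:
            if s > cur:
                segs.append(PeriodSegment(c, cur, s, "C"))
            segs.append(PeriodSegment(c, s, e, "F"))
            cur = e
        if cur < win.end:
            segs.append(PeriodSegment(c, cur, win.end, "C"))
        out[c] = segs
    return out


@dataclass
class ScheduleTruth:
    """Realised schedule: per-half-day, per-class period segments plus
    the internal block structure the event process needs."""

    segments: dict[tuple[int, str], dict[int, list[PeriodSegment]]]
    blocks: dict[tuple[int, str], list[_Block]]


def simulate_schedule(config: SimulationConfig,
                      seed: int | None = None) -> ScheduleTruth:
    """Realise the free-block template on every half-day.

    Each class's yard entry/exit is jittered by up to
    ``schedule_jitter_s``; by construction every free segment overlaps a
    free segment of at least one other class in its block.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    segments, blocks = {}, {}
    for day, sess in config.half_days:
        win = session_window(day, sess)
        blks = _realise_blocks(config, win, rng)
        segments[(day, sess)] = _segments_from_blocks(blks, win, config.n_classes)
        blocks[(day, sess)] = blks
    return ScheduleTruth(segments, blocks)


# ---------------------------------------------------------------------------
# latent contact events

def _powerlaw_pmf(alpha: float, cutoff: int, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1, dtype=float)
    w = k ** (-alpha) * np.exp(-k / cutoff)
    return w / w.sum()


class _HeavyTail:
    """Discrete power law with exponential cutoff, P(k) ~ k^-a e^-k/κ."""

    def __init__(self, alpha: float, cutoff: int):
        self.pmf = _powerlaw_pmf(alpha, cutoff, kmax=5 * cutoff)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(len(self.pmf), size=size, p=self.pmf) + 1

    def mean(self) -> float:
        return float(np.sum((np.arange(len(self.pmf)) + 1) * self.pmf))


def _interval_intersection(a: list[tuple[int, int]], b: list[tuple[int, int]]
                           ) -> list[tuple[int, int]]:
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _interval_subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]
                       ) -> list[tuple[int, int]]:
    out = []
    for lo, hi in a:
        cur = lo
        for s, e in b:
            if e <= cur or s >= hi:
                continue
            if s > cur:
                out.append((cur, min(s, hi)))
            cur = max(cur, e)
        if cur < hi:
            out.append((cur, hi))
    return out


def _dyad_windows(c_i: int, c_j: int, segments: dict[int, list[PeriodSegment]],
                  blocks: list[_Block], win: SessionWindow,
                  margin: int) -> list[tuple[int, int, float]]:
    """Eligibility windows (lo, hi, mixing) for a dyad on one half-day.

    Same-class dyads may interact any time (classroom or shared yard);
    cross-class dyads only while both classes are simultaneously out,
    excluding mixing lulls; each window carries its block's mixing
    intensity.
    """
    core = [(win.start + margin, win.end - margin)]
    if c_i == c_j:
        return [(lo, hi, 1.0) for lo, hi in core]
    f_i = [(s.start, s.end) for s in segments[c_i] if s.label == "F"]
    f_j = [(s.start, s.end) for s in segments[c_j] if s.label == "F"]
    shared = _interval_intersection(f_i, f_j)
    lulls = [b.lull for b in blocks if b.lull is not None
             and c_i in b.classes and c_j in b.classes]
    shared = _interval_subtract(shared, sorted(lulls))
    out = []
    for lo, hi in _interval_intersection(shared, core):
        mixing = 1.0
        for b in blocks:
            if (c_i in b.classes and c_j in b.classes
                    and any(lo < e and s < hi
                            for s, e in [b.bounds[c_i], b.bounds[c_j]])):
                mixing = b.mixing
                break
        out.append((lo, hi, mixing))
    return out


def simulate_events(config: SimulationConfig, schedule: ScheduleTruth,
                    roster: Roster, seed: int | None = None) -> TruthBundle:
    """Draw the latent contact process for every eligible dyad.

    Per eligibility window a dyad participates with a thinning
    probability, then alternates heavy-tailed inter-event gaps and
    durations (all boundaries on the 5-s grid).  Cross-class dyads can
    only be active while both classes share the yard.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ev = config.events
    dur_dist = _HeavyTail(ev.duration_alpha, ev.duration_cutoff_slots)
    iet_dist = _HeavyTail(ev.iet_alpha, ev.iet_cutoff_slots)
    truth = TruthBundle(roster, schedule.segments)
    class_map = roster.class_map
    badges = roster.prox_badges()

    for key in config.half_days:
        day, sess = key
        win = session_window(day, sess)
        segs = schedule.segments[key]
        blks = schedule.blocks[key]
        events: list[ContactEvent] = []
        states: dict[tuple[str, str], np.ndarray] = {}
        for a, b in itertools.combinations(badges, 2):
            i, j = canonical_dyad(a, b)
            c_i, c_j = class_map[i], class_map[j]
            p = ev.dyad_participation
            if c_i != c_j:
                p *= ev.cross_class_factor
            n_adults = (badge_kind(i) == "adult") + (badge_kind(j) == "adult")
            if n_adults:
                p *= ev.adult_factor ** n_adults
            windows = _dyad_windows(c_i, c_j, segs, blks, win, ev.edge_margin_s)
            slots_acc = []
            for lo, hi, mixing in windows:
                if rng.random() >= p * mixing:
                    continue
                n_slots = (hi - lo) // SLOT_S
                t_slot = int(iet_dist.draw(rng, 1)[0])
                while t_slot < n_slots:
                    d = int(dur_dist.draw(rng, 1)[0])
                    d = min(d, n_slots - t_slot)
                    t0 = lo + t_slot * SLOT_S
                    events.append(ContactEvent(t0, i, j, d * SLOT_S))
                    slots_acc.append(np.arange(t0, t0 + d * SLOT_S, SLOT_S))
                    t_slot += d + int(iet_dist.draw(rng, 1)[0])
            if slots_acc:
                states[(i, j)] = np.concatenate(slots_acc)
        events.sort()
        truth.events[key] = events
        truth.states[key] = states
        truth.artifacts[key] = []
        truth.lulls[key] = [(frozenset(b.classes), b.lull[0], b.lull[1])
                            for b in blks if b.lull is not None]
    return truth


# ---------------------------------------------------------------------------
# beacon emission

def _draw_rssi(regime: RssiRegime, size: int,
               rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal draws rounded onto the integer dBm grid."""
    a = (regime.lo - regime.mean) / regime.sd
    b = (regime.hi - regime.mean) / regime.sd
    x = stats.truncnorm.rvs(a, b, loc=regime.mean, scale=regime.sd,
                            size=size, random_state=rng)
    return np.clip(np.round(x), regime.lo, regime.hi).astype(np.int64)


def _room_pieces(segments: dict[int, list[PeriodSegment]],
                 win: SessionWindow,
                 lulls: list[tuple[frozenset, int, int]] | None = None
                 ) -> list[tuple[int, int, dict[int, str]]]:
    """Cut the session into pieces of constant room assignment.

    Returns (start, end, {class: 'room'}) with room 'C' (own
    classroom), 'F' (shared yard), or 'L' (out, but regrouped apart
    from the other classes during a mixing lull).
    """
    lulls = lulls or []
    bounds = {win.start, win.end}
    for segs in segments.values():
        for s in segs:
            bounds.update((s.start, s.end))
    for _, lo, hi in lulls:
        bounds.update((lo, hi))
    cuts = sorted(bounds)
    pieces = []
    for lo, hi in zip(cuts, cuts[1:]):
        rooms = {}
        for c, segs in segments.items():
            lab = next(s.label for s in segs if s.start <= lo < s.end)
            if lab == "F" and any(c in cls and l0 <= lo and hi <= l1
                                  for cls, l0, l1 in lulls):
                lab = "L"
            rooms[c] = lab
        pieces.append((lo, hi, rooms))
    return pieces


def emit_signals(truth: TruthBundle, config: SimulationConfig,
                 seed: int | None = None
                 ) -> dict[tuple[int, str], dict[str, HalfDaySequence]]:
    """Turn the latent truth into raw per-badge signal logs.

    Every 5-s slot, each co-located (same-room) dyad exchanges two
    directed records: interaction-regime RSSI when the dyad is active,
    background regime otherwise.  Each direction is independently lost
    with ``packet_loss_prob``; draws never fall below the −94 dBm
    sensitivity floor (regime truncation).  The class RX logs every
    badge present in its classroom each slot.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    roster = truth.roster
    class_map = roster.class_map
    loss = config.packet_loss_prob
    out: dict[tuple[int, str], dict[str, HalfDaySequence]] = {}

    for key, segments in truth.schedule.items():
        day, sess = key
        win = session_window(day, sess)
        states = truth.states.get(key, {})
        recv, send, times, rssis = [], [], [], []

        def _emit_pairs(pairs: list[tuple[str, str]], slot_arr: np.ndarray,
                        proximity: float = 1.0):
            """Directed background/interaction exchange for co-located
            dyads; ``proximity`` thins the slots a non-interacting pair
            is within radio range (yard sparsity)."""
            for i, j in pairs:
                active = states.get((i, j))
                s = slot_arr
                if active is not None and len(active):
                    mask = np.isin(s, active, assume_unique=True)
                else:
                    mask = np.zeros(len(s), dtype=bool)
                if proximity < 1.0:
                    present = mask | (rng.random(len(s)) < proximity)
                    s = s[present]
                    mask = mask[present]
                for src, dst in ((i, j), (j, i)):
                    r = _draw_rssi(config.rssi_background, len(s), rng)
                    if mask.any():
                        r[mask] = _draw_rssi(config.rssi_interaction,
                                             int(mask.sum()), rng)
                    keep = rng.random(len(s)) >= loss
                    recv.append(np.repeat(dst, keep.sum()))
                    send.append(np.repeat(src, keep.sum()))
                    times.append(s[keep])
                    rssis.append(r[keep])

        for lo, hi, rooms in _room_pieces(segments, win,
                                          truth.lulls.get(key)):
            slot_arr = np.arange(lo, hi, SLOT_S)
            yard_members: list[str] = []
            for c in sorted(rooms):
                members = roster.members(c)
                if rooms[c] == "C":
                    pairs = [canonical_dyad(x, y)
                             for x, y in itertools.combinations(members, 2)]
                    _emit_pairs(pairs, slot_arr)
                    # the class RX hears everyone in the room
                    rx = roster.rx[c]
                    for m in members:
                        r = _draw_rssi(config.rssi_background, len(slot_arr), rng)
                        keep = rng.random(len(slot_arr)) >= loss
                        recv.append(np.repeat(rx, keep.sum()))
                        send.append(np.repeat(m, keep.sum()))
                        times.append(slot_arr[keep])
                        rssis.append(r[keep])
                elif rooms[c] == "L":
                    # out, but regrouped by class: within-class exchange only
                    pairs = [canonical_dyad(x, y)
                             for x, y in itertools.combinations(members, 2)]
                    _emit_pairs(pairs, slot_arr)
                else:
                    yard_members.extend(members)
            if len(yard_members) >= 2:
                pairs = [canonical_dyad(x, y)
                         for x, y in itertools.combinations(sorted(yard_members), 2)]
                _emit_pairs(pairs, slot_arr, config.yard_proximity)

        # fake strong cross-class exchanges while not co-located
        # (interference / corridor passings); no true interaction behind
        rate = config.events.interference_rate_ph
        if rate > 0:
            slots_all = win.slots()
            f_stat = {}
            for c, segs in segments.items():
                mask = np.zeros(len(slots_all), dtype=bool)
                for s in segs:
                    if s.label == "F":
                        mask |= (slots_all >= s.start) & (slots_all < s.end)
                f_stat[c] = mask
            shared_lull = {}
            for cls_set, l0, l1 in truth.lulls.get(key, []):
                m = (slots_all >= l0) & (slots_all < l1)
                for x, y in itertools.combinations(sorted(cls_set), 2):
                    prev = shared_lull.get((x, y))
                    shared_lull[(x, y)] = m if prev is None else (prev | m)
            lam = rate * (win.end - win.start) / 3600.0
            badges = roster.prox_badges()
            for i, j in itertools.combinations(badges, 2):
                c_i, c_j = class_map[i], class_map[j]
                if c_i == c_j:
                    continue
                k = rng.poisson(lam)
                if not k:
                    continue
                idx = rng.integers(0, len(slots_all), size=k)
                coloc = f_stat[c_i] & f_stat[c_j]
                pair_lull = shared_lull.get(tuple(sorted((c_i, c_j))))
                if pair_lull is not None:
                    coloc = coloc & ~pair_lull
                idx = np.unique(idx[~coloc[idx]])
                if not len(idx):
                    continue
                fake_t = slots_all[idx]
                for src, dst in ((i, j), (j, i)):
                    keep = rng.random(len(fake_t)) >= loss
                    recv.append(np.repeat(dst, keep.sum()))
                    send.append(np.repeat(src, keep.sum()))
                    times.append(fake_t[keep])
                    rssis.append(_draw_rssi(config.rssi_interaction,
                                            int(keep.sum()), rng))

        df = pd.DataFrame({
            "receiver": np.concatenate(recv) if recv else np.array([], dtype=str),
            "did": np.concatenate(send) if send else np.array([], dtype=str),
            "t": np.concatenate(times) if times else np.array([], dtype=np.int64),
            "rssi": np.concatenate(rssis) if rssis else np.array([], dtype=np.int64),
        })
        half_day: dict[str, HalfDaySequence] = {}
        grouped = dict(tuple(df.groupby("receiver"))) if len(df) else {}
        for did in roster.prox_badges() + sorted(roster.rx.values()):
            cls = class_map.get(did, int(did[3]) if badge_kind(did) == "rx" else 0)
            sub = grouped.get(did)
            data = (sub[["did", "t", "rssi"]] if sub is not None
                    else pd.DataFrame(columns=["did", "t", "rssi"]))
            half_day[did] = HalfDaySequence(did, cls, day, sess, data)
        out[key] = half_day
    return out


# ---------------------------------------------------------------------------
# artifact injection

def _aligned_start(lo: int, hi: int, length: int,
                   rng: np.random.Generator, align: int = 60) -> int | None:
    """A random ``align``-aligned start of an interval of ``length``
    seconds inside [lo, hi); None when it does not fit."""
    lo_a = -(-lo // align) * align
    hi_a = hi - length
    if hi_a < lo_a:
        return None
    return int(rng.choice(np.arange(lo_a, hi_a + 1, align)))


def _rebuild_dyad_events(states: np.ndarray, i: str, j: str
                         ) -> list[ContactEvent]:
    """Maximal runs of active slots -> events (keeps truth consistent)."""
    if not len(states):
        return []
    breaks = np.flatnonzero(np.diff(states) != SLOT_S)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(states) - 1]))
    return [ContactEvent(int(states[s]), i, j,
                         int(states[e] - states[s]) + SLOT_S)
            for s, e in zip(starts, ends)]


def _neutralize_badge(seqs: dict[str, HalfDaySequence], truth: TruthBundle,
                      key: tuple[int, str], did: str, lo: int, hi: int,
                      config: SimulationConfig,
                      rng: np.random.Generator) -> None:
    """Erase a badge's true contacts inside [lo, hi).

    An unworn badge cannot interact: its active slots in the interval
    are removed from the truth (events rebuilt as the remaining maximal
    runs) and the corresponding interaction-regime records between the
    two badges are replaced by background draws.
    """
    states = truth.states.get(key, {})
    affected = [dyad for dyad in states if did in dyad]
    for dyad in affected:
        active = states[dyad]
        inside = active[(active >= lo) & (active < hi)]
        if not len(inside):
            continue
        remaining = active[(active < lo) | (active >= hi)]
        i, j = dyad
        for dst, src in ((i, j), (j, i)):
            seq = seqs[dst]
            df = seq.data
            hit = (df.did.values == src) & np.isin(df.t.values, inside)
            if hit.any():
                new = df.copy()
                new.loc[hit, "rssi"] = _draw_rssi(config.rssi_background,
                                                  int(hit.sum()), rng)
                seqs[dst] = seq.with_data(new)
        truth.events[key] = [e for e in truth.events[key]
                             if (e.i, e.j) != dyad]
        if len(remaining):
            states[dyad] = remaining
            truth.events[key].extend(_rebuild_dyad_events(remaining, i, j))
        else:
            del states[dyad]
    truth.events[key].sort()


def _class_time_intervals(segments: list[PeriodSegment]) -> list[tuple[int, int]]:
    return [(s.start, s.end) for s in segments if s.label == "C"]


def inject_artifacts(signals: dict[tuple[int, str], dict[str, HalfDaySequence]],
                     truth: TruthBundle, config: SimulationConfig,
                     seed: int | None = None
                     ) -> tuple[dict, TruthBundle]:
    """Inject the four artifact classes into emitted signals (in place on
    a copy), recording every injected interval in the truth bundle.

    * unworn-near-hub: the class RX hears the badge strongly and stably
      (mean >= −62 dBm, SD <= 2.5) for the interval;
    * badge piles: two badges exchange very strong, very stable signals
      far from the hub (the more restrictive −55/1.5 signature);
    * edge bursts: gathered badges exchange unstable signals including
      values above −45 dBm at session start and end;
    * silent badges: own emissions vanish from every peer log;
    * deaf badges: own reception log vanishes.

    Artifact intervals are placed where the badge has no true contact
    (an unworn badge cannot interact), keeping truth consistent.
    """
    art = config.artifacts
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    out: dict[tuple[int, str], dict[str, HalfDaySequence]] = {}

    for key, half_day in signals.items():
        day, sess = key
        win = session_window(day, sess)
        seqs = {d: s.copy() for d, s in half_day.items()}
        marks: list[InactiveInterval] = list(truth.artifacts.get(key, []))
        prox = truth.roster.prox_badges()

        # exclusive role assignment per badge
        roles: dict[str, str] = {}
        for did in prox:
            u = rng.random()
            if u < art.unworn_prob:
                roles[did] = "unworn"
            elif u < art.unworn_prob + art.pile_prob:
                roles[did] = "pile"
            elif u < art.unworn_prob + art.pile_prob + art.silent_prob:
                roles[did] = "silent"
            elif u < (art.unworn_prob + art.pile_prob + art.silent_prob
                      + art.deaf_prob):
                roles[did] = "deaf"

        def _replace_directed(dst: str, src: str, lo: int, hi: int,
                              regime: RssiRegime):
            """Replace dst's records of src in [lo, hi) with fresh
            full-rate draws from ``regime`` (packet loss applied)."""
            seq = seqs[dst]
            df = seq.data
            keep = ~((df.did.values == src) & (df.t.values >= lo)
                     & (df.t.values < hi))
            slots = np.arange(lo, hi, SLOT_S)
            kept = rng.random(len(slots)) >= config.packet_loss_prob
            add = pd.DataFrame({"did": src, "t": slots[kept],
                                "rssi": _draw_rssi(regime, int(kept.sum()), rng)})
            seqs[dst] = seq.with_data(pd.concat([df[keep], add],
                                                ignore_index=True))

        # Issue 2: unworn near hub
        for did in [d for d, r in roles.items() if r == "unworn"]:
            cls = truth.roster.class_map[did]
            spans = [s for s in _class_time_intervals(truth.schedule[key][cls])
                     if s[1] - s[0] >= art.unworn_duration_s]
            if not spans:
                continue
            lo, hi = spans[int(rng.integers(len(spans)))]
            start = _aligned_start(lo, hi, art.unworn_duration_s, rng)
            if start is None:
                continue
            end = start + art.unworn_duration_s
            _neutralize_badge(seqs, truth, key, did, start, end, config, rng)
            _replace_directed(truth.roster.rx[cls], did, start, end,
                              config.rssi_unworn_hub)
            marks.append(InactiveInterval(did, start, end, "issue2"))

        # Issue 3: piles of badges away from the hub
        pile_badges = [d for d, r in roles.items() if r == "pile"]
        by_class: dict[int, list[str]] = {}
        for d in pile_badges:
            by_class.setdefault(truth.roster.class_map[d], []).append(d)
        for cls, group in sorted(by_class.items()):
            for p1, p2 in zip(group[::2], group[1::2]):
                spans = [s for s in
                         _class_time_intervals(truth.schedule[key][cls])
                         if s[1] - s[0] >= art.pile_duration_s]
                if not spans:
                    continue
                lo, hi = spans[int(rng.integers(len(spans)))]
                start = _aligned_start(lo, hi, art.pile_duration_s, rng)
                if start is None:
                    continue
                end = start + art.pile_duration_s
                for p in (p1, p2):
                    _neutralize_badge(seqs, truth, key, p, start, end,
                                      config, rng)
                _replace_directed(p1, p2, start, end, config.rssi_pile)
                _replace_directed(p2, p1, start, end, config.rssi_pile)
                marks.append(InactiveInterval(p1, start, end, "issue3"))
                marks.append(InactiveInterval(p2, start, end, "issue3"))

        # Issue 4: edge bursts among gathered badges
        burst = art.edge_burst_duration_s
        for cls in sorted(truth.roster.rx):
            members = [m for m in truth.roster.members(cls)
                       if rng.random() < art.edge_burst_prob]
            if len(members) < 2:
                continue
            for lo, hi in ((win.start, win.start + burst),
                           (win.end - burst, win.end)):
                for x, y in itertools.combinations(members, 2):
                    _replace_directed(x, y, lo, hi, config.rssi_burst)
                    _replace_directed(y, x, lo, hi, config.rssi_burst)
                for m in members:
                    marks.append(InactiveInterval(m, lo, hi, "issue4"))

        # Issue 1: silent and deaf badges
        for did in [d for d, r in roles.items() if r == "silent"]:
            for other, seq in seqs.items():
                if other != did:
                    seqs[other] = seq.with_data(seq.data[seq.data.did != did])
            marks.append(InactiveInterval(did, win.start, win.end, "silent"))
        for did in [d for d, r in roles.items() if r == "deaf"]:
            seqs[did] = seqs[did].with_data(seqs[did].data.iloc[0:0])
            marks.append(InactiveInterval(did, win.start, win.end, "deaf"))

        truth.artifacts[key] = marks
        out[key] = seqs
    return out, truth


# ---------------------------------------------------------------------------
# top level and truth utilities

def simulate_deployment(config: SimulationConfig, seed: int | None = None
                        ) -> tuple[dict, TruthBundle]:
    """Roster → schedule → events → signals → artifacts, one call."""
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base).generate_state(4) % (2 ** 31)
    roster = simulate_population(config, int(ss[0]))
    schedule = simulate_schedule(config, int(ss[1]))
    truth = simulate_events(config, schedule, roster, int(ss[2]))
    signals = emit_signals(truth, config, int(ss[3]))
    signals, truth = inject_artifacts(signals, truth, config, int(ss[3]) + 1)
    return signals, truth


def colocation_slots(truth: TruthBundle, key: tuple[int, str],
                     i: str, j: str) -> np.ndarray:
    """Slots during which dyad (i, j) shares a room (classroom or yard)."""
    win = session_window(*key)
    c_i = truth.roster.class_map[i]
    c_j = truth.roster.class_map[j]
    if c_i == c_j:
        return win.slots()
    f_i = [(s.start, s.end) for s in truth.schedule[key][c_i] if s.label == "F"]
    f_j = [(s.start, s.end) for s in truth.schedule[key][c_j] if s.label == "F"]
    shared = _interval_intersection(f_i, f_j)
    lulls = sorted((l0, l1) for cls, l0, l1 in truth.lulls.get(key, [])
                   if c_i in cls and c_j in cls)
    shared = _interval_subtract(shared, lulls)
    if not shared:
        return np.array([], dtype=np.int64)
    return np.concatenate([np.arange(lo, hi, SLOT_S) for lo, hi in shared])


def truth_state_sequences(truth: TruthBundle, key: tuple[int, str],
                          dyads=None) -> dict[tuple[str, str], BinaryStateSequence]:
    """Ground-truth binary sequences over each dyad's co-location grid."""
    if dyads is None:
        dyads = sorted(truth.states.get(key, {}))
    out = {}
    for i, j in dyads:
        grid = colocation_slots(truth, key, i, j)
        active = truth.states.get(key, {}).get((i, j), np.array([], dtype=np.int64))
        states = np.isin(grid, active).astype(np.int8)
        out[(i, j)] = BinaryStateSequence(i, j, grid, states)
    return out


def gt1_table(truth: TruthBundle, key: tuple[int, str],
              n_pairs: int = 7, seed: int = 0) -> pd.DataFrame:
    """A GT1-style observation table: per-dyad interaction scans on a
    10-s grid for a sample of same-class dyads (synthetic stand-in for
    the in-situ dyadic scan protocol)."""
    rng = np.random.default_rng(seed)
    dyads = sorted(truth.states.get(key, {}))
    same = [(i, j) for i, j in dyads
            if truth.roster.class_map[i] == truth.roster.class_map[j]]
    pick = [same[k] for k in rng.choice(len(same), size=min(n_pairs, len(same)),
                                        replace=False)]
    rows = []
    for i, j in pick:
        grid = colocation_slots(truth, key, i, j)[::2]  # 10-s scans
        active = truth.states[key][(i, j)]
        for t, on in zip(grid, np.isin(grid, active)):
            rows.append((f"{i}-{j}", int(t), int(on), "FF"))
    return pd.DataFrame(rows, columns=["pair", "t", "interaction", "orientation"])
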