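"""Validation statistics of the inferred temporal networks.

Event-duration, inter-event-time and degree distributions (raw and
log-binned), weighted aggregated networks per context (free/class/all),
and the per-label annotation summary with its percentage and hour
arithmetic (percentages half-up to 2 decimals, hours to the nearest
integer).
"""

from __future__ import annotations

import importlib.resources
import math
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .types import ContactEvent, TnetRecord, canonical_dyad


def _pct(x: float) -> float:
    """Percentage rounded half-up to 2 decimals."""
    return float(Decimal(str(x)).quantize(Decimal("0.01"),
                                          rounding=ROUND_HALF_UP))


def _hours(seconds: float) -> int:
    """Seconds to the nearest whole hour (half-up)."""
    return int(math.floor(seconds / 3600 + 0.5))


# ---------------------------------------------------------------------------
# distributions

def _empirical(values: np.ndarray, log_base: float | None = 10 ** 0.25
               ) -> pd.DataFrame:
    """Empirical PDF: raw probability mass per value, plus a
    logarithmically binned density when ``log_base`` is given."""
    values = np.asarray(values, dtype=float)
    uniq, counts = np.unique(values, return_counts=True)
    raw = pd.DataFrame({"value": uniq, "pdf": counts / counts.sum(),
                        "binned": False})
    if log_base is None or not len(values) or values.min() <= 0:
        return raw
    lo = math.floor(math.log(values.min(), log_base))
    hi = math.ceil(math.log(values.max(), log_base)) + 1
    edges = np.unique(log_base ** np.arange(lo, hi + 1))
    hist, edges = np.histogram(values, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = hist > 0
    binned = pd.DataFrame({"value": centers[keep],
                           "pdf": hist[keep] / (widths[keep] * len(values)),
                           "binned": True})
    return pd.concat([raw, binned], ignore_index=True)


def duration_distribution(events: Sequence[ContactEvent],
                          log_base: float | None = 10 ** 0.25) -> pd.DataFrame:
    """Distribution of event durations (seconds)."""
    if not events:
        raise ValueError("no events")
    return _empirical(np.array([e.delta for e in events]), log_base)


def inter_event_times(events: Sequence[ContactEvent]) -> np.ndarray:
    """Per-dyad gaps between the end of one event and the start of the
    next, pooled over dyads.  A dyad with a single event contributes
    nothing."""
    by_dyad: dict[tuple[str, str], list[ContactEvent]] = {}
    for ev in events:
        by_dyad.setdefault(canonical_dyad(ev.i, ev.j), []).append(ev)
    iets = []
    for evs in by_dyad.values():
        evs.sort()
        for a, b in zip(evs, evs[1:]):
            iets.append(b.t - (a.t + a.delta))
    return np.array(iets, dtype=float)


def iet_distribution(events: Sequence[ContactEvent],
                     log_base: float | None = 10 ** 0.25) -> pd.DataFrame:
    """Distribution of inter-event times on links (seconds)."""
    if not events:
        raise ValueError("no events")
    return _empirical(inter_event_times(events), log_base)


def degree_distribution(network: nx.Graph) -> pd.DataFrame:
    """Empirical node-degree distribution of an aggregated network."""
    degs = np.array([d for _, d in network.degree()], dtype=float)
    if not len(degs):
        return pd.DataFrame({"value": [], "pdf": [], "binned": []})
    return _empirical(degs, log_base=None)


# ---------------------------------------------------------------------------
# aggregation

def aggregate_network(records: Iterable[TnetRecord | ContactEvent],
                      context_filter: str | None = None) -> nx.Graph:
    """Aggregate events into a weighted network.

    Edge weight is the summed duration (seconds) of the contributing
    events; node strength is the sum of incident weights.
    ``context_filter`` 'F' keeps events fully in free time (labels
    FFFF), 'C' fully in class time; annotation is required when a
    filter is used.
    """
    g = nx.Graph()
    for rec in records:
        if isinstance(rec, TnetRecord):
            ev, labels = rec.event, rec.labels
        else:
            ev, labels = rec, None
        if context_filter is not None:
            if labels is None:
                raise ValueError("context filtering needs annotated records")
            if labels != context_filter * 4:
                continue
        i, j = canonical_dyad(ev.i, ev.j)
        w = g.edges[i, j]["weight"] + ev.delta if g.has_edge(i, j) else ev.delta
        g.add_edge(i, j, weight=w)
    for n in g.nodes:
        g.nodes[n]["strength"] = sum(g.edges[n, m]["weight"]
                                     for m in g.neighbors(n))
    return g


# ---------------------------------------------------------------------------
# annotation summary

def summarize_totals(totals: pd.DataFrame) -> pd.DataFrame:
    """Percentage/hour arithmetic over a per-label count/duration table.

    ``totals`` needs columns (label, count, duration_s).  Adds the
    count and duration shares (half-up, 2 decimals) and whole hours
    (nearest integer), sorted by count descending.
    """
    df = totals[["label", "count", "duration_s"]].copy()
    tc = df["count"].sum()
    td = df["duration_s"].sum()
    df["count_pct"] = [_pct(100 * c / tc) for c in df["count"]]
    df["duration_pct"] = [_pct(100 * d / td) for d in df["duration_s"]]
    df["duration_h"] = [_hours(d) for d in df["duration_s"]]
    return (df.sort_values(["count", "label"], ascending=[False, True])
              .reset_index(drop=True))


def annotation_summary(records: Sequence[TnetRecord]) -> pd.DataFrame:
    """Per-label-type counts and durations of annotated events."""
    rows: dict[str, list[float]] = {}
    for rec in records:
        acc = rows.setdefault(rec.label_type, [0, 0])
        acc[0] += 1
        acc[1] += rec.event.delta
    totals = pd.DataFrame(
        [(lab, int(c), int(d)) for lab, (c, d) in rows.items()],
        columns=["label", "count", "duration_s"])
    return summarize_totals(totals)


def load_reference_annotation_totals() -> pd.DataFrame:
    """Published per-label event counts and total durations from a
    year-long preschool deployment (the package's reference input for
    the summary arithmetic)."""
    with importlib.resources.files("proxinet.data").joinpath(
            "annotation_totals.csv").open() as fh:
        return pd.read_csv(fh)
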