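"""Core domain types for wearable proximity-sensor data.

The atom of every signal file is the triplet *(observed DID, timestamp,
RSSI)*: one received beacon packet.  Timestamps are seconds since the
project reference midnight (T0); worn badges beacon every 5 seconds, so
cleaned timestamps live on a 5-second grid.  RSSI is the received signal
strength in integer dBm (more negative = weaker); badges record nothing
below the −94 dBm sensitivity floor and cleaned data span −93…−16 dBm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, NamingError, RecordError

#: beacon emission period, seconds
SLOT_S = 5
#: radio sensitivity floor: packets below this are never recorded
RSSI_SENSITIVITY = -94
#: recordable RSSI range after initial cleaning (dBm)
RSSI_MIN, RSSI_MAX = -93, -16
#: mutual observations weaker than this never form a handshake pair
HANDSHAKE_RSSI_FLOOR = -93
#: maximum raw-time offset between the two directions of a handshake
HANDSHAKE_MAX_DT = 2.5

#: half-day session windows as seconds-of-day: morning 08:30-11:20,
#: afternoon 13:45-15:50.  Wednesday (day 3) has no afternoon session.
SESSION_CLOCK = {"M": (8 * 3600 + 30 * 60, 11 * 3600 + 20 * 60),
                 "A": (13 * 3600 + 45 * 60, 15 * 3600 + 50 * 60)}
HALF_DAYS_PER_WEEK = tuple(
    (day, sess) for day in range(1, 6) for sess in ("M", "A")
    if not (day == 3 and sess == "A")
)


class BeaconRecord(NamedTuple):
    """One received packet: who was heard, when, and how strongly."""

    observed_did: str
    timestamp: int
    rssi: int


class SessionWindow(NamedTuple):
    """Absolute [start, end) bounds of one half-day session."""

    session: str
    start: int
    end: int

    @property
    def n_slots(self) -> int:
        return (self.end - self.start) // SLOT_S

    def slots(self) -> np.ndarray:
        return np.arange(self.start, self.end, SLOT_S)


def session_window(day: int, session: str) -> SessionWindow:
    """Absolute session window for ``day`` (1=Monday … 5=Friday).

    Timestamps count from the project T0 midnight, so day *d* adds
    ``(d-1) * 86400`` seconds to the clock times.
    """
    if session not in SESSION_CLOCK:
        raise NamingError(f"session must be 'M' or 'A', got {session!r}")
    if not 1 <= day <= 5:
        raise NamingError(f"day must be 1-5, got {day}")
    lo, hi = SESSION_CLOCK[session]
    off = (day - 1) * 86400
    return SessionWindow(session, lo + off, hi + off)


@dataclass(frozen=True)
class BadgeId:
    """A 4-digit badge identifier.

    The first digit encodes the bearer: 0 = child, 1 = adult (school
    staff), 2 = stationary RX badge.  For RX badges the last digit is the
    class number (2001-2007) or a gym room (2010, 2011).
    """

    did: str

    def __post_init__(self):
        if len(self.did) != 4 or not self.did.isdigit():
            raise NamingError(f"DID must be a 4-digit code, got {self.did!r}")
        if self.did[0] not in "012":
            raise NamingError(f"DID first digit must be 0/1/2: {self.did!r}")

    @property
    def kind(self) -> str:
        return {"0": "child", "1": "adult", "2": "rx"}[self.did[0]]

    @property
    def rx_room(self) -> str:
        """Room an RX badge is fixed in: 'class<k>' or 'gym<k>'."""
        if self.kind != "rx":
            raise NamingError(f"{self.did} is not an RX badge")
        last = int(self.did[3])
        if self.did in ("2010", "2011"):
            return f"gym{last}"
        if 1 <= last <= 7 and self.did[:3] == "200":
            return f"class{last}"
        raise NamingError(f"unrecognised RX code {self.did!r}")

    def __str__(self) -> str:
        return self.did


def badge_kind(did: str) -> str:
    return BadgeId(did).kind


_SEQ_COLUMNS = ["did", "t", "rssi"]


@dataclass
class HalfDaySequence:
    """All packets one badge received during one half-day session.

    ``data`` holds the triplets as a DataFrame with columns
    ``(did, t, rssi)``, sorted by timestamp with ties broken by observed
    DID ascending.
    """

    owner: str
    class_id: int
    day: int
    session: str
    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_SEQ_COLUMNS))

    def __post_init__(self):
        df = self.data
        if list(df.columns) != _SEQ_COLUMNS:
            df = df[_SEQ_COLUMNS]
        df = df.astype({"did": str, "t": np.int64, "rssi": np.int64})
        self.data = (df.sort_values(["t", "did"], kind="mergesort")
                       .reset_index(drop=True))

    @classmethod
    def from_records(cls, owner: str, class_id: int, day: int, session: str,
                     records: Iterable[tuple]) -> "HalfDaySequence":
        df = pd.DataFrame(list(records), columns=_SEQ_COLUMNS)
        return cls(owner, class_id, day, session, df)

    @property
    def window(self) -> SessionWindow:
        return session_window(self.day, self.session)

    @property
    def records(self) -> list[BeaconRecord]:
        return [BeaconRecord(d, int(t), int(r))
                for d, t, r in self.data.itertuples(index=False)]

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HalfDaySequence):
            return NotImplemented
        meta = (self.owner, self.class_id, self.day, self.session) == \
               (other.owner, other.class_id, other.day, other.session)
        return meta and self.data.equals(other.data)

    def copy(self) -> "HalfDaySequence":
        return replace(self, data=self.data.copy())

    def with_data(self, df: pd.DataFrame) -> "HalfDaySequence":
        return replace(self, data=df.reset_index(drop=True))

    def validate(self) -> None:
        """Check record invariants (cleaned-range RSSI, in-window times)."""
        bad = self.data.index[(self.data.rssi < RSSI_SENSITIVITY) |
                              (self.data.rssi > RSSI_MAX)]
        if len(bad):
            raise RecordError(
                f"RSSI outside [{RSSI_SENSITIVITY}, {RSSI_MAX}]",
                row=int(bad[0]))
        win = self.window
        out = self.data.index[(self.data.t < win.start) | (self.data.t >= win.end)]
        if len(out):
            raise RecordError("timestamp outside session window", row=int(out[0]))


class ContactEvent(NamedTuple):
    """Temporal edge theta = (t, i, j, delta): an interaction event
    between badges i and j starting at t and lasting delta seconds
    (a positive multiple of the 5-s slot)."""

    t: int
    i: str
    j: str
    delta: int


@dataclass(frozen=True)
class TnetRecord:
    """One row of a reconstructed temporal-network file.

    ``labels`` is the 4-symbol free/class state string (start/end state
    for each member) and ``same_class`` flags classmates; ``method``
    names the reconstruction route that produced the event.
    """

    event: ContactEvent
    labels: str
    same_class: int
    method: str = "unrec"

    def __post_init__(self):
        if len(self.labels) != 4 or set(self.labels) - {"F", "C"}:
            raise FormatError(f"labels must be 4 symbols over {{F,C}}: {self.labels!r}")
        if self.same_class not in (0, 1):
            raise FormatError(f"same-class flag must be 0/1: {self.same_class!r}")
        if self.event.delta <= 0 or self.event.delta % SLOT_S:
            raise FormatError(
                f"duration must be a positive multiple of {SLOT_S} s: {self.event.delta}")

    @property
    def label_type(self) -> str:
        """Full SSSSX annotation, e.g. 'FCFC1'."""
        return f"{self.labels}{self.same_class}"


class PeriodSegment(NamedTuple):
    """A labelled schedule interval [start, end) for one class.

    ``label`` is 'F' for free time (class out in the shared yard) or 'C'
    for class time (class in its own room).
    """

    class_id: int
    start: int
    end: int
    label: str


class InactiveInterval(NamedTuple):
    """A half-open interval [start, end) of one badge's data flagged for
    removal, tagged with the issue that detected it."""

    did: str
    start: int
    end: int
    cause: str


class HandshakePair(NamedTuple):
    """A mutual observation on the 5-s grid: badge i heard j and j heard
    i within ±2.5 s.  ``rssi_ij`` is i's emission as received by j;
    ``rssi_ji`` is j's emission as received by i.  One side may be None
    when an unmatched single direction is retained."""

    slot: int
    i: str
    j: str
    rssi_ij: int | None
    rssi_ji: int | None


@dataclass
class BinaryStateSequence:
    """Per-dyad interaction states on the 5-s grid.

    Only slots with a handshake (or a reconstructed state) are present;
    ``slots`` is strictly increasing on the grid and ``states`` holds the
    matching 0/1 values.
    """

    i: str
    j: str
    slots: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        self.slots = np.asarray(self.slots, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.slots.shape != self.states.shape:
            raise RecordError("slots and states must align")
        if len(self.slots) and (np.any(np.diff(self.slots) <= 0)
                                or np.any(self.slots % SLOT_S)):
            raise RecordError("slots must be strictly increasing on the 5-s grid")

    @property
    def dyad(self) -> tuple[str, str]:
        return (self.i, self.j)

    def __len__(self) -> int:
        return len(self.slots)


def canonical_dyad(a: str, b: str) -> tuple[str, str]:
    """Order a badge pair canonically (smaller DID first)."""
    return (a, b) if a < b else (b, a)
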