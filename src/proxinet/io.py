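"""Readers and writers for every file dialect of the processing chain.

Half-day signal files are headerless CSV triplets ``did,t,rssi`` named
``CID-D-DID-MA.csv`` (class, weekday, badge, morning/afternoon) and live
under ``Y_WEEKXX/HD_individual_{cleaned,preprocessed}/{PROX,RX}/``.
Temporal-network (tnet) files ``D-MA-RM.csv`` carry a header
``t,i,j,delta,labels,flag`` where RM names the reconstruction method.
Ground-truth observation tables (GT1/GT2/GT3) and the weekly IN-OUT /
DURATION presence tables are plain CSV with headers; the column coding
is bundled in ``data/gt_variables.csv``.

The canonical dialects are declared here (the field fixes the column
names, not header conventions); round-trips are byte-stable.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (FormatError, MixingError, NamingError, RecordError,
                     UnknownBadgeError)
from .types import (ContactEvent, HalfDaySequence, SessionWindow, SLOT_S,
                    TnetRecord, RSSI_MAX, RSSI_SENSITIVITY, badge_kind)

#: reconstruction-method tags allowed in tnet filenames
TNET_METHODS = ("unrec", "naive", "hmm", "blstm_RSSI")

_HALF_DAY_RE = re.compile(r"^([1-7])-([1-5])-(\d{4})-([MA])\.csv$")
_TNET_RE = re.compile(r"^([1-5])-([MA])-(\w+)\.csv$")


def half_day_filename(seq: HalfDaySequence) -> str:
    return f"{seq.class_id}-{seq.day}-{seq.owner}-{seq.session}.csv"


def parse_half_day_filename(name: str) -> tuple[int, int, str, str]:
    """Parse ``CID-D-DID-MA.csv`` into (class_id, day, did, session)."""
    m = _HALF_DAY_RE.match(name)
    if not m:
        raise NamingError(f"filename does not parse as CID-D-DID-MA.csv: {name!r}")
    cid, day, did, session = m.groups()
    return int(cid), int(day), did, session


def read_half_day(path: str | Path) -> HalfDaySequence:
    """Read one half-day triplet file; metadata comes from the filename.

    Rows are validated: non-numeric fields or RSSI outside the
    recordable range [−94, −16] dBm raise a :class:`RecordError` carrying
    the offending row index.
    """
    path = Path(path)
    cid, day, did, session = parse_half_day_filename(path.name)
    try:
        df = pd.read_csv(path, header=None, names=["did", "t", "rssi"],
                         dtype={"did": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["did", "t", "rssi"])
    for col in ("t", "rssi"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise RecordError(f"non-numeric {col} field", row=int(bad[0]))
        df[col] = vals
    bad = df.index[(df.rssi < RSSI_SENSITIVITY) | (df.rssi > RSSI_MAX)]
    if len(bad):
        raise RecordError(
            f"RSSI outside [{RSSI_SENSITIVITY}, {RSSI_MAX}] dBm", row=int(bad[0]))
    return HalfDaySequence(did, cid, day, session, df)


def write_half_day(seq: HalfDaySequence, directory: str | Path) -> Path:
    """Write a half-day file in the canonical dialect (no header)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / half_day_filename(seq)
    seq.data.to_csv(path, header=False, index=False)
    return path


def half_day_directory(root: str | Path, stage: str, kind: str) -> Path:
    """Folder for half-day files: <root>/HD_individual_<stage>/<PROX|RX>."""
    if stage not in ("cleaned", "preprocessed"):
        raise NamingError(f"stage must be cleaned/preprocessed: {stage!r}")
    if kind not in ("PROX", "RX"):
        raise NamingError(f"kind must be PROX/RX: {kind!r}")
    return Path(root) / f"HD_individual_{stage}" / kind


def read_half_day_tree(root: str | Path, stage: str = "cleaned"
                       ) -> dict[tuple[int, str], dict[str, HalfDaySequence]]:
    """Read every PROX and RX half-day file below ``root``.

    Returns a mapping (day, session) -> {owner DID: sequence}; RX
    sequences are included under their 2xxx DIDs.
    """
    out: dict[tuple[int, str], dict[str, HalfDaySequence]] = {}
    for kind in ("PROX", "RX"):
        d = half_day_directory(root, stage, kind)
        if not d.is_dir():
            continue
        for path in sorted(d.glob("*.csv")):
            seq = read_half_day(path)
            out.setdefault((seq.day, seq.session), {})[seq.owner] = seq
    return out


def write_half_day_tree(sequences: Mapping[tuple[int, str], Mapping[str, HalfDaySequence]],
                        root: str | Path, stage: str = "cleaned") -> None:
    for half_day in sequences.values():
        for seq in half_day.values():
            kind = "RX" if badge_kind(seq.owner) == "rx" else "PROX"
            write_half_day(seq, half_day_directory(root, stage, kind))


# ---------------------------------------------------------------------------
# tnet files

def tnet_filename(day: int, session: str, method: str) -> str:
    if method not in TNET_METHODS:
        raise FormatError(f"unknown reconstruction method tag {method!r}")
    return f"{day}-{session}-{method}.csv"


def write_tnet(records: Sequence[TnetRecord], directory: str | Path,
               day: int, session: str, method: str) -> Path:
    """Write one temporal-network file ``D-MA-RM.csv`` (with header)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / tnet_filename(day, session, method)
    rows = [(r.event.t, r.event.i, r.event.j, r.event.delta,
             r.labels, r.same_class) for r in records]
    df = pd.DataFrame(rows, columns=["t", "i", "j", "delta", "labels", "flag"])
    df.to_csv(path, index=False)
    return path


def read_tnet(path: str | Path) -> list[TnetRecord]:
    path = Path(path)
    m = _TNET_RE.match(path.name)
    if not m:
        raise NamingError(f"filename does not parse as D-MA-RM.csv: {path.name!r}")
    method = m.group(3)
    if method not in TNET_METHODS:
        raise FormatError(f"unknown reconstruction method tag {method!r}")
    df = pd.read_csv(path, dtype={"i": str, "j": str, "labels": str})
    out = []
    for row in df.itertuples(index=False):
        ev = ContactEvent(int(row.t), str(row.i), str(row.j), int(row.delta))
        out.append(TnetRecord(ev, row.labels, int(row.flag), method))
    return out


# ---------------------------------------------------------------------------
# initial cleaning: incidents and fragment merging

class Incident:
    """One logged field incident: badge unused/broken/missing over
    [start, end).  All signals emitted *or* received by the badge inside
    the interval are dropped."""

    def __init__(self, did: str, start: int, end: int, reason: str = ""):
        self.did, self.start, self.end, self.reason = did, int(start), int(end), reason


def apply_incident_log(sequences: Mapping[str, HalfDaySequence],
                       incidents: Iterable[Incident]
                       ) -> dict[str, HalfDaySequence]:
    """Remove all traces of incident badges inside their intervals.

    Removal is bidirectional: the badge's own received records in the
    interval go, and so does every appearance of the badge as observed
    DID in other badges' sequences.  Nothing else is touched.
    """
    incidents = list(incidents)
    known = set(sequences)
    for inc in incidents:
        if inc.did not in known:
            raise UnknownBadgeError(f"incident references unknown DID {inc.did}")
    out = {}
    for owner, seq in sequences.items():
        df = seq.data
        drop = np.zeros(len(df), dtype=bool)
        for inc in incidents:
            in_window = (df.t.values >= inc.start) & (df.t.values < inc.end)
            if owner == inc.did:
                drop |= in_window
            drop |= in_window & (df.did.values == inc.did)
        out[owner] = seq.with_data(df[~drop])
    return out


def merge_fragments(fragments: Sequence[HalfDaySequence],
                    window: SessionWindow | None = None) -> HalfDaySequence:
    """Merge per-badge file fragments into the single half-day sequence.

    The union of fragment records is clipped to the session window,
    de-duplicated on (observed DID, timestamp) keeping the strongest
    RSSI (a receiver logs one packet per sender per slot), and sorted.
    """
    if not fragments:
        raise MixingError("no fragments to merge")
    first = fragments[0]
    for f in fragments[1:]:
        if (f.owner, f.day, f.session) != (first.owner, first.day, first.session):
            raise MixingError(
                f"fragment {f.owner}/{f.day}{f.session} does not belong with "
                f"{first.owner}/{first.day}{first.session}")
    if window is None:
        window = first.window
    df = pd.concat([f.data for f in fragments], ignore_index=True)
    df = df[(df.t >= window.start) & (df.t < window.end)]
    df = (df.sort_values("rssi", ascending=False)
            .drop_duplicates(["did", "t"], keep="first"))
    return first.with_data(df)


# ---------------------------------------------------------------------------
# presence tables

def coverage_seconds(seq: HalfDaySequence) -> int:
    """Covered observation time: 5 s per distinct slot with any record."""
    if not len(seq.data):
        return 0
    return SLOT_S * int(seq.data.t.floordiv(SLOT_S).nunique())


def presence_tables(enrollment: Mapping[str, Mapping[int, bool]],
                    sequences: Iterable[tuple[int, HalfDaySequence]]
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the weekly IN-OUT and DURATION tables.

    ``enrollment`` maps DID -> {week: enrolled?}; ``sequences`` yields
    (week, half-day sequence) pairs.  The DURATION cell is the summed
    covered seconds for that badge and week, or NA when it produced no
    data (an enrolled participant absent all week is IN + NA).
    """
    totals: dict[tuple[str, int], int] = {}
    for week, seq in sequences:
        if seq.owner not in enrollment:
            raise UnknownBadgeError(f"sequence owner {seq.owner} not in roster")
        key = (seq.owner, week)
        totals[key] = totals.get(key, 0) + coverage_seconds(seq)
    weeks = sorted({w for m in enrollment.values() for w in m})
    dids = sorted(enrollment)
    in_out = pd.DataFrame(
        [["IN" if enrollment[d].get(w, False) else "OUT" for w in weeks]
         for d in dids],
        index=pd.Index(dids, name="DID"),
        columns=[f"WEEK{w:02d}" for w in weeks])
    duration = pd.DataFrame(
        [[totals.get((d, w), np.nan) if totals.get((d, w), 0) else np.nan
          for w in weeks] for d in dids],
        index=pd.Index(dids, name="DID"),
        columns=[f"WEEK{w:02d}" for w in weeks])
    return in_out, duration


def write_presence_tables(in_out: pd.DataFrame, duration: pd.DataFrame,
                          directory: str | Path) -> tuple[Path, Path]:
    directory = Path(directory) / "PRESENCEDURATION"
    directory.mkdir(parents=True, exist_ok=True)
    p1 = directory / "IN-OUT.csv"
    p2 = directory / "DURATION.csv"
    in_out.to_csv(p1)
    duration.to_csv(p2, na_rep="NA", float_format="%.0f")
    return p1, p2


# ---------------------------------------------------------------------------
# ground-truth observation tables

#: canonical columns of the three ground-truth observation layouts
GT_COLUMNS = {
    "GT1": ["pair", "t", "interaction", "orientation"],
    "GT2": ["pair", "t", "distance_cm", "orientation", "rssi"],
    "GT3": ["session", "t", "id_a", "id_b", "distance_m"],
}


def write_gt_table(df: pd.DataFrame, directory: str | Path, which: str) -> Path:
    if which not in GT_COLUMNS:
        raise FormatError(f"unknown ground-truth table {which!r}")
    missing = [c for c in GT_COLUMNS[which] if c not in df.columns]
    if missing:
        raise FormatError(f"{which} table missing columns {missing}")
    directory = Path(directory) / "GROUNDTRUTH"
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{which}.csv"
    df[GT_COLUMNS[which]].to_csv(path, index=False)
    return path


def read_gt_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    which = path.stem
    if which not in GT_COLUMNS:
        raise FormatError(f"unknown ground-truth table {which!r}")
    return pd.read_csv(path)
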