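"""Temporal-network reconstruction from pre-processed signal logs.

Mutual observations on the 5-s beacon grid are matched into *handshake
pairs* (both directions within ±2.5 s, RSSI at least −93 dBm), each
pair is classified into interaction / non-interaction by a logistic
model over the two directed RSSI values, and the resulting binary state
sequence is cleaned up by one of three routes — naive gap-merging,
2-state HMM decoding over short-envelope features, or an optional
bidirectional recurrent labeler — before maximal runs of 1-states are
merged into contact events (t, i, j, delta).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import (AlignmentError, CapabilityError, DegenerateFitError,
                     ProxinetError)
from .types import (BinaryStateSequence, ContactEvent, HalfDaySequence,
                    HandshakePair, HANDSHAKE_MAX_DT, HANDSHAKE_RSSI_FLOOR,
                    SLOT_S, canonical_dyad)

#: default naive-merge gap: 6 slots = 30 seconds
DEFAULT_GAP_SLOTS = 6


# ---------------------------------------------------------------------------
# handshake pairs

def build_handshakes(seq_i: HalfDaySequence, seq_j: HalfDaySequence,
                     min_rssi: int = HANDSHAKE_RSSI_FLOOR,
                     max_dt: float = HANDSHAKE_MAX_DT,
                     keep_unmatched: bool = False) -> list[HandshakePair]:
    """Match the two badges' mutual observations into handshake pairs.

    Records weaker than ``min_rssi`` never participate.  Matching is
    greedy by nearest timestamp within ``±max_dt`` seconds, each record
    used at most once.  Unmatched one-directional records are dropped
    unless ``keep_unmatched`` (then the absent side is None).  The
    output is symmetric in the argument order (canonical dyad).
    """
    i, j = canonical_dyad(seq_i.owner, seq_j.owner)
    if i != seq_i.owner:
        seq_i, seq_j = seq_j, seq_i
    # j->i packets live in i's log and vice versa
    obs_ji = seq_i.data[(seq_i.data.did == j) & (seq_i.data.rssi >= min_rssi)]
    obs_ij = seq_j.data[(seq_j.data.did == i) & (seq_j.data.rssi >= min_rssi)]
    t_ji, r_ji = obs_ji.t.values, obs_ji.rssi.values
    t_ij, r_ij = obs_ij.t.values, obs_ij.rssi.values

    # candidate pairs within the time tolerance, greedily matched by |dt|
    cand = []
    start = 0
    for a, ta in enumerate(t_ij):
        while start < len(t_ji) and t_ji[start] < ta - max_dt:
            start += 1
        b = start
        while b < len(t_ji) and t_ji[b] <= ta + max_dt:
            cand.append((abs(ta - t_ji[b]), a, b))
            b += 1
    cand.sort(key=lambda x: (x[0], x[1], x[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: dict[int, HandshakePair] = {}
    for _, a, b in cand:
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        slot = int(round(min(t_ij[a], t_ji[b]) / SLOT_S)) * SLOT_S
        if slot not in pairs:
            pairs[slot] = HandshakePair(slot, i, j, int(r_ij[a]), int(r_ji[b]))
    if keep_unmatched:
        for a, ta in enumerate(t_ij):
            if a not in used_a:
                slot = int(round(ta / SLOT_S)) * SLOT_S
                pairs.setdefault(slot, HandshakePair(slot, i, j, int(r_ij[a]), None))
        for b, tb in enumerate(t_ji):
            if b not in used_b:
                slot = int(round(tb / SLOT_S)) * SLOT_S
                pairs.setdefault(slot, HandshakePair(slot, i, j, None, int(r_ji[b])))
    return [pairs[s] for s in sorted(pairs)]


def all_dyad_handshakes(sequences: Mapping[str, HalfDaySequence],
                        **kwargs) -> dict[tuple[str, str], list[HandshakePair]]:
    """Handshake pairs for every dyad with any mutual observation."""
    dyads = set()
    for owner, seq in sequences.items():
        for did in seq.data.did.unique():
            if did in sequences and did != owner:
                dyads.add(canonical_dyad(owner, did))
    out = {}
    for i, j in sorted(dyads):
        pairs = build_handshakes(sequences[i], sequences[j], **kwargs)
        if pairs:
            out[(i, j)] = pairs
    return out


# ---------------------------------------------------------------------------
# logistic state classification

def pair_features(pairs: Sequence[HandshakePair],
                  floor: int = HANDSHAKE_RSSI_FLOOR) -> np.ndarray:
    """Feature matrix (n, 2): both directed RSSIs, absent side imputed
    at the −93 dBm floor."""
    return np.array([[p.rssi_ij if p.rssi_ij is not None else floor,
                      p.rssi_ji if p.rssi_ji is not None else floor]
                     for p in pairs], dtype=float)


@dataclass
class StateClassifier:
    """Logistic interaction/non-interaction classifier over RSSI.

    Predicted interaction probability must be non-decreasing in each
    RSSI feature.  Coefficient signs are checked after fitting: when
    the two (nearly collinear) directions produce a negative weight,
    the model is refit on the symmetric mean-RSSI feature, which
    guarantees monotonicity; ties at probability 0.5 resolve
    conservatively to non-interaction.
    """

    model: LogisticRegression
    symmetric: bool = False

    @classmethod
    def train(cls, pairs: Sequence[HandshakePair], labels: Sequence[int],
              C: float = 1.0) -> "StateClassifier":
        y = np.asarray(labels, dtype=int)
        if len(set(y.tolist())) < 2:
            raise DegenerateFitError("training labels contain a single class")
        X = pair_features(pairs)
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
        model.fit(X, y)
        if not np.any(model.coef_ < 0):
            return cls(model)
        model = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
        model.fit(X.mean(axis=1, keepdims=True), y)
        if np.any(model.coef_ < 0):
            raise DegenerateFitError(
                "interaction probability decreases with RSSI; the training "
                "labels contradict a signal-strength classifier")
        return cls(model, symmetric=True)

    def _X(self, pairs: Sequence[HandshakePair]) -> np.ndarray:
        X = pair_features(pairs)
        return X.mean(axis=1, keepdims=True) if self.symmetric else X

    def predict_proba(self, pairs: Sequence[HandshakePair]) -> np.ndarray:
        return self.model.predict_proba(self._X(pairs))[:, 1]

    def predict(self, pairs: Sequence[HandshakePair]) -> np.ndarray:
        return (self.predict_proba(pairs) > 0.5).astype(np.int8)


def train_state_classifier(gt_pairs: Sequence[HandshakePair],
                           gt_labels: Sequence[int],
                           C: float = 1.0) -> StateClassifier:
    """Fit the logistic interaction classifier on ground-truth pairs."""
    return StateClassifier.train(gt_pairs, gt_labels, C=C)


def classify_states(pairs: Sequence[HandshakePair],
                    classifier: StateClassifier) -> BinaryStateSequence:
    """One binary state per handshake slot (threshold 0.5)."""
    if not pairs:
        return BinaryStateSequence("", "", np.array([], dtype=np.int64),
                                   np.array([], dtype=np.int8))
    states = classifier.predict(pairs)
    return BinaryStateSequence(pairs[0].i, pairs[0].j,
                               np.array([p.slot for p in pairs]), states)


# ---------------------------------------------------------------------------
# naive reconstruction

def naive_reconstruct(states: BinaryStateSequence,
                      gap_slots: int = DEFAULT_GAP_SLOTS) -> BinaryStateSequence:
    """Bridge short non-interaction gaps between 1-states.

    Any maximal run of non-1 slots — explicit 0-states and missing
    slots alike, since packet loss is exactly what gap-merging exists to
    bridge — of length at most ``gap_slots`` lying between two 1-states
    is rewritten to 1.  ``gap_slots=0`` is the identity
    (unreconstructed sequence).
    """
    if gap_slots < 0:
        raise ValueError("gap_slots must be >= 0")
    if gap_slots == 0 or len(states) == 0:
        return BinaryStateSequence(states.i, states.j, states.slots.copy(),
                                   states.states.copy())
    lo, hi = int(states.slots[0]), int(states.slots[-1])
    grid = np.arange(lo, hi + SLOT_S, SLOT_S)
    dense = np.zeros(len(grid), dtype=np.int8)
    idx = (states.slots - lo) // SLOT_S
    dense[idx] = states.states
    ones = np.flatnonzero(dense == 1)
    for a, b in zip(ones, ones[1:]):
        if 0 < b - a - 1 <= gap_slots:
            dense[a:b] = 1
    filled = np.flatnonzero(dense == 1)
    keep = np.union1d(idx, filled)
    return BinaryStateSequence(states.i, states.j, grid[keep], dense[keep])


def merge_events(states: BinaryStateSequence) -> list[ContactEvent]:
    """Merge maximal runs of grid-adjacent 1-slots into contact events
    (t = first slot, delta = 5 s × run length)."""
    on = states.slots[states.states == 1]
    if not len(on):
        return []
    breaks = np.flatnonzero(np.diff(on) != SLOT_S)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(on) - 1]))
    return [ContactEvent(int(on[s]), states.i, states.j,
                         int(on[e] - on[s]) + SLOT_S)
            for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# HMM reconstruction

def hmm_features(pairs: Sequence[HandshakePair],
                 classifier: StateClassifier,
                 envelope_slots: int = 3) -> np.ndarray:
    """Per-slot features: trailing-envelope mean RSSI and the logistic
    interaction probability.  The envelope covers the current and the
    preceding ``envelope_slots - 1`` handshake slots."""
    X = pair_features(pairs)
    rssi = X.mean(axis=1)
    prob = classifier.predict_proba(pairs)
    env = np.array([rssi[max(0, k - envelope_slots + 1):k + 1].mean()
                    for k in range(len(rssi))])
    return np.column_stack([env, prob])


class HmmReconstructor:
    """2-hidden-state Gaussian HMM over short-envelope features.

    The hidden states are mapped to interaction/non-interaction by the
    emission mean of the classifier-probability feature; decoding uses
    the most likely (Viterbi) path.
    """

    def __init__(self, envelope_slots: int = 3, n_iter: int = 50,
                 random_state: int = 0):
        from hmmlearn.hmm import GaussianHMM
        self.envelope_slots = envelope_slots
        self.model = GaussianHMM(n_components=2, covariance_type="diag",
                                 n_iter=n_iter, random_state=random_state,
                                 min_covar=1e-3)
        self.fitted = False
        self.on_state = 1

    def fit(self, feature_seqs: Sequence[np.ndarray]) -> "HmmReconstructor":
        X = np.concatenate(feature_seqs)
        lengths = [len(f) for f in feature_seqs]
        self.model.fit(X, lengths)
        # component with the higher mean classifier probability is 'interaction'
        self.on_state = int(np.argmax(self.model.means_[:, -1]))
        self.fitted = True
        return self

    def decode(self, features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ProxinetError("HMM reconstructor is not fitted")
        _, path = self.model.decode(features, algorithm="viterbi")
        return (path == self.on_state).astype(np.int8)


def hmm_reconstruct(pairs: Sequence[HandshakePair],
                    states: BinaryStateSequence,
                    model: HmmReconstructor,
                    classifier: StateClassifier) -> BinaryStateSequence:
    """Decode the dyad's handshake sequence with a fitted HMM."""
    if not pairs:
        return states
    feats = hmm_features(pairs, classifier, model.envelope_slots)
    decoded = model.decode(feats)
    return BinaryStateSequence(states.i, states.j, states.slots.copy(), decoded)


# ---------------------------------------------------------------------------
# optional BiLSTM plug-in

def _torch():
    try:
        import torch
        return torch
    except ImportError as exc:  # pragma: no cover - torch absent
        raise CapabilityError(
            "BiLSTM reconstruction needs the optional 'torch' dependency; "
            "install pytorch or use the naive/hmm methods") from exc


class BiLstmReconstructor:
    """Small bidirectional recurrent sequence labeler over RSSI features.

    Unlike the HMM, it conditions each slot's state on both preceding
    and succeeding handshake pairs.  Optional: constructing it without
    pytorch installed raises a :class:`CapabilityError`.
    """

    def __init__(self, hidden: int = 16, seed: int = 0):
        torch = _torch()
        torch.manual_seed(seed)
        self.net = torch.nn.Sequential()  # placeholder until built
        self.hidden = hidden
        self._build(torch)

    def _build(self, torch):
        class _Net(torch.nn.Module):
            def __init__(self, hidden):
                super().__init__()
                self.lstm = torch.nn.LSTM(2, hidden, batch_first=True,
                                          bidirectional=True)
                self.head = torch.nn.Linear(2 * hidden, 1)

            def forward(self, x):
                h, _ = self.lstm(x)
                return self.head(h).squeeze(-1)

        self.net = _Net(self.hidden)

    def fit(self, feature_seqs, label_seqs, epochs: int = 30,
            lr: float = 1e-2):
        torch = _torch()
        opt = torch.optim.Adam(self.net.parameters(), lr=lr)
        loss_fn = torch.nn.BCEWithLogitsLoss()
        for _ in range(epochs):
            for X, y in zip(feature_seqs, label_seqs):
                xb = torch.tensor(X, dtype=torch.float32).unsqueeze(0)
                yb = torch.tensor(y, dtype=torch.float32).unsqueeze(0)
                opt.zero_grad()
                loss = loss_fn(self.net(xb), yb)
                loss.backward()
                opt.step()
        return self

    def predict(self, features) -> np.ndarray:
        torch = _torch()
        with torch.no_grad():
            xb = torch.tensor(features, dtype=torch.float32).unsqueeze(0)
            logits = self.net(xb).squeeze(0).numpy()
        return (logits > 0).astype(np.int8)


def bilstm_reconstruct(pairs: Sequence[HandshakePair],
                       model: "BiLstmReconstructor") -> BinaryStateSequence:
    """Per-slot states from the bidirectional labeler (optional)."""
    _torch()
    feats = pair_features(pairs)
    states = model.predict(feats)
    return BinaryStateSequence(pairs[0].i, pairs[0].j,
                               np.array([p.slot for p in pairs]), states)


# ---------------------------------------------------------------------------
# evaluation

def evaluate_accuracy(pred: BinaryStateSequence,
                      true: BinaryStateSequence) -> dict:
    """Per-slot accuracy over the slots present in the truth grid.

    A predicted slot missing from the prediction counts as state 0
    (no interaction claimed).  Raises :class:`AlignmentError` when the
    grids are disjoint.
    """
    if len(true) == 0:
        raise AlignmentError("truth sequence has no slots")
    if len(pred) and not np.intersect1d(pred.slots, true.slots).size:
        raise AlignmentError("prediction and truth grids are disjoint")
    pred_map = np.zeros(len(true.slots), dtype=np.int8)
    if len(pred):
        idx = np.searchsorted(true.slots, pred.slots)
        ok = (idx < len(true.slots))
        ok[ok] &= true.slots[idx[ok]] == pred.slots[ok]
        pred_map[idx[ok]] = pred.states[ok]
    match = pred_map == true.states
    return {"accuracy": float(match.mean()), "n_slots": int(len(true)),
            "n_correct": int(match.sum())}


def pooled_accuracy(per_dyad: Iterable[dict]) -> dict:
    """Pool per-dyad accuracy reports: both the slot-pooled fraction and
    the unweighted per-dyad mean (the two conventions for averaging)."""
    reports = list(per_dyad)
    n = sum(r["n_slots"] for r in reports)
    correct = sum(r["n_correct"] for r in reports)
    return {
        "pooled_accuracy": correct / n if n else float("nan"),
        "mean_dyad_accuracy": (float(np.mean([r["accuracy"] for r in reports]))
                               if reports else float("nan")),
        "n_slots": n,
        "n_dyads": len(reports),
    }


def train_test_split_dyads(dyads: Sequence, test_frac: float = 0.1,
                           seed: int = 0) -> tuple[list, list]:
    """Split dyads 90/10 for training vs held-out evaluation."""
    rng = np.random.default_rng(seed)
    dyads = list(dyads)
    order = rng.permutation(len(dyads))
    n_test = max(1, int(round(test_frac * len(dyads))))
    test = [dyads[k] for k in order[:n_test]]
    train = [dyads[k] for k in order[n_test:]]
    return train, test
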