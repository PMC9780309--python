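"""Shared fixtures: tiny hand-built sequences plus seeded simulated
deployments (built once per session; the simulator is itself under
test, so end-to-end fixtures always carry their truth bundle)."""

from __future__ import annotations

import pytest

from proxinet.config import ArtifactConfig, RssiRegime, small_config
from proxinet.simulate import simulate_deployment, truth_state_sequences
from proxinet.reconstruct import all_dyad_handshakes, train_state_classifier
from proxinet.types import HalfDaySequence, badge_kind, session_window

#: morning session start (seconds since the reference midnight, day 1)
S = session_window(1, "M").start
KEY = (1, "M")


def make_seq(owner="0001", records=(), class_id=1, day=1, session="M"):
    return HalfDaySequence.from_records(owner, class_id, day, session, records)


@pytest.fixture(scope="session")
def oracle_deployment():
    """Noise-free conditions: zero loss, zero artifacts, zero
    interference, fully separated RSSI regimes."""
    cfg = small_config(
        seed=7,
        packet_loss_prob=0.0,
        rssi_interaction=RssiRegime(-60, 1, -63, -57),
        rssi_background=RssiRegime(-88, 2, -93, -83),
    )
    cfg.events.interference_rate_ph = 0.0
    cfg.artifacts = ArtifactConfig(unworn_prob=0, pile_prob=0, silent_prob=0,
                                   deaf_prob=0, edge_burst_prob=0)
    signals, truth = simulate_deployment(cfg)
    return cfg, signals, truth


@pytest.fixture(scope="session")
def noisy_deployment():
    """Default study conditions (scaled roster): noise and artifacts."""
    cfg = small_config(seed=5)
    signals, truth = simulate_deployment(cfg)
    return cfg, signals, truth


def prox_of(signals, key=KEY):
    return {d: s for d, s in signals[key].items() if badge_kind(d) != "rx"}


def rx_of(signals, key=KEY):
    return {s.class_id: s for d, s in signals[key].items()
            if badge_kind(d) == "rx"}


def labelled_handshakes(signals, truth, key=KEY):
    """Handshake pairs of every dyad with their ground-truth labels."""
    handshakes = all_dyad_handshakes(prox_of(signals, key))
    ts = truth_state_sequences(truth, key)
    pairs, labels = [], []
    for dyad, plist in sorted(handshakes.items()):
        t = ts.get(dyad)
        active = set() if t is None else set(t.slots[t.states == 1].tolist())
        for p in plist:
            pairs.append(p)
            labels.append(1 if p.slot in active else 0)
    return handshakes, ts, pairs, labels


@pytest.fixture(scope="session")
def oracle_classifier(oracle_deployment):
    _, signals, truth = oracle_deployment
    handshakes, ts, pairs, labels = labelled_handshakes(signals, truth)
    return train_state_classifier(pairs, labels), handshakes, ts
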