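"""Deployment simulator: roster, schedules, event process, emission,
artifact injection, determinism."""

import numpy as np
import pytest
from scipy import stats

from proxinet.config import (ArtifactConfig, EventProcessConfig, FreeBlock,
                             SimulationConfig, small_config)
from proxinet.errors import IdSpaceError, ScheduleError
from proxinet.simulate import (emit_signals, inject_artifacts,
                               simulate_deployment, simulate_events,
                               simulate_population, simulate_schedule,
                               _HeavyTail)
from proxinet.types import SLOT_S, badge_kind, session_window

from conftest import KEY, prox_of, rx_of


class TestPopulation:
    def test_rx_coding_scheme(self):
        cfg = SimulationConfig(seed=3)
        roster = simulate_population(cfg)
        assert sorted(roster.rx.values()) == [f"200{c}" for c in range(1, 8)]
        assert roster.gym_rx == ("2010", "2011")
        kinds = {badge_kind(d) for d in roster.children}
        assert kinds == {"child"}
        assert {badge_kind(d) for d in roster.adults} == {"adult"}

    def test_zero_adults(self):
        cfg = small_config(n_adults=0)
        roster = simulate_population(cfg)
        assert not roster.adults
        assert {d[0] for d in roster.all_badges()} == {"0", "2"}

    def test_too_many_classes_rejected(self):
        with pytest.raises(IdSpaceError):
            simulate_population(SimulationConfig(
                n_classes=8, class_sizes=(5,) * 8))

    def test_same_seed_same_roster(self):
        cfg = small_config(seed=9)
        assert simulate_population(cfg) == simulate_population(cfg)


class TestSchedule:
    def test_template_classes_share_free_segments(self):
        cfg = small_config(seed=2, schedule_jitter_s=0)
        sched = simulate_schedule(cfg)
        segs = sched.segments[KEY]
        f1 = [(s.start, s.end) for s in segs[1] if s.label == "F"]
        f2 = [(s.start, s.end) for s in segs[2] if s.label == "F"]
        assert f1 == f2 and len(f1) == 2

    def test_no_free_blocks_gives_all_class_time(self):
        cfg = small_config(n_classes=2, seed=0)
        cfg.free_blocks = ()
        sched = simulate_schedule(cfg)
        for segs in sched.segments[KEY].values():
            assert [s.label for s in segs] == ["C"]

    def test_every_free_segment_shared_by_two_classes(self):
        # exhaustive interval-overlap oracle on jittered schedules
        for seed in range(5):
            sched = simulate_schedule(small_config(seed=seed))
            segs = sched.segments[KEY]
            for c, slist in segs.items():
                for s in (x for x in slist if x.label == "F"):
                    assert any(
                        o.label == "F" and o.start < s.end and s.start < o.end
                        for c2, ol in segs.items() if c2 != c for o in ol)

    def test_segments_tile_the_half_day(self):
        sched = simulate_schedule(small_config(seed=4))
        win = session_window(*KEY)
        for slist in sched.segments[KEY].values():
            assert slist[0].start == win.start
            assert slist[-1].end == win.end
            for a, b in zip(slist, slist[1:]):
                assert a.end == b.start

    def test_overlapping_blocks_rejected(self):
        cfg = small_config(n_classes=2, seed=0)
        cfg.free_blocks = (FreeBlock((1, 2), 1800, 3600),
                           FreeBlock((1, 2), 3000, 4800))
        with pytest.raises(ScheduleError):
            simulate_schedule(cfg)


class TestEvents:
    def test_zero_participation_gives_no_events(self):
        cfg = small_config(n_classes=2, class_size=3, seed=0)
        cfg.events.dyad_participation = 0.0
        roster = simulate_population(cfg)
        sched = simulate_schedule(cfg)
        truth = simulate_events(cfg, sched, roster)
        assert truth.events[KEY] == []
        assert truth.states[KEY] == {}

    def test_disjoint_free_times_forbid_cross_class_dyads(self):
        cfg = small_config(n_classes=4, class_size=4, seed=1)
        # classes 1/2 and 3/4 never share the yard in this template
        cfg.free_blocks = (FreeBlock((1, 2), 1800, 3600),
                           FreeBlock((3, 4), 4200, 6000))
        roster = simulate_population(cfg)
        sched = simulate_schedule(cfg)
        truth = simulate_events(cfg, sched, roster)
        cm = roster.class_map
        for i, j in truth.states[KEY]:
            groups = {frozenset({1, 2}), frozenset({3, 4})}
            assert frozenset({cm[i], cm[j]}) in groups \
                or cm[i] == cm[j]

    def test_events_and_states_mutually_consistent(self):
        cfg = small_config(seed=3)
        roster = simulate_population(cfg)
        truth = simulate_events(cfg, simulate_schedule(cfg), roster)
        by_dyad = {}
        for ev in truth.events[KEY]:
            assert ev.delta > 0 and ev.delta % SLOT_S == 0
            by_dyad.setdefault((ev.i, ev.j), []).append(ev)
        for dyad, evs in by_dyad.items():
            slots = np.concatenate([np.arange(e.t, e.t + e.delta, SLOT_S)
                                    for e in evs])
            assert np.array_equal(np.sort(slots), truth.states[KEY][dyad])
            evs.sort()
            for a, b in zip(evs, evs[1:]):  # non-overlap, positive gap
                assert b.t > a.t + a.delta

    def test_duration_tail_heavier_than_exponential(self):
        """Likelihood-ratio check at n=1e4: the duration family beats an
        exponential fit at matched mean."""
        rng = np.random.default_rng(0)
        cfg = EventProcessConfig()
        draws = _HeavyTail(cfg.duration_alpha,
                           cfg.duration_cutoff_slots).draw(rng, 10_000)
        lam = 1.0 / draws.mean()
        ll_exp = np.sum(np.log(lam) - lam * draws)
        pmf = _HeavyTail(cfg.duration_alpha, cfg.duration_cutoff_slots).pmf
        ll_heavy = np.sum(np.log(pmf[draws - 1]))
        assert ll_heavy > ll_exp
        # heavier tail: more mass far beyond the mean than exponential
        q = np.quantile(draws, 0.999)
        assert q > stats.expon(scale=draws.mean()).ppf(0.999)


class TestEmission:
    def test_full_packet_loss_gives_empty_logs(self):
        cfg = small_config(n_classes=2, class_size=3, seed=0,
                           packet_loss_prob=1.0)
        cfg.events.interference_rate_ph = 0.0
        roster = simulate_population(cfg)
        truth = simulate_events(cfg, simulate_schedule(cfg), roster)
        signals = emit_signals(truth, cfg)
        assert all(len(s) == 0 for s in signals[KEY].values())

    def test_isolated_always_active_dyad_two_records_per_slot(self):
        cfg = small_config(n_classes=2, class_size=1, n_adults=0, seed=0,
                           packet_loss_prob=0.0)
        cfg.free_blocks = (FreeBlock((1, 2), 0, 10200),)
        cfg.schedule_jitter_s = 0
        cfg.yard_proximity = 1.0
        cfg.events.interference_rate_ph = 0.0
        roster = simulate_population(cfg)
        sched = simulate_schedule(cfg)
        truth = simulate_events(cfg, sched, roster)
        # force the dyad continuously active
        win = session_window(*KEY)
        (i, j) = sorted(roster.children)
        slots = win.slots()
        truth.states[KEY] = {(i, j): slots}
        signals = emit_signals(truth, cfg)
        n = len(slots)
        assert len(signals[KEY][i]) == n and len(signals[KEY][j]) == n

    def test_active_rssi_matches_interaction_regime(self):
        """Monte-Carlo: mean observed RSSI on active slots within 3
        standard errors of the configured regime mean (n ~ 1e4)."""
        cfg = small_config(seed=6, packet_loss_prob=0.0)
        roster = simulate_population(cfg)
        truth = simulate_events(cfg, simulate_schedule(cfg), roster)
        signals = emit_signals(truth, cfg)
        reg = cfg.rssi_interaction
        vals = []
        for (i, j), active in truth.states[KEY].items():
            df = signals[KEY][j].data
            hit = (df.did.values == i) & np.isin(df.t.values, active)
            vals.append(df.rssi.values[hit])
        vals = np.concatenate(vals)
        a, b = (reg.lo - reg.mean) / reg.sd, (reg.hi - reg.mean) / reg.sd
        expected = stats.truncnorm.mean(a, b, loc=reg.mean, scale=reg.sd)
        se = vals.std() / np.sqrt(len(vals))
        assert len(vals) > 10_000
        assert abs(vals.mean() - expected) < 3 * se + 0.5  # integer rounding

    def test_rssi_never_below_sensitivity_floor(self):
        cfg = small_config(seed=8)
        signals, _ = simulate_deployment(cfg)
        for seq in signals[KEY].values():
            if len(seq):
                assert seq.data.rssi.min() >= -94
                assert seq.data.rssi.max() <= -16


class TestArtifacts:
    def test_zero_rates_change_nothing(self):
        cfg = small_config(n_classes=2, class_size=3, seed=1)
        cfg.artifacts = ArtifactConfig(unworn_prob=0, pile_prob=0,
                                       silent_prob=0, deaf_prob=0,
                                       edge_burst_prob=0)
        roster = simulate_population(cfg, 1)
        truth = simulate_events(cfg, simulate_schedule(cfg, 2), roster, 3)
        signals = emit_signals(truth, cfg, 4)
        out, truth2 = inject_artifacts(signals, truth, cfg, 5)
        assert all(out[KEY][d] == signals[KEY][d] for d in signals[KEY])
        assert truth2.artifacts[KEY] == []

    def _with_artifacts(self, seed=1):
        cfg = small_config(seed=seed)
        cfg.artifacts = ArtifactConfig(unworn_prob=0.3, pile_prob=0.3,
                                       silent_prob=0.1, deaf_prob=0.1,
                                       edge_burst_prob=0.5)
        signals, truth = simulate_deployment(cfg)
        return cfg, signals, truth

    def test_silent_badge_absent_from_peers_own_log_intact(self):
        cfg, signals, truth = self._with_artifacts()
        silents = [a.did for a in truth.artifacts[KEY] if a.cause == "silent"]
        assert silents, "seed produced no silent badge"
        for s in silents:
            assert len(signals[KEY][s]) > 0
            for other, seq in signals[KEY].items():
                if other != s:
                    assert s not in set(seq.data.did)

    def test_deaf_badge_log_empty_but_heard(self):
        cfg, signals, truth = self._with_artifacts(seed=3)
        deafs = [a.did for a in truth.artifacts[KEY] if a.cause == "deaf"]
        assert deafs, "seed produced no deaf badge"
        for d in deafs:
            assert len(signals[KEY][d]) == 0
            assert any(d in set(seq.data.did)
                       for o, seq in signals[KEY].items() if o != d)

    def test_unworn_interval_shows_flagged_window_statistics(self):
        """Recomputed 3-min window stats inside injected unworn
        intervals fall in the flagged (mean >= -62, STD <= 2.5) region
        for at least 95% of complete windows."""
        flagged = total = 0
        for seed in (1, 2, 4, 6):
            cfg, signals, truth = self._with_artifacts(seed)
            rxs = rx_of(signals)
            for a in truth.artifacts[KEY]:
                if a.cause != "issue2":
                    continue
                cls = truth.roster.class_map[a.did]
                df = rxs[cls].data
                for w0 in range(a.start, a.end - 180 + 1, 60):
                    sel = df[(df.did == a.did) & (df.t >= w0)
                             & (df.t < w0 + 180)]
                    if len(sel) < 29:
                        continue
                    total += 1
                    flagged += (sel.rssi.mean() >= -62
                                and sel.rssi.std(ddof=0) <= 2.5)
        assert total > 10
        assert flagged / total >= 0.95

    def test_edge_bursts_include_strong_signals(self):
        cfg, signals, truth = self._with_artifacts()
        bursts = [a for a in truth.artifacts[KEY] if a.cause == "issue4"]
        assert bursts
        strong = 0
        for a in bursts:
            df = signals[KEY][a.did].data
            sel = df[(df.t >= a.start) & (df.t < a.end)]
            strong += (sel.rssi > -45).any()
        assert strong / len(bursts) > 0.9


class TestDeterminism:
    def test_same_seed_bit_identical_outputs(self):
        a_sig, a_truth = simulate_deployment(small_config(seed=12))
        b_sig, b_truth = simulate_deployment(small_config(seed=12))
        assert sorted(a_sig[KEY]) == sorted(b_sig[KEY])
        for d in a_sig[KEY]:
            assert a_sig[KEY][d] == b_sig[KEY][d]
        assert a_truth.events[KEY] == b_truth.events[KEY]

    def test_loss_free_mutual_observations_reproduce_truth(self,
                                                           oracle_deployment):
        """With zero loss and no artifacts, per-slot mutual observations
        at interaction strength recover true states exactly (end-to-end
        generator oracle)."""
        cfg, signals, truth = oracle_deployment
        prox = prox_of(signals)
        for (i, j), active in truth.states[KEY].items():
            df = prox[i].data
            got = np.sort(df.t.values[(df.did.values == j)
                                      & (df.rssi.values >= -63)])
            assert np.array_equal(got, active)
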