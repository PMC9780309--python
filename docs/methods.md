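# Methods

## The measurement model

A worn badge broadcasts a packet every 5 seconds and logs every packet
it receives as *(observed DID, timestamp, RSSI)*. RSSI (dBm, more
negative = weaker) is a noisy proxy for distance and relative
orientation: close face-to-face interaction gives strong signals,
co-presence in the same room gives weak ones, and badges piled within
centimetres give very strong, very stable ones. Nothing below the
−94 dBm sensitivity floor is ever recorded; cleaned data span −93 to
−16 dBm. Timestamps count seconds from a project reference midnight;
half-day sessions run 08:30–11:20 and 13:45–15:50 (no Wednesday
afternoon, nine half-days per week).

All downstream inference rests on one idea: a *real* interaction is a
run of strong, mutually observed packets, while the many failure modes
of a fleet of badges (unworn devices, piles, gathered bursts, silent or
deaf radios, packet loss, interference) leave signatures that are
separable in window statistics of the RSSI stream.

## Pre-processing: the four issue corrections

Applied strictly in order, each consuming the previous stage's output:

1. **Silent/deaf repair.** A silent badge receives but is never heard;
   a deaf badge is heard but recorded nothing. Radio links are treated
   as approximately reciprocal, so the intact direction is copied with
   sender/receiver reversed. A badge with neither direction is
   unrecoverable and left empty (flagged).
2. **Unworn near the hub.** The stationary class RX sits on the
   charging hub; an unworn badge left there reaches it strongly and
   stably. Sliding 3-minute windows, stepped by 1 minute, over the RX's
   per-badge stream flag mean ≥ −62 dBm and population SD ≤ 2.5.
   Windows holding fewer than ⌈0.8 × 36⌉ = 29 of the expected beacons
   are not trusted (the badge was out of the room).
3. **Piles away from the hub.** Same windowing on each badge's own log,
   per observed peer, with the stricter thresholds mean ≥ −55 dBm and
   SD ≤ 1.5 — deliberately conservative so genuine close face-to-face
   contact (strong but *unstable*, children never stand still) is never
   deleted.
4. **Edge bursts.** Gathered badges at equipment/retrieval exchange
   very strong (> −45 dBm) unstable signals at the clip edges. From the
   first timestamp, strong records inside a 1-minute window set the
   strong-signal time t_s; past the window t_s only advances when a new
   strong record lies within 20 s of it; the head [t₀, t_s] is
   deleted. Mirrored from the last timestamp for the tail. If the
   initial window holds no strong record the edge is untouched.

Flagged intervals from (2) and (3) are bridged when separated by less
than 120 s, padded by a 30 s safety margin, and all removals are
bidirectional (the badge's own records and its appearances in peers'
logs). The margin is applied once, as part of deletion: re-applying the
consolidation to its own output would stack margins and re-merge across
the shrunken gaps, so the operation is deliberately not a fixpoint —
only the bridge/merge stage is (tested at margin 0).

## Interaction inference

*Handshake pairs*: mutual observations with both RSSIs ≥ −93 dBm
matched greedily by nearest timestamp within ±2.5 s, each record used
once, one pair per 5-s slot. *Classification*: L2-regularised logistic
regression on the two directed RSSIs (an absent direction is imputed at
the −93 dBm floor); interaction probability must be non-decreasing in
each RSSI — when near-collinear separable features drive one
coefficient negative, the model refits on the symmetric mean-RSSI
feature. Probability 0.5 resolves to non-interaction. *Reconstruction*:

- **naive** — a maximal run of non-1 slots (explicit 0s and missing
  slots alike; packet loss is what merging exists to bridge) no longer
  than the gap threshold between two 1-states is rewritten to 1.
  Default gap 6 slots = 30 s; gap 0 is the unreconstructed sequence.
- **hmm** — a 2-hidden-state Gaussian HMM over (trailing 3-slot mean
  RSSI, classifier probability), Viterbi-decoded; the state with the
  higher mean probability feature is "interaction".
- **bilstm** — an optional bidirectional recurrent labeler (uses both
  past and future context); it requires pytorch and reports a
  capability error when that optional dependency is absent. The core
  pipeline never requires it.

Maximal runs of grid-adjacent 1-slots become events θ = (t, i, j, δ).
Accuracy is the per-slot agreement over the truth grid, reported both
pooled over slots and averaged per dyad (the two conventions differ
when dyads have unequal observation spans).

On the synthetic calibration below the classifier is already accurate
per slot, so gap-merging mainly trades recovery of loss-hidden slots
against bridging true short gaps; field data with heavier classifier
noise is where the reconstruction routes pay off. Neither the printed
accuracies of any particular deployment nor their ordering is a target
of this package's tests.

## Free-/class-time segmentation

Children in class interact with classmates only; in the shared yard
they mix across classes. Per class and 10-s bin, the package counts
active child-dyad states that cross class lines (*inter*, credited to
both classes) and those inside the class (*intra*); adults are
excluded. Both series are smoothed with a normalised Gaussian kernel
(σ = 3 bins, reflected boundaries) before division; a zero smoothed
intra count yields the default ratio 2 × threshold (no classroom signal
reads as "out"). Bins at or above the ratio threshold are free-time
candidates; runs of either label shorter than the gap threshold are
absorbed by their neighbours (sub-gap class-time runs inside free time
first, then the reverse — within a phase the result is
order-independent). Defaults: ratio 0.15, gap 600 s.

The alignment correction intersects each class's detected free time
with the instants where at least two classes were detected free
(computed simultaneously against the unaligned input). This clips the
first class into the yard to the second arrival and the last out to the
second departure, relabels lone-class "free" periods (a class on the
move through corridors), and guarantees every retained free instant is
shared — a guarantee pure edge-clipping does not give.

The error of a segmentation against a reference is the measure of the
symmetric difference of the free-time sets, computed interval-wise:
for overlapping period pairs this is τ_pred + τ_true − 2·τ_overlap, and
completely unmatched periods contribute their whole duration. It is
symmetric, non-negative, and zero iff the free-time sets coincide. The
grid search evaluates every (ratio, gap) cell, breaking ties toward the
smaller gap and then the smaller ratio.

Event annotation reads each member's label at the event start and end —
half-open segments, an instant on a boundary belongs to the later
segment, the session end to the last — producing the `SSSSX` string
(e.g. `FCFC1`: classmates who started in the yard and ended in class).

## Summary arithmetic

Share percentages are rounded half-up to 2 decimals; second→hour
conversions round to the nearest whole hour. The package bundles the
published per-label count/duration totals of a year-long preschool
deployment (19 label types, `data/annotation_totals.csv`) as the
reference input for this arithmetic; all percentages and hours are
recomputed at run time, never stored.

## The deployment simulator

The generator emulates what badges measure, not why people move:

- **Roster** — children 0xxx, adults 1xxx, one RX per class (2001…2007)
  plus gym RXs 2010/2011; defaults are deployment scale (7 classes of
  24, 32 staff).
- **Schedule** — a free-block template (groups of 2–4 classes
  successively in the yard) with per-class entry/exit jitter up to
  60 s. Blocks may carry a *lull* (classes regroup apart mid-recess —
  still free time, but no cross-class co-location) and a per-block
  *mixing* intensity (class-group pairs differ in how much they
  mingle).
- **Contact process** — per eligible dyad (same class any time;
  cross-class only while both classes share the yard outside lulls),
  a thinning participation probability (0.55 within class, ×0.15 for
  cross-class pairs, ×0.3 per adult member) followed by alternating
  heavy-tailed draws: discrete power laws with exponential cutoff,
  durations k^−2.2·e^(−k/240), gaps k^−1.7·e^(−k/600) in 5-s slots.
  This produces the bursty event trains and fat-tailed duration/IET
  distributions characteristic of face-to-face contact data, with a
  non-trivial share of true gaps near the 30-s merge scale.
  Eligibility is shaved 120 s at session edges (children being equipped
  are not interacting).
- **Emission** — per slot, each co-located dyad exchanges two directed
  records; RSSI regimes are truncated normals on the integer dBm grid:
  interaction −68 ± 6 (bounds −92…−50), room background −82 ± 6
  (−94…−60), gathered ≤10 cm −50 ± 5 (−60…−30), in-the-box burst
  −46 ± 5, unworn-on-hub −58 ± 1.5 (−62…−50), pile −52 ± 1.2
  (−55…−48). Only the ordering of these regimes is externally
  constrained (box-plot level evidence); the parameters are declared
  calibration defaults. Each direction is independently lost with
  probability 0.1. In the (large) yard a non-interacting pair is in
  radio range only 35% of slots; classrooms are small enough that
  everyone hears everyone, and the class RX logs all badges in its
  room. *Interference*: occasional fake strong cross-class exchanges
  (0.2 per non-co-located pair per hour at deployment scale) model
  corridor passings and radio artifacts — the false signals that
  reconstruction and segmentation must tolerate.
- **Artifacts** — per badge per half-day: unworn-near-hub (p = 0.08,
  900 s on the hub with the strong/stable RX signature), piles
  (p = 0.05, pairs, 900 s), silent (0.02) and deaf (0.02) badges, and
  edge bursts (participation 0.3 per badge, 60 s at each session edge).
  Artifact intervals erase the badge's true contacts there (an unworn
  badge cannot interact; truth and signals are adjusted together) and
  are recorded in the truth bundle.

Everything is driven by one seed (stage seeds are spawned from it);
outputs are bit-identical across runs.

### What the simulator does and does not capture

It reproduces the *signatures* each pipeline stage keys on — regime
ordering, window statistics, completeness drops when children leave the
room, schedule-driven co-location, burstiness — under full ground
truth. It does not model space continuously (co-location is room- and
block-level plus a Bernoulli yard-range thinning), orientation
(folded into regime dispersion), acoustics, or radio propagation, and
badge-to-badge reciprocity is exact up to independent draws. Passing
tests therefore demonstrate correctness of the algorithms under the
stated measurement model, not field performance on any particular real
deployment.

### Scaled study conditions

Tests and the acceptance script run scaled deployments (one morning;
4 classes of 6 for signal-level checks, 4 classes of 12 for
segmentation, since very small classes make the intra-class count
series too bursty for a meaningful ratio; the interference rate is
rescaled to 0.35/pair/h there so the class-time ratio noise floor sits
near 0.07, between floor and plateau as at full scale). The
segmentation template realises an effective decision boundary at ratio
0.15 and gap 600 s: a 540-s mixing lull (defeats gap 450), a 700-s
in-class interlude between two yard blocks (defeats gap 750), a
low-mixing block with plateau near 0.25–0.3 (defeats ratio 0.25), and
a class-time noise floor near 0.07 (defeats ratio 0.05).

## Numerical conventions

- Intervals are half-open [start, end) everywhere; edge-burst trims
  include their boundary strong signal.
- Population (divide-by-n) standard deviation in window statistics.
- Duplicate (observed DID, timestamp) rows keep the strongest RSSI.
- Ties: classifier probability 0.5 → no interaction; grid-search ties →
  smaller gap, then smaller ratio; canonical dyad order is the smaller
  DID first.
- Window flags are unioned into intervals (no voting between
  overlapping windows): the conservative reading for data deletion.
- Removals for issues 3 and 4 are bidirectional like the others; the
  repair stage is the only stage that ever adds records, and those are
  mirrored copies.

## Known limitations

- The handshake matcher is greedy by nearest timestamp; with jitter
  beyond ±2.5 s/2 it can in principle differ from a maximum matching
  (not reachable at the 5-s emission spacing with realistic clock
  skew).
- The HMM's "short-term envelope" is a trailing 3-slot feature window;
  other envelope definitions are plausible.
- Gym-session detection via RX-2010/2011 is out of scope; the gym RXs
  exist in the roster only.
- The BiLSTM path is untested in environments without pytorch.
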