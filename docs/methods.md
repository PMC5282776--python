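# Methods

## Scope and shape

`wardwatch` models a ward hand-hygiene (HH) monitoring information system
as five cooperating layers: a spatial ward model (`ward_layout`), a
behavioural shift simulator (`simulator`), proximity-log processing
(`event_processing`), WHO five-moments compliance inference (`moments`) and
a gamification engine (`gamification`), orchestrated batch-per-shift by
`pipeline`/`cli`.  Rendering (web/app UI), hardware integration and
delivery channels (SMTP, analytics) are out of scope: the package emits
structured payloads only.

## Ward model

Rooms are rectangles with room-local coordinates in metres, origin at the
door corner; the default ward is a three-room ICU (one four-bed room,
8×6 m; two two-bed rooms, 5×6 m) equipped per room with one sink, one
dispenser at the entrance and one at each bed's foot, plus one beacon per
facility and one at a central point — 25 beacons in all.  Room dimensions
are modelling choices (they matter only to the RSSI channel); facility
identity and room membership are what the rules consume.  Every interval is
half-open `[start, end)` in seconds from shift start; serialised timestamps
are timezone-naive ISO-8601, and a shift never crosses midnight.

## Behavioural simulator

A nurse's shift is an alternating renewal process: patient-care visits at
one of her assigned beds (duration 120 s + Exp(480 s), mean 10 min) and
general-area work near the room centre (mean ≈ 5 min), with corridor walks
between rooms.  Visits open a moment-1 opportunity at bed-zone entry and a
moment-4-or-5 at exit; the exit is a moment 4 (patient touched) with
probability mix₄/(mix₄+mix₅) = 0.75.  Care steps inside the zone create
moment-2/3 opportunities at rate (mix₂+mix₃)/mix₁ = 0.5 per visit,
flagged `detectable=False`: they involve no change of location and no
proximity system can see them.  With the default mix
(0.40/0.10/0.10/0.30/0.10) moments 1/4/5 are 80 % of all opportunities in
expectation, matching the ratio reported across observational studies.

**Compliance draw.**  The linking rules make any action performed between
two visits count for *both* the exit moment it follows and the entry moment
it precedes (one rub between patients covers "after patient A" and "before
patient B").  Independent per-opportunity coin flips are therefore
unrealisable: an action satisfying the exit moment necessarily also lies in
the following entry moment's window.  The generator instead draws one
Bernoulli(`compliance_prob`, default 0.698 — the ward baseline reported by
direct observation) per inter-visit gap and, on success, emits exactly one
action in that gap (a sink wash, Uniform(40, 60) s, with probability
`p_wash` = 0.15, else a dispenser rub with an acquisition dwell of
Uniform(4, 10) s and a rub of Uniform(20, 30) s).  Marginal per-opportunity
compliance equals `compliance_prob` exactly; the two opportunities sharing
a gap are perfectly correlated, which roughly doubles the variance of a
pooled estimate relative to a pure binomial — tests and tolerances account
for this.  Moment-2/3 draws are independent; a complied one is a quick rub
at the bed-foot dispenser without leaving the bed zone, so it splits the
bed dwell by less than the 10 s re-entry grace and is invisible to the
opportunity detector, as intended.  Because ground-truth complied flags are
constructed to coincide with what the business rules later score, the
noiseless pipeline recovers compliance without bias; this is a designed
property, verified end to end.

**Randomness.** All draws descend from one seed through named substreams
(trajectory, compliance, noise, RSSI) keyed per nurse, so any component can
be re-run reproducibly in isolation.

**Sensing noise.** The message channel drops each message with
`p_missed_msg` (0.05), duplicates it with `p_duplicate_msg` (0.1) and adds
Poisson interference copies so the expected emitted/ideal ratio equals
`msg_rate_multiplier` (1.5 — the deployed hardware sent far more messages
than the one-approach-one-leave contract, with no visible pattern).  Ghost
approach/leave pairs arrive at `p_ghost_msg_per_hour` (0.2) from beacons in
rooms the wearer never entered, mirroring the observed field failure.  The
RSSI channel is log-distance path loss, `rssi = A − 10·n·log10(max(d, d₀))
+ ε`, with A = −60 dBm at 1 m, n = 2.0, d₀ = 0.1 m and shadowing
σ = 4 dB — chosen so that a single-sample distance estimate at a few metres
errs on the order of the ~2 m error seen in hardware trials; a calibration
constant, not a claim.

**What the simulator does not emulate:** multi-tag radio interference,
battery decay, continuous-space movement between facilities, shift
hand-overs, or nurses deviating from their bed assignment.  Passing tests
therefore demonstrate correctness of the *rules and plumbing* under a
plausible behavioural model, not field accuracy of any particular radio
hardware.

## Event processing

Message pairing is robust by contract: duplicate APPROACHes inside an open
dwell are ignored, orphan LEAVEs dropped, dangling APPROACHes closed at
shift end — all counted and logged.  Denoising merges per-beacon intervals
separated by less than 2 s, drops intervals shorter than 1 s (both sit
below the smallest meaningful threshold, 4 s, so they can never mask a
dispenser visit) and resolves physically impossible cross-room overlaps by
keeping the longer dwell; on equal durations the beacon seen most recently
wins, then the earlier start, then the beacon id — a total order, making
the operation deterministic and idempotent.  Dwell-time validation is
inclusive ("registered after 40 s" is read as *once 40 s have elapsed*):
sink ≥ 40 s → wash visit, dispenser ≥ 4 s → rub visit, stamped at the dwell
end (hands are clean when the worker steps away); zones emit enter/exit at
face value.  RSSI dwell detection uses a centred 5-sample median with
−70/−75 dBm enter/exit hysteresis (no values were reported for the
original; these hold the dwell through ~1 s fades at the boundary).

## Moments engine

Only bed zones define opportunities; central/entrance zones are general
area.  Re-entering the same bed within 10 s is beacon flicker, merged into
one visit.  Windows: moment 1 at entry e is complied by an action in
`(previous exit, e]` (optionally bounded by `pre_entry_window_s`, default
unbounded — whether a wash long before entry "still counts" is genuinely
open; the unbounded reading is the default and the bound is exposed);
merged moment 4/5 at exit x by an action in `(x, x+120]` and not after the
next entry.  120 s exceeds the longest action (60 s wash) plus walking
time.  An action may serve at most one exit moment and one entry moment;
assignment is greedy in time order, which for well-formed alternating
visits coincides with per-window existence.  Actions performed *inside* a
bed zone (mid-care rubs) are detected but linked to nothing: counting them
toward the surrounding boundary moments would inflate recovered compliance.
Compliance is an exact rational; zero opportunities yield an explicit
undefined marker, never 0 or 1.  Moment 4 vs 5 cannot be inferred from
proximity; an optional dwell-length heuristic (`≥ 120 s → moment 4`) exists
for evaluation against ground truth only.

## Gamification

Only ordinal properties were prescribed: levels convex, badge tier 1 after
one qualifying shift and tier 2 after ten, harder badges worth more
currency, the gate *strictly above* 70 %.  The concrete defaults — 10
points per complied moment, 50-point win bonus, T(L) = 100·L·(L+1)/2, tier
ladder [1, 10, 25, 50], currency rewards rising per tier, shop prices
25–60 — are configuration, not findings.  The leaderboard ranks lifetime
points (persistent progression, not last shift score), ties going to the
player who needed fewer opportunities; it is partial — rank and movement
only, adjacent ranks visible only to owners of the corresponding shop item.
Win-state ties are shared.  Scores round half-up to one decimal.  E-mail
payloads carry the player's own rate and an opaque stats-link token and
never reference another player.

## Problem sizes and numerics

The shipped checks use 200 simulated shifts for the moment-mix structure
(pooled n ≈ 60 000 opportunities; the 1/4/5 share has a standard error of
about 0.2 pp) and 100 noiseless shifts for end-to-end compliance recovery
(pooled n ≈ 25 000; estimator sd ≈ 0.5 pp including the within-gap
correlation), sizes at which both statistics are far inside their
tolerances while the whole acceptance script completes in seconds.
Floating-point time comparisons use exact arithmetic on the shared
timestamps the simulator emits; thresholds are inclusive everywhere, and
ties in the denoiser and leaderboard are broken by documented total orders
so every pipeline output is byte-reproducible from (layout, config, seed).

## Known limitations

Dispenser dwells shorter than 4 s are invisible by design, so a real nurse
grabbing product in 2 s would be scored non-compliant; the simulator
accordingly draws acquisition dwells ≥ 4 s.  The room-consistency filter
assumes ghost dwells are shorter than the true dwell they overlap; a ghost
outlasting a real visit would displace it.  Compliance recovery is unbiased
only because ground truth and rules share the same window semantics; with
sensing noise enabled, missed messages bias compliance downward (lost
dwells become missed opportunities and actions), which
`evaluate_against_truth` quantifies as sensitivity, spurious counts and
rate bias rather than hiding it.
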