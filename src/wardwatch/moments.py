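"""WHO "five moments" business rules: opportunities, linking, compliance.

A proximity system sees only *changes of location*, so of the WHO five
moments for hand hygiene it can detect exactly three: before touching a
patient (moment 1, a transition from the general healthcare area into a
patient zone), after touching a patient (moment 4) and after touching
patient surroundings (moment 5) — both of the latter being transitions out
of a patient zone.  Moments 2 and 3 happen *inside* the patient zone with
no change of location and are structurally invisible; they are never
emitted by the inference path.  Moments 4 and 5 cannot be told apart from
proximity alone, so the engine emits a merged moment-4/5 at every patient-
zone exit (an optional dwell-time heuristic can relabel it, for evaluation
only).

Compliance is the ratio of complied moments to occurred moments.  A moment
is complied when a validated hygiene action falls inside its linking
window: for an entry moment, any action since the previous patient-zone
exit; for an exit moment, an action within a short window after the exit
and before the next patient-zone entry.  One action performed between two
patient-zone visits therefore satisfies both the exit it follows and the
entry it precedes — the standard reading of the WHO framework.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

from .event_processing import (
    HYGIENE_STATION_VISIT,
    ZONE_ENTER,
    ZONE_EXIT,
    LocationEvent,
)
from .ward_layout import FacilityKind

logger = logging.getLogger(__name__)

__all__ = [
    "Moment",
    "HHAction",
    "HHOpportunity",
    "ShiftSummary",
    "ConfusionReport",
    "DEFAULT_REENTRY_GRACE_S",
    "DEFAULT_POST_EXIT_WINDOW_S",
    "actions_from_events",
    "detect_opportunities",
    "link_actions",
    "compliance_rate",
    "summarize_shift",
    "evaluate_against_truth",
    "heuristic_touch_label",
]

DEFAULT_REENTRY_GRACE_S = 10.0
DEFAULT_POST_EXIT_WINDOW_S = 120.0
DEFAULT_MATCH_TOLERANCE_S = 30.0

WASH = "WASH"
RUB = "RUB"


class Moment(str, enum.Enum):
    """WHO moment label.  M45 is the merged, proximity-detectable 4-or-5."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"
    M5 = "M5"
    M45 = "M45_MERGED"

    @property
    def is_exit_moment(self) -> bool:
        return self in (Moment.M4, Moment.M5, Moment.M45)


@dataclass(frozen=True)
class HHAction:
    """A validated hand-hygiene action (wash at a sink, rub from a dispenser)."""

    tag_id: str
    kind: str  # WASH | RUB
    time: float  # action completion time, s from shift start
    duration_s: float
    station_id: str


@dataclass
class HHOpportunity:
    """One indication for hand hygiene, complied or not."""

    tag_id: str
    moment: Moment
    time: float
    zone_id: str  # the bed defining the patient zone
    complied: bool = False
    linked_action: HHAction | None = None
    detectable: bool = True  # False for ground-truth moments 2/3


@dataclass
class ShiftSummary:
    tag_id: str
    n_opportunities: int
    n_complied: int
    n_actions: int
    compliance_rate: float | None  # None = undefined (no opportunities)
    per_hour: list[tuple[int, int]]  # (opportunities, complied) per shift hour
    last_position: str | None  # facility id of the last detection


@dataclass
class ConfusionReport:
    """Inference quality against ground truth, detectable moments only."""

    n_truth_detectable: int
    n_detected: int
    n_missed: int
    n_spurious: int
    sensitivity: float | None
    truth_compliance: float | None
    inferred_compliance: float | None
    compliance_bias: float | None


# ---------------------------------------------------------------------------
# Actions from validated events
# ---------------------------------------------------------------------------


def actions_from_events(events: Sequence[LocationEvent]) -> list[HHAction]:
    """Hygiene-station visits become actions: sink → wash, dispenser → rub.

    The recorded duration is the station dwell, which for a wash is the
    wash itself and for a rub is only the product acquisition (the rub is
    performed walking away); duration is a proxy, technique is not assessed.
    """
    actions = []
    for e in events:
        if e.kind == HYGIENE_STATION_VISIT:
            kind = WASH if e.facility.kind == FacilityKind.SINK else RUB
            actions.append(HHAction(e.tag_id, kind, e.time, e.dwell_s, e.facility.id))
    return actions


# ---------------------------------------------------------------------------
# Opportunity detection
# ---------------------------------------------------------------------------


def detect_opportunities(
    events: Sequence[LocationEvent],
    reentry_grace_s: float = DEFAULT_REENTRY_GRACE_S,
    counters: dict | None = None,
) -> list[HHOpportunity]:
    """Patient-zone transitions become an uncomplied opportunity skeleton.

    Each transition from the general healthcare area into a bed zone emits
    a moment 1 at the entry time; each transition out emits a merged
    moment 4/5 at the exit time.  A re-entry into the *same* bed within
    ``reentry_grace_s`` of leaving it is beacon flicker, not a new visit,
    and is merged.  Events must be time-sorted per tag.  Truncated logs
    (exit without entry, entry never closed) are handled leniently and
    counted under ``counters``.
    """
    stats = {"orphan_exits": 0, "duplicate_enters": 0, "unclosed_visits": 0}
    by_tag: dict[str, list[LocationEvent]] = {}
    last_t: dict[str, float] = {}
    for e in events:
        if e.time < last_t.get(e.tag_id, float("-inf")):
            raise ValueError(f"events out of order for tag {e.tag_id!r} at t={e.time}")
        last_t[e.tag_id] = e.time
        if e.facility.kind == FacilityKind.BED and e.kind in (ZONE_ENTER, ZONE_EXIT):
            by_tag.setdefault(e.tag_id, []).append(e)

    opps: list[HHOpportunity] = []
    for tag, evs in by_tag.items():
        # visits: (zone_id, entry or None, exit)
        visits: list[list] = []
        open_visit: list | None = None  # [zone_id, entry]
        for e in evs:
            if e.kind == ZONE_ENTER:
                if open_visit is not None:
                    if open_visit[0] == e.facility.id:
                        stats["duplicate_enters"] += 1
                        continue
                    # different bed while one open: close the old visit here
                    stats["unclosed_visits"] += 1
                    visits.append([open_visit[0], open_visit[1], e.time])
                if (
                    visits
                    and visits[-1][0] == e.facility.id
                    and e.time - visits[-1][2] < reentry_grace_s
                ):
                    open_visit = [visits[-1][0], visits[-1][1]]
                    visits.pop()  # resume the flickered visit
                else:
                    open_visit = [e.facility.id, e.time]
            else:  # ZONE_EXIT
                if open_visit is not None and open_visit[0] == e.facility.id:
                    visits.append([open_visit[0], open_visit[1], e.time])
                    open_visit = None
                else:
                    stats["orphan_exits"] += 1
                    visits.append([e.facility.id, None, e.time])
        if open_visit is not None:
            stats["unclosed_visits"] += 1
            visits.append([open_visit[0], open_visit[1], evs[-1].time])

        for zone_id, entry, exit_ in visits:
            if entry is not None:
                opps.append(HHOpportunity(tag, Moment.M1, entry, zone_id))
            opps.append(HHOpportunity(tag, Moment.M45, exit_, zone_id))

    if any(stats.values()):
        logger.info("opportunity detection anomalies: %s", stats)
    if counters is not None:
        for k, v in stats.items():
            counters[k] = counters.get(k, 0) + v
    opps.sort(key=lambda o: (o.tag_id, o.time, o.moment.value))
    return opps


# ---------------------------------------------------------------------------
# Linking actions to opportunities
# ---------------------------------------------------------------------------


def link_actions(
    opps: Sequence[HHOpportunity],
    actions: Sequence[HHAction],
    pre_entry_window_s: float | None = None,
    post_exit_window_s: float = DEFAULT_POST_EXIT_WINDOW_S,
) -> list[HHOpportunity]:
    """Resolve compliance by linking actions to opportunity windows.

    * an entry moment at time *e* is complied iff some action lies in
      ``(previous patient-zone exit (or -inf), e]`` — optionally further
      bounded below by ``e - pre_entry_window_s``;
    * an exit moment at time *x* is complied iff some action lies in
      ``(x, x + post_exit_window_s]`` and not after the next patient-zone
      entry.

    One action between two visits may satisfy both the preceding exit
    moment and the following entry moment, but no action ever serves two
    exit moments or two entry moments; assignment is greedy in time order
    (earliest eligible unused action first).
    """
    out: list[HHOpportunity] = []
    by_tag: dict[str, list[HHOpportunity]] = {}
    for o in opps:
        by_tag.setdefault(o.tag_id, []).append(o)
    acts_by_tag: dict[str, list[HHAction]] = {}
    for a in sorted(actions, key=lambda a: a.time):
        acts_by_tag.setdefault(a.tag_id, []).append(a)

    for tag, os_ in by_tag.items():
        os_ = sorted(os_, key=lambda o: (o.time, o.moment.value))
        acts = acts_by_tag.get(tag, [])
        entry_times = [o.time for o in os_ if o.moment == Moment.M1]
        exit_times = [o.time for o in os_ if o.moment.is_exit_moment]
        used_for_entry: set[int] = set()
        used_for_exit: set[int] = set()
        for o in os_:
            if o.moment == Moment.M1:
                prev_exits = [t for t in exit_times if t < o.time]
                lo = max(prev_exits) if prev_exits else float("-inf")
                if pre_entry_window_s is not None:
                    lo = max(lo, o.time - pre_entry_window_s)
                hi = o.time
                pool = used_for_entry
            else:
                lo = o.time
                next_entries = [t for t in entry_times if t > o.time]
                hi = o.time + post_exit_window_s
                if next_entries:
                    hi = min(hi, next_entries[0])
                pool = used_for_exit
            chosen = None
            for i, a in enumerate(acts):
                if i in pool:
                    continue
                if lo < a.time <= hi:
                    chosen = i
                    break
            if chosen is not None:
                pool.add(chosen)
                out.append(replace(o, complied=True, linked_action=acts[chosen]))
            else:
                out.append(replace(o, complied=False, linked_action=None))
    out.sort(key=lambda o: (o.tag_id, o.time, o.moment.value))
    return out


# ---------------------------------------------------------------------------
# Compliance
# ---------------------------------------------------------------------------


def compliance_rate(n_complied: int, n_opportunities: int) -> Fraction | None:
    """Complied moments over occurred moments, exact; None when undefined.

    An empty shift has *undefined* compliance — never 0 or 1.
    """
    if n_complied < 0 or n_opportunities < 0:
        raise ValueError("counts must be non-negative")
    if n_complied > n_opportunities:
        raise ValueError(
            f"complied count {n_complied} exceeds opportunity count {n_opportunities}"
        )
    if n_opportunities == 0:
        return None
    return Fraction(n_complied, n_opportunities)


def summarize_shift(
    opps: Sequence[HHOpportunity],
    events: Sequence[LocationEvent],
    shift_hours: int | None = None,
) -> ShiftSummary:
    """Totals, rate, hourly breakdown and last detected position for one tag."""
    tags = {o.tag_id for o in opps} | {e.tag_id for e in events}
    if len(tags) > 1:
        raise ValueError(f"summarize_shift expects a single tag, got {sorted(tags)}")
    tag = tags.pop() if tags else ""

    n_opps = len(opps)
    n_complied = sum(1 for o in opps if o.complied)
    n_actions = sum(1 for e in events if e.kind == HYGIENE_STATION_VISIT)
    rate = compliance_rate(n_complied, n_opps)

    max_t = max(
        [o.time for o in opps] + [e.time for e in events], default=0.0
    )
    n_hours = shift_hours if shift_hours is not None else max(int(max_t // 3600) + 1, 1)
    per_hour = []
    for h in range(n_hours):
        in_bucket = [o for o in opps if h * 3600 <= o.time < (h + 1) * 3600]
        per_hour.append((len(in_bucket), sum(1 for o in in_bucket if o.complied)))
    # anything past the nominal last hour lands in the final bucket
    overflow = [o for o in opps if o.time >= n_hours * 3600]
    if overflow and per_hour:
        last = per_hour[-1]
        per_hour[-1] = (
            last[0] + len(overflow),
            last[1] + sum(1 for o in overflow if o.complied),
        )

    last_position = None
    if events:
        last_position = max(events, key=lambda e: e.time).facility.id

    return ShiftSummary(
        tag_id=tag,
        n_opportunities=n_opps,
        n_complied=n_complied,
        n_actions=n_actions,
        compliance_rate=float(rate) if rate is not None else None,
        per_hour=per_hour,
        last_position=last_position,
    )


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------


def heuristic_touch_label(opp: HHOpportunity, theta_touch_s: float = 120.0,
                          visit_duration_s: float | None = None) -> Moment:
    """Optional moment 4 vs 5 guess: long bed dwell suggests patient contact.

    Purely for evaluation against ground truth; the inference path always
    reports the merged moment.
    """
    if not opp.moment.is_exit_moment:
        return opp.moment
    if visit_duration_s is not None and visit_duration_s >= theta_touch_s:
        return Moment.M4
    return Moment.M5


def _rate(opps: Sequence[HHOpportunity]) -> float | None:
    r = compliance_rate(sum(1 for o in opps if o.complied), len(opps))
    return float(r) if r is not None else None


def evaluate_against_truth(
    inferred: Sequence[HHOpportunity],
    truth,
    tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
) -> ConfusionReport:
    """Match inferred opportunities to ground truth and report sensitivity.

    ``truth`` is anything with an ``opportunities`` attribute (one tag's
    ground truth) or a plain sequence of ground-truth opportunities.
    Matching pairs an inferred opportunity with a truth opportunity of the
    same tag, same bed zone and compatible moment (entry with entry, exit
    with exit) at the nearest time within ``tolerance_s``.  Sensitivity is
    restricted to the detectable moments 1, 4 and 5.
    """
    truth_opps = list(getattr(truth, "opportunities", truth))
    detectable = [o for o in truth_opps
                  if o.detectable and o.moment not in (Moment.M2, Moment.M3)]

    matched_truth: set[int] = set()
    n_detected = 0
    n_spurious = 0
    for inf in inferred:
        candidates = [
            (abs(t.time - inf.time), j)
            for j, t in enumerate(detectable)
            if j not in matched_truth
            and t.tag_id == inf.tag_id
            and t.zone_id == inf.zone_id
            and t.moment.is_exit_moment == inf.moment.is_exit_moment
            and abs(t.time - inf.time) <= tolerance_s
        ]
        if candidates:
            _, j = min(candidates)
            matched_truth.add(j)
            n_detected += 1
        else:
            n_spurious += 1

    n_truth = len(detectable)
    n_missed = n_truth - len(matched_truth)
    sensitivity = n_detected / n_truth if n_truth else None
    truth_rate = _rate(detectable)
    inf_rate = _rate(list(inferred))
    bias = (
        inf_rate - truth_rate if inf_rate is not None and truth_rate is not None else None
    )
    return ConfusionReport(
        n_truth_detectable=n_truth,
        n_detected=n_detected,
        n_missed=n_missed,
        n_spurious=n_spurious,
        sensitivity=sensitivity,
        truth_compliance=truth_rate,
        inferred_compliance=inf_rate,
        compliance_bias=bias,
    )
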