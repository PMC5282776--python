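"""From raw proximity logs to validated location events.

Two sensing dialects are supported:

* **message streams** — the tag emits one APPROACH message when it enters a
  beacon's range and one LEAVE message when it exits; interference produces
  duplicates, drop-outs and ghost pairs, so the stream is paired and
  denoised before use;
* **RSSI streams** — periodic signal-strength samples per (tag, beacon),
  turned into dwells by a sliding-median filter with hysteresis.

Either way the output is a set of :class:`DwellInterval` records, which the
validator converts into :class:`LocationEvent` records using dwell-time
rules: proximity to a sink registers a hand-wash visit once 40 s of
proximity have elapsed, proximity to an ABHR dispenser registers a hand-rub
visit once 4 s have elapsed (the rub itself is performed walking away from
the dispenser), and bed / central / entrance zones register enter and exit
events at the times they are detected, regardless of duration.

All intervals are half-open ``[start, end)`` in seconds from shift start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .ward_layout import Facility, FacilityKind, WardLayout, facility_of_beacon

logger = logging.getLogger(__name__)

__all__ = [
    "DwellInterval",
    "LocationEvent",
    "SINK_MIN_DWELL_S",
    "DISPENSER_MIN_DWELL_S",
    "pair_messages_to_dwells",
    "detect_proximity_rssi",
    "denoise_dwells",
    "validate_locations",
]

#: Dwell (s) at a sink before a hand-wash visit is registered.
SINK_MIN_DWELL_S = 40.0
#: Dwell (s) at an ABHR dispenser before a hand-rub visit is registered.
DISPENSER_MIN_DWELL_S = 4.0

DEFAULT_MERGE_GAP_S = 2.0
DEFAULT_MIN_DWELL_S = 1.0

APPROACH = "APPROACH"
LEAVE = "LEAVE"

ZONE_ENTER = "ZONE_ENTER"
ZONE_EXIT = "ZONE_EXIT"
HYGIENE_STATION_VISIT = "HYGIENE_STATION_VISIT"

_ZONE_KINDS = {FacilityKind.BED, FacilityKind.CENTRAL, FacilityKind.ENTRANCE}
_STATION_KINDS = {FacilityKind.SINK, FacilityKind.DISPENSER}


@dataclass(frozen=True, order=True)
class DwellInterval:
    """Contiguous period one tag spends inside one beacon's range."""

    tag_id: str
    beacon_id: str
    start: float
    end: float
    source: str = "MESSAGES"  # MESSAGES | RSSI

    @property
    def duration_s(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class LocationEvent:
    """A validated, semantically typed location fact about one tag."""

    tag_id: str
    facility: Facility
    time: float
    kind: str  # ZONE_ENTER | ZONE_EXIT | HYGIENE_STATION_VISIT
    dwell_s: float


# ---------------------------------------------------------------------------
# Message pairing
# ---------------------------------------------------------------------------


def pair_messages_to_dwells(
    messages: Sequence,
    shift_end_s: float | None = None,
    counters: dict | None = None,
) -> list[DwellInterval]:
    """Pair APPROACH/LEAVE messages into dwell intervals.

    Robust by contract: a duplicate APPROACH inside an open dwell is
    ignored, a LEAVE with no open dwell is dropped as an orphan, and an
    APPROACH still open at the end of the stream is closed at
    ``shift_end_s`` (default: the last timestamp seen).  Anomaly counts are
    logged and, if a ``counters`` dict is supplied, accumulated under the
    keys ``duplicates``, ``orphans`` and ``dangling``.
    """
    msgs = sorted(messages, key=lambda m: (m.timestamp, m.tag_id, m.beacon_id))
    if shift_end_s is None:
        shift_end_s = msgs[-1].timestamp if msgs else 0.0
    stats = {"duplicates": 0, "orphans": 0, "dangling": 0}
    open_dwells: dict[tuple[str, str], float] = {}
    dwells: list[DwellInterval] = []
    for m in msgs:
        key = (m.tag_id, m.beacon_id)
        if m.msg_type == APPROACH:
            if key in open_dwells:
                stats["duplicates"] += 1
            else:
                open_dwells[key] = m.timestamp
        elif m.msg_type == LEAVE:
            start = open_dwells.pop(key, None)
            if start is None:
                stats["orphans"] += 1
            elif m.timestamp > start:
                dwells.append(DwellInterval(key[0], key[1], start, m.timestamp))
            # zero-length dwell: drop silently (start == end carries no information)
        else:
            stats["orphans"] += 1
    for (tag, beacon), start in open_dwells.items():
        stats["dangling"] += 1
        if shift_end_s > start:
            dwells.append(DwellInterval(tag, beacon, start, shift_end_s))
    if any(stats.values()):
        logger.info(
            "message pairing anomalies: %d duplicates, %d orphans, %d dangling",
            stats["duplicates"], stats["orphans"], stats["dangling"],
        )
    if counters is not None:
        for k, v in stats.items():
            counters[k] = counters.get(k, 0) + v
    dwells.sort()
    return dwells


# ---------------------------------------------------------------------------
# RSSI proximity detection
# ---------------------------------------------------------------------------


def detect_proximity_rssi(
    samples: Sequence,
    window: int = 5,
    enter_dbm: float = -70.0,
    exit_dbm: float = -75.0,
) -> list[DwellInterval]:
    """Hysteresis dwell detection on sliding-window median RSSI.

    Per (tag, beacon) stream the rolling median (odd ``window``, centred)
    opens a dwell when it reaches ``enter_dbm`` and closes it when it falls
    below ``exit_dbm``; ``enter_dbm > exit_dbm`` so a noisy signal near the
    threshold does not chatter.  A stream shorter than ``window`` yields no
    dwells (logged as a warning).
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if not enter_dbm > exit_dbm:
        raise ValueError("hysteresis requires enter_dbm > exit_dbm")

    streams: dict[tuple[str, str], list] = {}
    for s in samples:
        streams.setdefault((s.tag_id, s.beacon_id), []).append(s)

    dwells: list[DwellInterval] = []
    half = window // 2
    for (tag, beacon), ss in streams.items():
        ss.sort(key=lambda s: s.timestamp)
        if len(ss) < window:
            logger.warning(
                "rssi stream (%s, %s): %d samples < window %d; skipped",
                tag, beacon, len(ss), window,
            )
            continue
        values = np.array([s.rssi_dbm for s in ss])
        times = np.array([s.timestamp for s in ss])
        medians = np.array(
            [np.median(values[max(0, i - half): i + half + 1]) for i in range(len(values))]
        )
        inside = False
        start = 0.0
        for t, med in zip(times, medians):
            if not inside and med >= enter_dbm:
                inside, start = True, t
            elif inside and med < exit_dbm:
                inside = False
                if t > start:
                    dwells.append(DwellInterval(tag, beacon, start, t, source="RSSI"))
        if inside and times[-1] > start:
            dwells.append(DwellInterval(tag, beacon, start, float(times[-1]), source="RSSI"))
    dwells.sort()
    return dwells


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------


def denoise_dwells(
    dwells: Iterable[DwellInterval],
    layout: WardLayout,
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
    min_dwell_s: float = DEFAULT_MIN_DWELL_S,
) -> list[DwellInterval]:
    """Merge, prune and room-filter dwell intervals.

    1. per (tag, beacon), intervals separated by a gap shorter than
       ``merge_gap_s`` are merged (beacon-edge flicker);
    2. intervals shorter than ``min_dwell_s`` are dropped (blips);
    3. when two dwells of one tag overlap across *different rooms* — a
       physical impossibility, typically a ghost message pair from a room
       the wearer never entered — the shorter dwell is dropped.

    The defaults (2 s merge gap, 1 s minimum dwell) sit below the smallest
    meaningful dwell threshold (4 s at a dispenser) so denoising can never
    mask a hygiene-station visit.  The operation is idempotent.
    """
    by_key: dict[tuple[str, str], list[DwellInterval]] = {}
    for d in dwells:
        by_key.setdefault((d.tag_id, d.beacon_id), []).append(d)

    merged: list[DwellInterval] = []
    for key, ds in by_key.items():
        ds.sort(key=lambda d: d.start)
        cur = ds[0]
        for d in ds[1:]:
            if d.start - cur.end < merge_gap_s:
                cur = replace(cur, end=max(cur.end, d.end))
            else:
                merged.append(cur)
                cur = d
        merged.append(cur)

    pruned = [d for d in merged if d.duration_s >= min_dwell_s]

    room_of = {b.beacon_id: layout.facility(b.facility_id).room_id for b in layout.beacons}

    # room-consistency: greedily keep longer dwells; drop a dwell that
    # overlaps an already-kept dwell of the same tag in a different room
    by_tag: dict[str, list[DwellInterval]] = {}
    for d in pruned:
        by_tag.setdefault(d.tag_id, []).append(d)

    kept: list[DwellInterval] = []
    for tag, ds in by_tag.items():
        def _recency(d: DwellInterval) -> float:
            # most recent earlier sighting of the same beacon for this tag
            prev = [o.end for o in ds if o.beacon_id == d.beacon_id and o.end <= d.start]
            return max(prev, default=-np.inf)

        order = sorted(
            ds,
            key=lambda d: (-d.duration_s, -_recency(d), d.start, d.beacon_id),
        )
        accepted: list[DwellInterval] = []
        for d in order:
            conflict = any(
                room_of[d.beacon_id] != room_of[o.beacon_id]
                and d.start < o.end
                and o.start < d.end
                for o in accepted
            )
            if conflict:
                logger.info("dropped cross-room dwell %s", d)
            else:
                accepted.append(d)
        kept.extend(accepted)
    kept.sort()
    return kept


# ---------------------------------------------------------------------------
# Dwell-time validation
# ---------------------------------------------------------------------------


def validate_locations(
    dwells: Iterable[DwellInterval],
    layout: WardLayout,
    sink_min_s: float = SINK_MIN_DWELL_S,
    dispenser_min_s: float = DISPENSER_MIN_DWELL_S,
) -> list[LocationEvent]:
    """Convert denoised dwells into validated location events.

    Sink dwells of at least ``sink_min_s`` (inclusive) register a
    HYGIENE_STATION_VISIT, as do dispenser dwells of at least
    ``dispenser_min_s``; shorter hygiene-station dwells are passes-by and
    produce nothing.  Bed, central and entrance dwells always emit
    ZONE_ENTER at the dwell start and ZONE_EXIT at the dwell end.  The
    hygiene visit is stamped at the dwell *end*: the worker's hands are
    clean when they step away from the station.
    """
    events: list[LocationEvent] = []
    for d in dwells:
        fac = facility_of_beacon(layout, d.beacon_id)  # KeyError for unknown beacon
        if fac.kind in _STATION_KINDS:
            threshold = sink_min_s if fac.kind == FacilityKind.SINK else dispenser_min_s
            if d.duration_s >= threshold:
                events.append(
                    LocationEvent(d.tag_id, fac, d.end, HYGIENE_STATION_VISIT, d.duration_s)
                )
        elif fac.kind in _ZONE_KINDS:
            events.append(LocationEvent(d.tag_id, fac, d.start, ZONE_ENTER, d.duration_s))
            events.append(LocationEvent(d.tag_id, fac, d.end, ZONE_EXIT, d.duration_s))
    events.sort(key=lambda e: (e.time, e.tag_id, e.kind))
    return events
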