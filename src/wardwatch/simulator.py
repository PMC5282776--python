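"""Synthetic ICU shifts: nurse trajectories, ground truth and sensor logs.

No deposited dataset of ward proximity logs exists, so every downstream
stage is exercised against a behavioural simulation of a nursing shift.
Each nurse is assigned a fixed set of beds and alternates between
patient-care visits (mean 10 min at a bed) and general-area work (mean
5 min near the room's central point), an alternating renewal process.
Every visit opens a moment-1 opportunity at the bed-zone entry and a
moment-4-or-5 opportunity at the exit (moment 4 if the patient was
touched, probability taken from the configured moment mix); care steps
inside the zone additionally generate moment-2/3 opportunities, which are
ground truth only — flagged ``detectable=False`` because a proximity
system cannot see them.  With the default mix, moments 1, 4 and 5 make up
80 % of all opportunities.

Compliance is drawn once per inter-visit gap: with probability
``compliance_prob`` the nurse performs one hygiene action in the gap — a
hand wash at the sink (uniform 40–60 s) or an ABHR rub (product acquired
at a dispenser, rub uniform 20–30 s) — and that single action satisfies
both the exit moment it follows and the entry moment it precedes, exactly
as the compliance rules later score it.  Both opportunities in a gap
therefore share one Bernoulli draw; the *marginal* per-opportunity
compliance still equals ``compliance_prob`` exactly.  Moment-2/3
opportunities get independent draws (a complied one is a quick rub at the
bed-foot dispenser without leaving the bed zone).

Sensing is emulated in both dialects: approach/leave message streams with
duplicate, drop-out and ghost-message noise, and periodic RSSI samples
under a log-distance path-loss model.  With all noise rates zero the
message stream encodes the trajectory exactly (one approach and one leave
per dwell), which is what makes end-to-end identity testable.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .event_processing import APPROACH, LEAVE, DwellInterval
from .moments import RUB, WASH, HHAction, HHOpportunity, Moment
from .ward_layout import FacilityKind, WardLayout, beacon_of_facility

__all__ = [
    "NoiseConfig",
    "SimConfig",
    "TrajectorySegment",
    "GroundTruth",
    "RawMessage",
    "RssiSample",
    "simulate_shift",
    "sense_messages",
    "sense_rssi",
    "truth_dwells",
    "path_loss_rssi",
    "distance_from_rssi",
    "write_messages_csv",
    "write_messages_jsonl",
    "read_messages_csv",
    "read_messages_jsonl",
    "write_rssi_csv",
    "read_rssi_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "DEFAULT_SHIFT_START",
]

#: Nominal shift start used when serialising timestamps to ISO-8601.
DEFAULT_SHIFT_START = datetime(2025, 1, 6, 8, 0, 0)

# log-distance path-loss model defaults
RSSI_REF_DBM = -60.0  # received power at 1 m
PATH_LOSS_EXPONENT = 2.0
RSSI_CLAMP_M = 0.1

_TAG_COLORS = ["pink", "green", "red", "yellow"]


class ConfigError(ValueError):
    pass


class NoiseConfig(BaseModel):
    """Sensing imperfections of the message/RSSI channels.

    ``msg_rate_multiplier`` is the target expected ratio of emitted to
    ideal messages (the deployed hardware sent far more messages than the
    one-approach-one-leave contract); extra interference copies are added
    on top of simple duplicates to reach it.
    """

    p_duplicate_msg: float = Field(default=0.1, ge=0, le=1)
    p_missed_msg: float = Field(default=0.05, ge=0, le=1)
    p_ghost_msg_per_hour: float = Field(default=0.2, ge=0)
    rssi_sigma_db: float = Field(default=4.0, ge=0)
    msg_rate_multiplier: float = Field(default=1.5, gt=0)

    @classmethod
    def off(cls) -> "NoiseConfig":
        """A noiseless channel: exactly one approach/leave per dwell."""
        return cls(
            p_duplicate_msg=0.0,
            p_missed_msg=0.0,
            p_ghost_msg_per_hour=0.0,
            rssi_sigma_db=0.0,
            msg_rate_multiplier=1.0,
        )

    @property
    def extra_copy_rate(self) -> float:
        """Poisson rate of interference copies per surviving message."""
        if self.p_missed_msg >= 1.0:
            return 0.0
        return max(
            0.0,
            self.msg_rate_multiplier / (1.0 - self.p_missed_msg)
            - 1.0
            - self.p_duplicate_msg,
        )


class SimConfig(BaseModel):
    """Study conditions for one simulated shift."""

    n_nurses_per_shift: int = Field(default=4, ge=1)
    shift_hours: float = Field(default=8.0, gt=0)
    #: per-opportunity probability the required hygiene action is performed;
    #: default is the ward's observed baseline compliance.
    compliance_prob: float = Field(default=0.698, ge=0, le=1)
    #: target fractions of the five WHO moment types; defaults put moments
    #: 1, 4 and 5 at 80 % of all opportunities.
    moment_mix: dict[str, float] = Field(
        default_factory=lambda: {"1": 0.40, "2": 0.10, "3": 0.10, "4": 0.30, "5": 0.10}
    )
    wash_duration_band: tuple[float, float] = (40.0, 60.0)
    rub_duration_band: tuple[float, float] = (20.0, 30.0)
    #: probability a complied inter-visit action is a wash rather than a rub
    p_wash: float = Field(default=0.15, ge=0, le=1)
    patient_visit_mean_s: float = Field(default=600.0, gt=0)
    general_task_mean_s: float = Field(default=300.0, gt=0)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if set(self.moment_mix) != {"1", "2", "3", "4", "5"}:
            raise ConfigError("moment_mix must have keys '1'..'5'")
        total = sum(self.moment_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"moment_mix must sum to 1, got {total}")
        m = self.moment_mix
        if m["1"] <= 0 or abs(m["1"] - (m["4"] + m["5"])) > 1e-9:
            raise ConfigError(
                "every visit pairs one entry with one exit opportunity, so the "
                "moment mix must satisfy mix[1] == mix[4] + mix[5] > 0"
            )
        for band, name in [(self.wash_duration_band, "wash"), (self.rub_duration_band, "rub")]:
            if not (0 < band[0] < band[1]):
                raise ConfigError(f"{name}_duration_band must satisfy 0 < low < high")
        if self.patient_visit_mean_s <= 130 or self.general_task_mean_s <= 40:
            raise ConfigError("visit/gap means too short for the activity grammar")
        return self

    @property
    def shift_s(self) -> float:
        return self.shift_hours * 3600.0

    @property
    def p_touch(self) -> float:
        """P(patient touched | visit): moment 4 vs 5 at the exit."""
        m = self.moment_mix
        return m["4"] / (m["4"] + m["5"])

    @property
    def inzone_rate(self) -> float:
        """Expected moment-2/3 opportunities per patient-zone visit."""
        m = self.moment_mix
        return (m["2"] + m["3"]) / m["1"]


@dataclass(frozen=True)
class TrajectorySegment:
    """Nurse at one facility (or off-beacon, facility_id None) for [start, end)."""

    facility_id: str | None
    start: float
    end: float


@dataclass
class GroundTruth:
    """Everything that really happened for one nurse in one shift."""

    tag_id: str
    shift_s: float
    trajectory: list[TrajectorySegment]
    actions: list[HHAction]
    opportunities: list[HHOpportunity]


@dataclass(frozen=True, order=True)
class RawMessage:
    timestamp: float
    tag_id: str
    beacon_id: str
    msg_type: str  # APPROACH | LEAVE


@dataclass(frozen=True, order=True)
class RssiSample:
    timestamp: float
    tag_id: str
    beacon_id: str
    rssi_dbm: float


# ---------------------------------------------------------------------------
# Random substreams
# ---------------------------------------------------------------------------

_STREAMS = {"trajectory": 0, "compliance": 1, "noise": 2, "rssi": 3}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Independent, reproducible substream: components can be re-run alone."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream], index))
    )


# ---------------------------------------------------------------------------
# Shift simulation
# ---------------------------------------------------------------------------


def sample_action_durations(kind: str, n: int, cfg: SimConfig | None = None,
                            seed: int = 0) -> np.ndarray:
    """Draw ``n`` compliant action durations (s) from the configured band.

    The same uniform bands drive every action the shift simulator emits:
    hand washes take 40-60 s, hand rubs 20-30 s by default.
    """
    cfg = cfg or SimConfig()
    band = cfg.wash_duration_band if kind == WASH else cfg.rub_duration_band
    return _rng(seed, "compliance", 99).uniform(band[0], band[1], n)


def _assign_beds(layout: WardLayout, n_nurses: int) -> list[list]:
    beds = sorted(layout.facilities_of_kind(FacilityKind.BED), key=lambda f: f.id)
    if not beds:
        raise ConfigError("layout has no beds")
    groups: list[list] = [[] for _ in range(n_nurses)]
    for i, bed in enumerate(beds):
        groups[i * n_nurses // len(beds)].append(bed)
    # a nurse with no bed of her own covers the whole ward
    for g in groups:
        if not g:
            g.extend(beds)
    return groups


def _tag_ids(n: int) -> list[str]:
    tags = list(_TAG_COLORS[:n])
    tags += [f"tag{i}" for i in range(len(tags) + 1, n + 1)]
    return tags[:n]


class _Timeline:
    """Append-only trajectory builder for one nurse."""

    def __init__(self) -> None:
        self.t = 0.0
        self.segments: list[TrajectorySegment] = []

    def emit(self, facility_id: str | None, duration: float) -> None:
        duration = max(duration, 0.0)
        if duration > 0:
            last = self.segments[-1] if self.segments else None
            if last is not None and last.facility_id == facility_id and last.end == self.t:
                # contiguous stay at the same facility is one segment
                self.segments[-1] = TrajectorySegment(facility_id, last.start, self.t + duration)
            else:
                self.segments.append(TrajectorySegment(facility_id, self.t, self.t + duration))
        self.t += duration


def _simulate_nurse(
    tag: str,
    beds: Sequence,
    layout: WardLayout,
    cfg: SimConfig,
    rng_t: np.random.Generator,
    rng_c: np.random.Generator,
) -> GroundTruth:
    room_id = beds[0].room_id
    central = {r.id: next((f for f in layout.facilities_of_kind(FacilityKind.CENTRAL)
                           if f.room_id == r.id), None) for r in layout.rooms}
    sinks = {r.id: next((f for f in layout.facilities_of_kind(FacilityKind.SINK)
                         if f.room_id == r.id), None) for r in layout.rooms}
    door_disp = {
        r.id: next(
            (f for f in layout.facilities_of_kind(FacilityKind.DISPENSER)
             if f.room_id == r.id and "BED" not in f.id.upper()),
            next((f for f in layout.facilities_of_kind(FacilityKind.DISPENSER)
                  if f.room_id == r.id), None),
        )
        for r in layout.rooms
    }
    bed_disp: dict[str, object] = {}
    for bed in beds:
        cands = [
            f for f in layout.facilities_of_kind(FacilityKind.DISPENSER)
            if f.room_id == bed.room_id
            and math.dist(f.position, bed.position) <= layout.associate_radius_m
        ]
        bed_disp[bed.id] = min(cands, key=lambda f: math.dist(f.position, bed.position))

    tl = _Timeline()
    actions: list[HHAction] = []
    opps: list[HHOpportunity] = []
    visit_exp_mean = cfg.patient_visit_mean_s - 120.0
    gap_exp_mean = max(cfg.general_task_mean_s - 30.0, 10.0)

    def do_rub(station) -> HHAction:
        dwell = rng_t.uniform(4.0, 10.0)
        tl.emit(station.id, dwell)
        a = HHAction(tag, RUB, tl.t, float(rng_c.uniform(*cfg.rub_duration_band)), station.id)
        actions.append(a)
        return a

    def do_wash(station) -> HHAction:
        dur = float(rng_c.uniform(*cfg.wash_duration_band))
        tl.emit(station.id, dur)
        a = HHAction(tag, WASH, tl.t, dur, station.id)
        actions.append(a)
        return a

    prev_exit_opp: HHOpportunity | None = None  # moment-4/5 of the previous visit
    first = True
    while True:
        bed = beds[rng_t.integers(len(beds))]
        visit = 120.0 + float(rng_t.exponential(visit_exp_mean))
        coin = bool(rng_c.random() < cfg.compliance_prob)
        gap_action: HHAction | None = None

        if first:
            lead = 30.0 + float(rng_t.exponential(gap_exp_mean))
            if coin:
                pre_offset = float(rng_t.uniform(2.0, 10.0))
                tl.emit(central[room_id].id if central[room_id] else None,
                        max(lead - 20.0, 5.0))
                gap_action = do_rub(door_disp[room_id] or bed_disp[bed.id])
                tl.emit(None, pre_offset)
            else:
                tl.emit(central[room_id].id if central[room_id] else None, lead)
            first = False
        else:
            # gap after the previous visit: optional hygiene, then general work
            if coin:
                tl.emit(None, float(rng_t.uniform(2.0, 8.0)))  # walk to the station
                if rng_c.random() < cfg.p_wash and sinks[room_id] is not None:
                    gap_action = do_wash(sinks[room_id])
                else:
                    gap_action = do_rub(door_disp[room_id] or bed_disp[bed.id])
            rest = 30.0 + float(rng_t.exponential(gap_exp_mean))
            tl.emit(central[room_id].id if central[room_id] else None, rest)
            # the one gap action also satisfies the exit moment it follows
            if prev_exit_opp is not None:
                prev_exit_opp.complied = coin
                prev_exit_opp.linked_action = gap_action

        if bed.room_id != room_id:
            tl.emit(None, 15.0)  # corridor walk between rooms
            room_id = bed.room_id

        if tl.t + visit + 80.0 > cfg.shift_s:
            # no room for another full visit: wind down in the general area.
            # The last exit moment was already resolved by the gap just built.
            remaining = cfg.shift_s - tl.t
            if remaining > 0 and central[room_id] is not None:
                tl.emit(central[room_id].id, remaining)
            break

        entry = tl.t
        opps.append(
            HHOpportunity(tag, Moment.M1, entry, bed.id, complied=coin,
                          linked_action=gap_action)
        )

        # in-zone care steps: ground-truth moments 2/3, invisible to sensing
        exit_ = entry + visit
        n_inzone = int(rng_t.poisson(cfg.inzone_rate)) if visit > 60 else 0
        taus = sorted(float(x) for x in rng_t.uniform(entry + 15.0, exit_ - 15.0, n_inzone))
        kept: list[float] = []
        for tau in taus:
            if not kept or tau - kept[-1] >= 12.0:
                kept.append(tau)
        cursor = entry
        for tau in kept:
            m = Moment.M2 if rng_t.random() < 0.5 else Moment.M3
            c = bool(rng_c.random() < cfg.compliance_prob)
            if c:
                tl.emit(bed.id, tau - cursor)
                dwell = float(rng_t.uniform(4.0, 8.0))
                tl.emit(bed_disp[bed.id].id, dwell)
                a = HHAction(tag, RUB, tl.t,
                             float(rng_c.uniform(*cfg.rub_duration_band)),
                             bed_disp[bed.id].id)
                actions.append(a)
                opps.append(HHOpportunity(tag, m, tau, bed.id, complied=True,
                                          linked_action=a, detectable=False))
                cursor = tl.t
            else:
                opps.append(HHOpportunity(tag, m, tau, bed.id, complied=False,
                                          detectable=False))
        tl.emit(bed.id, exit_ - cursor)

        touched = bool(rng_t.random() < cfg.p_touch)
        prev_exit_opp = HHOpportunity(
            tag, Moment.M4 if touched else Moment.M5, tl.t, bed.id
        )
        opps.append(prev_exit_opp)

    # clip the trajectory to the shift bounds (a long general-area draw can
    # overshoot; nothing semantically interesting happens past shift end)
    clipped: list[TrajectorySegment] = []
    for s in tl.segments:
        if s.start >= cfg.shift_s:
            break
        clipped.append(
            s if s.end <= cfg.shift_s
            else TrajectorySegment(s.facility_id, s.start, cfg.shift_s)
        )
    tl.segments = clipped

    opps.sort(key=lambda o: o.time)
    actions.sort(key=lambda a: a.time)
    return GroundTruth(tag, cfg.shift_s, tl.segments, actions, opps)


def simulate_shift(layout: WardLayout, cfg: SimConfig) -> list[GroundTruth]:
    """One shift of ground truth, one :class:`GroundTruth` per nurse.

    Reproducible: the same (layout, config, seed) always yields the same
    truth.  Trajectory/behaviour and compliance draw from independent
    named substreams of ``cfg.seed``.
    """
    if cfg.shift_hours <= 0:
        raise ConfigError("shift_hours must be positive")
    groups = _assign_beds(layout, cfg.n_nurses_per_shift)
    truths = []
    for i, tag in enumerate(_tag_ids(cfg.n_nurses_per_shift)):
        truths.append(
            _simulate_nurse(
                tag, groups[i], layout, cfg,
                _rng(cfg.seed, "trajectory", i), _rng(cfg.seed, "compliance", i),
            )
        )
    return truths


# ---------------------------------------------------------------------------
# Sensing: message dialect
# ---------------------------------------------------------------------------


def truth_dwells(truth: GroundTruth | Iterable[GroundTruth],
                 layout: WardLayout) -> list[DwellInterval]:
    """Ground-truth beacon dwells implied by the trajectory."""
    truths = [truth] if isinstance(truth, GroundTruth) else list(truth)
    out = []
    for tr in truths:
        for seg in tr.trajectory:
            if seg.facility_id is None:
                continue
            beacon = beacon_of_facility(layout, seg.facility_id)
            out.append(DwellInterval(tr.tag_id, beacon.beacon_id, seg.start, seg.end))
    out.sort()
    return out


def sense_messages(
    truth: GroundTruth | Iterable[GroundTruth],
    layout: WardLayout,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> list[RawMessage]:
    """Approach/leave messages for the ground-truth dwells, plus noise.

    With all noise rates zero: exactly one APPROACH and one LEAVE per
    dwell.  Noise drops messages (``p_missed_msg``), duplicates them
    (``p_duplicate_msg`` plus Poisson interference copies up to
    ``msg_rate_multiplier``), and injects ghost approach/leave pairs from
    beacons in rooms the wearer never entered (``p_ghost_msg_per_hour``).
    """
    noise = noise or NoiseConfig()
    rng = _rng(seed, "noise")
    truths = [truth] if isinstance(truth, GroundTruth) else list(truth)

    out: list[RawMessage] = []

    def emit(tag: str, beacon: str, t: float, mtype: str) -> None:
        if noise.p_missed_msg > 0 and rng.random() < noise.p_missed_msg:
            return
        n_copies = 1
        if noise.p_duplicate_msg > 0 and rng.random() < noise.p_duplicate_msg:
            n_copies += 1
        if noise.extra_copy_rate > 0:
            n_copies += int(rng.poisson(noise.extra_copy_rate))
        out.append(RawMessage(t, tag, beacon, mtype))
        for _ in range(n_copies - 1):
            out.append(RawMessage(t + float(rng.uniform(0.0, 1.0)), tag, beacon, mtype))

    for tr in truths:
        for d in truth_dwells(tr, layout):
            emit(d.tag_id, d.beacon_id, d.start, APPROACH)
            emit(d.tag_id, d.beacon_id, d.end, LEAVE)

        if noise.p_ghost_msg_per_hour > 0:
            visited_rooms = {
                layout.facility(s.facility_id).room_id
                for s in tr.trajectory
                if s.facility_id is not None
            }
            ghost_beacons = [
                b.beacon_id
                for b in layout.beacons
                if layout.facility(b.facility_id).room_id not in visited_rooms
            ]
            if ghost_beacons:
                n_pairs = int(rng.poisson(noise.p_ghost_msg_per_hour * tr.shift_s / 3600.0))
                for _ in range(n_pairs):
                    beacon = ghost_beacons[int(rng.integers(len(ghost_beacons)))]
                    t0 = float(rng.uniform(0.0, max(tr.shift_s - 30.0, 1.0)))
                    dur = float(rng.uniform(5.0, 30.0))
                    out.append(RawMessage(t0, tr.tag_id, beacon, APPROACH))
                    out.append(RawMessage(min(t0 + dur, tr.shift_s), tr.tag_id, beacon, LEAVE))

    out.sort()
    return out


# ---------------------------------------------------------------------------
# Sensing: RSSI dialect
# ---------------------------------------------------------------------------


def path_loss_rssi(
    distance_m: float,
    ref_dbm: float = RSSI_REF_DBM,
    exponent: float = PATH_LOSS_EXPONENT,
    clamp_m: float = RSSI_CLAMP_M,
) -> float:
    """Log-distance path loss: rssi = A − 10·n·log10(max(d, d0))."""
    return ref_dbm - 10.0 * exponent * math.log10(max(distance_m, clamp_m))


def distance_from_rssi(
    rssi_dbm: float,
    ref_dbm: float = RSSI_REF_DBM,
    exponent: float = PATH_LOSS_EXPONENT,
) -> float:
    """Inverse of :func:`path_loss_rssi` (no clamp below the reference)."""
    return 10.0 ** ((ref_dbm - rssi_dbm) / (10.0 * exponent))


def _global_positions(truth: GroundTruth, layout: WardLayout):
    """Piecewise-constant nurse position; off-beacon segments sit in the corridor."""
    positions = []
    current_room = layout.rooms[0].id
    for seg in truth.trajectory:
        if seg.facility_id is not None:
            current_room = layout.facility(seg.facility_id).room_id
            pos = layout.global_position(seg.facility_id)
        else:
            room = layout.room(current_room)
            pos = (room.origin[0] + 0.5, room.origin[1] - 1.5)  # corridor by the door
        positions.append((seg.start, seg.end, pos))
    return positions


def sense_rssi(
    truth: GroundTruth | Iterable[GroundTruth],
    layout: WardLayout,
    noise: NoiseConfig | None = None,
    period_s: float = 1.0,
    seed: int = 0,
    max_range_m: float = 12.0,
) -> list[RssiSample]:
    """Periodic RSSI samples for every beacon within ``max_range_m``.

    The channel is a log-distance path-loss model with Gaussian shadowing
    of ``noise.rssi_sigma_db``; distance is the true nurse-to-beacon
    distance along the trajectory.
    """
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    noise = noise or NoiseConfig()
    rng = _rng(seed, "rssi")
    truths = [truth] if isinstance(truth, GroundTruth) else list(truth)
    beacon_pos = {b.beacon_id: layout.global_position(b.facility_id) for b in layout.beacons}

    out: list[RssiSample] = []
    for tr in truths:
        positions = _global_positions(tr, layout)
        for start, end, pos in positions:
            t = math.ceil(start / period_s) * period_s
            while t < end:
                for beacon_id, bpos in beacon_pos.items():
                    d = math.dist(pos, bpos)
                    if d <= max_range_m:
                        rssi = path_loss_rssi(d)
                        if noise.rssi_sigma_db > 0:
                            rssi += float(rng.normal(0.0, noise.rssi_sigma_db))
                        out.append(RssiSample(t, tr.tag_id, beacon_id, rssi))
                t += period_s
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Log writers / readers
# ---------------------------------------------------------------------------


def _iso(t: float, shift_start: datetime) -> str:
    return (shift_start + timedelta(seconds=t)).isoformat(timespec="milliseconds")


def _from_iso(s: str, shift_start: datetime) -> float:
    return (datetime.fromisoformat(s) - shift_start).total_seconds()


def write_messages_csv(messages: Sequence[RawMessage], path: str | Path,
                       shift_start: datetime = DEFAULT_SHIFT_START) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tag_id", "beacon_id", "timestamp_iso8601", "msg_type"])
        for m in messages:
            w.writerow([m.tag_id, m.beacon_id, _iso(m.timestamp, shift_start), m.msg_type])


def write_messages_jsonl(messages: Sequence[RawMessage], path: str | Path,
                         shift_start: datetime = DEFAULT_SHIFT_START) -> None:
    with open(path, "w") as fh:
        for m in messages:
            fh.write(json.dumps(
                {"tag_id": m.tag_id, "beacon_id": m.beacon_id,
                 "timestamp_iso8601": _iso(m.timestamp, shift_start),
                 "msg_type": m.msg_type}, sort_keys=True) + "\n")


def read_messages_csv(path: str | Path, shift_start: datetime = DEFAULT_SHIFT_START,
                      counters: dict | None = None) -> list[RawMessage]:
    """Read a message log; malformed lines are skipped and counted."""
    out: list[RawMessage] = []
    bad = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            try:
                out.append(RawMessage(
                    _from_iso(row["timestamp_iso8601"], shift_start),
                    row["tag_id"], row["beacon_id"], row["msg_type"],
                ))
                if row["msg_type"] not in (APPROACH, LEAVE):
                    out.pop()
                    raise ValueError(row["msg_type"])
            except (KeyError, TypeError, ValueError):
                bad += 1
    if counters is not None:
        counters["bad_lines"] = counters.get("bad_lines", 0) + bad
    out.sort()
    return out


def read_messages_jsonl(path: str | Path, shift_start: datetime = DEFAULT_SHIFT_START,
                        counters: dict | None = None) -> list[RawMessage]:
    out: list[RawMessage] = []
    bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                row = json.loads(line)
                if row["msg_type"] not in (APPROACH, LEAVE):
                    raise ValueError(row["msg_type"])
                out.append(RawMessage(
                    _from_iso(row["timestamp_iso8601"], shift_start),
                    row["tag_id"], row["beacon_id"], row["msg_type"],
                ))
            except (KeyError, TypeError, ValueError, json.JSONDecodeError):
                bad += 1
    if counters is not None:
        counters["bad_lines"] = counters.get("bad_lines", 0) + bad
    out.sort()
    return out


def write_rssi_csv(samples: Sequence[RssiSample], path: str | Path,
                   shift_start: datetime = DEFAULT_SHIFT_START) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tag_id", "beacon_id", "timestamp_iso8601", "rssi_dbm"])
        for s in samples:
            w.writerow([s.tag_id, s.beacon_id, _iso(s.timestamp, shift_start),
                        f"{s.rssi_dbm:.3f}"])


def read_rssi_csv(path: str | Path, shift_start: datetime = DEFAULT_SHIFT_START,
                  counters: dict | None = None) -> list[RssiSample]:
    out: list[RssiSample] = []
    bad = 0
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            try:
                out.append(RssiSample(
                    _from_iso(row["timestamp_iso8601"], shift_start),
                    row["tag_id"], row["beacon_id"], float(row["rssi_dbm"]),
                ))
            except (KeyError, TypeError, ValueError):
                bad += 1
    if counters is not None:
        counters["bad_lines"] = counters.get("bad_lines", 0) + bad
    out.sort()
    return out


def _truth_to_dict(tr: GroundTruth) -> dict:
    return {
        "tag_id": tr.tag_id,
        "shift_s": tr.shift_s,
        "trajectory": [asdict(s) for s in tr.trajectory],
        "actions": [asdict(a) for a in tr.actions],
        "opportunities": [
            {
                "tag_id": o.tag_id, "moment": o.moment.value, "time": o.time,
                "zone_id": o.zone_id, "complied": o.complied,
                "detectable": o.detectable,
                "linked_action": asdict(o.linked_action) if o.linked_action else None,
            }
            for o in tr.opportunities
        ],
    }


def write_ground_truth_json(truths: Sequence[GroundTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([_truth_to_dict(t) for t in truths], fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth_json(path: str | Path) -> list[GroundTruth]:
    with open(path) as fh:
        raw = json.load(fh)
    truths = []
    for tr in raw:
        truths.append(GroundTruth(
            tag_id=tr["tag_id"],
            shift_s=tr["shift_s"],
            trajectory=[TrajectorySegment(**s) for s in tr["trajectory"]],
            actions=[HHAction(**a) for a in tr["actions"]],
            opportunities=[
                HHOpportunity(
                    tag_id=o["tag_id"], moment=Moment(o["moment"]), time=o["time"],
                    zone_id=o["zone_id"], complied=o["complied"],
                    detectable=o["detectable"],
                    linked_action=HHAction(**o["linked_action"]) if o["linked_action"] else None,
                )
                for o in tr["opportunities"]
            ],
        ))
    return truths
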