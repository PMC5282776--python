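"""Batch orchestration: simulate/ingest → events → compliance → game state.

One *run* covers one shift and lives in a run directory containing every
artifact as plain text (CSV / JSON / JSON-lines) plus a manifest, so a run
is reproducible byte-for-byte from (layout, config, seed).  Shift start
and end are explicit configuration — shifts are never auto-detected from
the data — and timestamps are timezone-naive ISO-8601; a shift does not
cross midnight.

The stats layer answers the web application's stats-page queries: the
compliance rate over a range of days or months, or hour by hour within a
single shift.  Every aggregate is a recount of the underlying opportunity
records; a bucket with no opportunities has an *undefined* rate, never
zero.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, model_validator

from . import event_processing as ep
from . import gamification as game
from . import moments
from . import simulator as sim
from .ward_layout import WardLayout, default_icu_layout, load_layout

logger = logging.getLogger(__name__)

__all__ = [
    "StatsQuery",
    "ShiftRecord",
    "run_pipeline",
    "process_messages",
    "stats_series",
    "read_summary_history",
    "append_summary_history",
]


# ---------------------------------------------------------------------------
# Serialisation helpers
# ---------------------------------------------------------------------------


def _event_dict(e: ep.LocationEvent) -> dict:
    return {
        "tag_id": e.tag_id,
        "facility_id": e.facility.id,
        "facility_kind": e.facility.kind.value,
        "time": round(e.time, 6),
        "kind": e.kind,
        "dwell_s": round(e.dwell_s, 6),
    }


def _opp_dict(o: moments.HHOpportunity) -> dict:
    return {
        "tag_id": o.tag_id,
        "moment": o.moment.value,
        "time": round(o.time, 6),
        "zone_id": o.zone_id,
        "complied": o.complied,
        "action_time": round(o.linked_action.time, 6) if o.linked_action else None,
        "action_kind": o.linked_action.kind if o.linked_action else None,
    }


def _summary_dict(s: moments.ShiftSummary) -> dict:
    d = asdict(s)
    d["shift_score"] = game.shift_score(s)
    return d


def _write_jsonl(records: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r, sort_keys=True) + "\n")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Processing core
# ---------------------------------------------------------------------------


def process_messages(
    messages: Sequence[sim.RawMessage],
    layout: WardLayout,
    shift_end_s: float,
    counters: dict | None = None,
) -> tuple[list[ep.LocationEvent], list[moments.HHOpportunity], list[moments.HHAction]]:
    """Raw messages → validated events → linked opportunities + actions."""
    dwells = ep.pair_messages_to_dwells(messages, shift_end_s=shift_end_s,
                                        counters=counters)
    dwells = ep.denoise_dwells(dwells, layout)
    events = ep.validate_locations(dwells, layout)
    actions = moments.actions_from_events(events)
    opps = moments.detect_opportunities(events, counters=counters)
    opps = moments.link_actions(opps, actions)
    return events, opps, actions


def _summaries_by_tag(
    events: Sequence[ep.LocationEvent],
    opps: Sequence[moments.HHOpportunity],
    shift_hours: int,
) -> dict[str, moments.ShiftSummary]:
    tags = sorted({e.tag_id for e in events} | {o.tag_id for o in opps})
    out = {}
    for tag in tags:
        out[tag] = moments.summarize_shift(
            [o for o in opps if o.tag_id == tag],
            [e for e in events if e.tag_id == tag],
            shift_hours=shift_hours,
        )
    return out


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    output_dir: str | Path,
    layout: WardLayout | str | Path | None = None,
    sim_config: sim.SimConfig | None = None,
    messages_path: str | Path | None = None,
    seed: int = 0,
    shift_date: str = "2025-01-06",
    game_state_in: str | Path | None = None,
) -> dict:
    """Run one shift end to end and write all artifacts to ``output_dir``.

    Either simulates a shift (``sim_config``; raw logs and ground truth are
    written too) or ingests an existing approach/leave message log
    (``messages_path``).  Outputs are deterministic given (layout, config,
    seed).  Returns the manifest dict.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if layout is None:
        layout = default_icu_layout()
    elif not isinstance(layout, WardLayout):
        layout = load_layout(layout)

    counters: dict[str, int] = {}
    shift_start = datetime.fromisoformat(f"{shift_date}T08:00:00")
    simulated = messages_path is None

    if simulated:
        cfg = (sim_config or sim.SimConfig()).model_copy(update={"seed": seed})
        truths = sim.simulate_shift(layout, cfg)
        messages = sim.sense_messages(truths, layout, cfg.noise, seed=seed)
        sim.write_ground_truth_json(truths, out / "ground_truth.json")
        sim.write_messages_csv(messages, out / "messages.csv", shift_start)
        shift_end_s = cfg.shift_s
        shift_hours = int(cfg.shift_hours)
    else:
        if sim_config is not None:
            raise ValueError("give either sim_config or messages_path, not both")
        messages = sim.read_messages_csv(messages_path, shift_start, counters=counters)
        if not messages:
            raise ValueError(f"no usable messages in {messages_path}")
        shift_end_s = max(m.timestamp for m in messages)
        shift_hours = max(math.ceil(shift_end_s / 3600), 1)

    events, opps, actions = process_messages(messages, layout, shift_end_s, counters)
    _write_jsonl([_event_dict(e) for e in events], out / "events.jsonl")
    _write_jsonl([_opp_dict(o) for o in opps], out / "opportunities.jsonl")

    summaries = _summaries_by_tag(events, opps, shift_hours)
    _write_json({t: _summary_dict(s) for t, s in summaries.items()},
                out / "summaries.json")

    # game-state delta
    if game_state_in is not None:
        states = _read_game_state(game_state_in)
    else:
        states = {}
    colors = dict(zip(sorted(summaries), game.SENSOR_COLORS * 10))
    for tag in summaries:
        states.setdefault(tag, game.PlayerState(player_id=tag,
                                                sensor_color=colors[tag]))

    scores = {t: game.shift_score(s) for t, s in summaries.items()}
    winners = game.determine_winner(scores)
    catalog = game.default_badge_catalog()
    previous_ranks = {
        v.player_id: v.rank for v in game.build_leaderboard(list(states.values()))
    }
    awarded_all = {}
    for tag, summary in summaries.items():
        st = game.award_points(states[tag], summary, is_winner=tag in winners)
        ctx = game.ShiftContext(summary, is_top_compliance=tag in winners)
        st, awarded = game.update_badges(st, ctx, catalog)
        states[tag] = st
        awarded_all[tag] = awarded
    leaderboard = game.build_leaderboard(list(states.values()), previous_ranks)

    _write_json(_game_state_dict(states), out / "game_state.json")
    _write_json([asdict(v) for v in leaderboard], out / "leaderboard.json")
    _write_json(game.dashboard_payload(summaries), out / "dashboard.json")
    _write_json(
        {
            t: game.email_payload(summaries[t], states[t], shift_date)
            for t in sorted(summaries)
        },
        out / "emails.json",
    )

    manifest = {
        "shift_date": shift_date,
        "seed": seed,
        "simulated": simulated,
        "anomaly_counters": dict(sorted(counters.items())),
        "n_messages": len(messages),
        "n_events": len(events),
        "n_opportunities": len(opps),
        "n_actions": len(actions),
        "winners": sorted(winners),
        "badges_awarded": {t: a for t, a in sorted(awarded_all.items()) if a},
        "artifacts": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    _write_json(manifest, out / "manifest.json")
    logger.info("pipeline run complete: %s", out)
    return manifest


def _game_state_dict(states: dict[str, game.PlayerState]) -> dict:
    out = {}
    for tag, s in sorted(states.items()):
        d = asdict(s)
        d["owned_items"] = sorted(s.owned_items)
        out[tag] = d
    return out


def _read_game_state(path: str | Path) -> dict[str, game.PlayerState]:
    with open(path) as fh:
        raw = json.load(fh)
    states = {}
    for tag, d in raw.items():
        d = dict(d)
        d["owned_items"] = set(d.get("owned_items", []))
        states[tag] = game.PlayerState(**d)
    return states


# ---------------------------------------------------------------------------
# Stats page
# ---------------------------------------------------------------------------


class StatsQuery(BaseModel):
    player_id: str
    granularity: str  # DAY | MONTH | SHIFT_HOURLY
    start: date
    end: date
    shift_id: str | None = None

    @model_validator(mode="after")
    def _check(self) -> "StatsQuery":
        if self.granularity not in ("DAY", "MONTH", "SHIFT_HOURLY"):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        if self.start > self.end:
            raise ValueError("query range start must not exceed end")
        if self.granularity == "SHIFT_HOURLY" and not self.shift_id:
            raise ValueError("SHIFT_HOURLY requires a single shift_id")
        return self


@dataclass(frozen=True)
class ShiftRecord:
    """One finished shift of one player, as stored in the summary history."""

    shift_id: str
    shift_date: str  # ISO date
    player_id: str
    summary: moments.ShiftSummary


def append_summary_history(path: str | Path, records: Sequence[ShiftRecord]) -> None:
    with open(path, "a") as fh:
        for r in records:
            fh.write(json.dumps(
                {"shift_id": r.shift_id, "shift_date": r.shift_date,
                 "player_id": r.player_id, "summary": asdict(r.summary)},
                sort_keys=True) + "\n")


def read_summary_history(path: str | Path) -> list[ShiftRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            srec = d["summary"]
            srec["per_hour"] = [tuple(x) for x in srec["per_hour"]]
            out.append(ShiftRecord(d["shift_id"], d["shift_date"], d["player_id"],
                                   moments.ShiftSummary(**srec)))
    return out


def stats_series(query: StatsQuery, records: Sequence[ShiftRecord]) -> list[dict]:
    """Per-bucket (opportunities, complied, rate) for one player.

    DAY and MONTH buckets recount the player's shifts in the inclusive
    date range; SHIFT_HOURLY returns the hourly breakdown of one shift.
    Buckets with zero opportunities have ``rate`` None (undefined).
    """
    mine = [
        r for r in records
        if r.player_id == query.player_id
        and query.start <= date.fromisoformat(r.shift_date) <= query.end
    ]
    if query.granularity == "SHIFT_HOURLY":
        shift = [r for r in mine if r.shift_id == query.shift_id]
        buckets = []
        for r in shift:
            for hour, (n, c) in enumerate(r.summary.per_hour):
                rate = moments.compliance_rate(c, n)
                buckets.append({
                    "bucket": f"{r.shift_date}T{hour:02d}",
                    "opportunities": n,
                    "complied": c,
                    "rate": float(rate) if rate is not None else None,
                })
        return buckets

    keyfn = (
        (lambda r: r.shift_date)
        if query.granularity == "DAY"
        else (lambda r: r.shift_date[:7])
    )
    grouped: dict[str, list[ShiftRecord]] = {}
    for r in mine:
        grouped.setdefault(keyfn(r), []).append(r)
    buckets = []
    for key in sorted(grouped):
        n = sum(r.summary.n_opportunities for r in grouped[key])
        c = sum(r.summary.n_complied for r in grouped[key])
        rate = moments.compliance_rate(c, n)
        buckets.append({
            "bucket": key,
            "opportunities": n,
            "complied": c,
            "rate": float(rate) if rate is not None else None,
        })
    return buckets
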