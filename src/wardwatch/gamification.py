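"""Gamification engine: shift scores, points, levels, badges, shop, leaderboard.

Players are pseudonymous — identified by the colour of the sensor they wear
(pink, green, red or yellow, like board-game pieces) — and their hand-
hygiene work in the ward is the only source of *points*, which drive a
convex level curve (each level costs strictly more points than the one
before).  *Badges* reward ward actions (e.g. being the shift's most
compliant player) and game actions (e.g. sending a suggestion), in tiers:
the first tier after one qualifying shift, the second after ten, and so
on.  Ward badges are gated: only shifts with a compliance rate strictly
above 70 % qualify, so only acceptable performance is rewarded.  Badges
pay *currency* (harder badges pay more), spendable in a virtual shop on
cosmetics, extra stats views and a peek at adjacent leaderboard ranks.
The leaderboard is partial — a player sees their own rank and whether they
moved up, down or stayed, not the full ordering.

Point values, the level curve, tier ladders, currency rewards and shop
prices are configuration defaults; the ordinal structure (convex levels,
1-then-10-shift tiers, harder-is-worth-more) is what matters.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Mapping, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

from .moments import ShiftSummary

__all__ = [
    "PlayerState",
    "BadgeSpec",
    "ShopItem",
    "ShiftContext",
    "LeaderboardView",
    "CatalogError",
    "PurchaseError",
    "POINTS_PER_COMPLIED",
    "WIN_BONUS",
    "BADGE_GATE_PERCENT",
    "ADJACENT_RANKS_ITEM",
    "shift_score",
    "determine_winner",
    "award_points",
    "level_for_points",
    "points_for_level",
    "badge_eligibility",
    "update_badges",
    "purchase_item",
    "build_leaderboard",
    "dashboard_payload",
    "email_payload",
    "encode_stats_token",
    "decode_stats_token",
    "default_badge_catalog",
    "default_shop_catalog",
    "load_badge_catalog",
    "load_shop_catalog",
]

POINTS_PER_COMPLIED = 10
WIN_BONUS = 50
#: ward badges require a shift compliance strictly above this percentage
BADGE_GATE_PERCENT = 70.0
ADJACENT_RANKS_ITEM = "adjacent_ranks"

SENSOR_COLORS = ("PINK", "GREEN", "RED", "YELLOW")


class CatalogError(KeyError):
    pass


class PurchaseError(ValueError):
    pass


class BadgeSpec(BaseModel):
    badge_id: str
    trigger: str  # WARD_ACTION | GAME_ACTION
    predicate_id: str
    tier_requirements: list[int] = Field(default_factory=lambda: [1, 10, 25, 50])
    currency_reward_per_tier: list[int] = Field(default_factory=lambda: [10, 25, 60, 150])

    @model_validator(mode="after")
    def _check(self) -> "BadgeSpec":
        reqs = self.tier_requirements
        if not reqs or reqs[0] != 1:
            raise ValueError("first badge tier must require exactly 1 qualifying shift")
        if any(b <= a for a, b in zip(reqs, reqs[1:])):
            raise ValueError("tier_requirements must be strictly increasing")
        if len(self.currency_reward_per_tier) != len(reqs):
            raise ValueError("one currency reward per tier required")
        if any(b <= a for a, b in zip(self.currency_reward_per_tier,
                                      self.currency_reward_per_tier[1:])):
            raise ValueError("harder tiers must be worth strictly more currency")
        if self.trigger not in ("WARD_ACTION", "GAME_ACTION"):
            raise ValueError(f"unknown trigger {self.trigger!r}")
        return self


class ShopItem(BaseModel):
    item_id: str
    name: str
    price: int = Field(gt=0)


@dataclass
class PlayerState:
    player_id: str
    sensor_color: str = "PINK"
    points: int = 0
    level: int = 0
    badges: dict[str, int] = field(default_factory=dict)  # badge_id -> achieved tier
    currency: int = 0
    owned_items: set[str] = field(default_factory=set)
    qualifying_shift_counts: dict[str, int] = field(default_factory=dict)
    total_complied: int = 0
    total_opportunities: int = 0

    def copy(self) -> "PlayerState":
        return replace(
            self,
            badges=dict(self.badges),
            owned_items=set(self.owned_items),
            qualifying_shift_counts=dict(self.qualifying_shift_counts),
        )


@dataclass(frozen=True)
class ShiftContext:
    """What a finished shift contributes to badge predicates."""

    summary: ShiftSummary
    is_top_compliance: bool = False
    game_actions: frozenset = frozenset()  # e.g. {"suggestion_sent"}


@dataclass(frozen=True)
class LeaderboardView:
    player_id: str
    rank: int
    movement: str  # UP | DOWN | SAME
    visible_neighbors: tuple = ()  # ((rank, player_id), ...) if unlocked


# ---------------------------------------------------------------------------
# Scores and the win state
# ---------------------------------------------------------------------------


def shift_score(summary: ShiftSummary) -> float | None:
    """Shift compliance as a percentage, half-up to 1 decimal; None if undefined."""
    if summary.compliance_rate is None:
        return None
    return float(
        Decimal(summary.compliance_rate * 100).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def determine_winner(scores: Mapping[str, float | None]) -> set[str]:
    """Players with the highest defined shift score; ties share the win."""
    defined = {p: s for p, s in scores.items() if s is not None}
    if not defined:
        return set()
    best = max(defined.values())
    return {p for p, s in defined.items() if s == best}


# ---------------------------------------------------------------------------
# Points and levels
# ---------------------------------------------------------------------------


def points_for_level(level: int) -> int:
    """Cumulative points needed to hold ``level``: T(L) = 100·L·(L+1)/2."""
    if level < 0:
        raise ValueError("level must be non-negative")
    return 50 * level * (level + 1)


def level_for_points(points: int) -> int:
    """Largest L with T(L) <= points.  Per-level increments grow strictly."""
    if points < 0:
        raise ValueError("points must be non-negative")
    level = int((-50 + (2500 + 200 * points) ** 0.5) // 100)
    while points_for_level(level + 1) <= points:
        level += 1
    while level > 0 and points_for_level(level) > points:
        level -= 1
    return level


def award_points(state: PlayerState, summary: ShiftSummary, is_winner: bool = False
                 ) -> PlayerState:
    """Credit a finished shift: 10 points per complied moment, 50 for the win."""
    new = state.copy()
    new.points += POINTS_PER_COMPLIED * summary.n_complied + (WIN_BONUS if is_winner else 0)
    new.level = level_for_points(new.points)
    new.total_complied += summary.n_complied
    new.total_opportunities += summary.n_opportunities
    return new


# ---------------------------------------------------------------------------
# Badges
# ---------------------------------------------------------------------------

_PREDICATES: dict[str, Callable[[ShiftContext], bool]] = {
    "compliant_shift": lambda ctx: True,
    "highest_compliance_in_shift": lambda ctx: ctx.is_top_compliance,
    "perfect_shift": lambda ctx: ctx.summary.compliance_rate == 1.0,
    "suggestion_sent": lambda ctx: "suggestion_sent" in ctx.game_actions,
}


def badge_eligibility(summary: ShiftSummary) -> bool:
    """Ward badges only count shifts with compliance strictly above 70 %."""
    if summary.compliance_rate is None:
        return False
    return summary.compliance_rate * 100 > BADGE_GATE_PERCENT


def update_badges(
    state: PlayerState,
    shift: ShiftContext,
    badge_catalog: Sequence[BadgeSpec],
) -> tuple[PlayerState, list[tuple[str, int]]]:
    """Advance badge progress for one finished shift.

    Ward-action predicates are evaluated only when the shift passes the
    70 % gate; game-action predicates are not gated.  Reaching
    ``tier_requirements[t]`` qualifying shifts awards tier ``t+1`` exactly
    once and credits its currency.  Returns the new state and the list of
    (badge_id, tier) awarded now.
    """
    new = state.copy()
    awarded: list[tuple[str, int]] = []
    gate_ok = badge_eligibility(shift.summary)
    for spec in badge_catalog:
        pred = _PREDICATES.get(spec.predicate_id)
        if pred is None:
            raise CatalogError(f"unknown badge predicate {spec.predicate_id!r}")
        if spec.trigger == "WARD_ACTION" and not gate_ok:
            continue
        if not pred(shift):
            continue
        count = new.qualifying_shift_counts.get(spec.badge_id, 0) + 1
        new.qualifying_shift_counts[spec.badge_id] = count
        current_tier = new.badges.get(spec.badge_id, 0)
        for tier_idx, req in enumerate(spec.tier_requirements, start=1):
            if count >= req and tier_idx > current_tier:
                new.badges[spec.badge_id] = tier_idx
                new.currency += spec.currency_reward_per_tier[tier_idx - 1]
                awarded.append((spec.badge_id, tier_idx))
                current_tier = tier_idx
    return new, awarded


# ---------------------------------------------------------------------------
# Shop
# ---------------------------------------------------------------------------


def purchase_item(state: PlayerState, item_id: str,
                  shop_catalog: Sequence[ShopItem]) -> PlayerState:
    """Spend currency on a shop item; rejects duplicates and overdrafts."""
    item = next((i for i in shop_catalog if i.item_id == item_id), None)
    if item is None:
        raise CatalogError(f"unknown shop item {item_id!r}")
    if item_id in state.owned_items:
        raise PurchaseError(f"item {item_id!r} already owned")
    if state.currency < item.price:
        raise PurchaseError(
            f"insufficient currency for {item_id!r}: have {state.currency}, "
            f"need {item.price}"
        )
    new = state.copy()
    new.currency -= item.price
    new.owned_items.add(item_id)
    return new


# ---------------------------------------------------------------------------
# Leaderboard
# ---------------------------------------------------------------------------


def build_leaderboard(
    states: Sequence[PlayerState],
    previous_ranks: Mapping[str, int] | None = None,
) -> list[LeaderboardView]:
    """Partial leaderboard: rank, movement, and neighbours only if unlocked.

    Ranking is by lifetime points, descending; ties go to the player who
    needed fewer opportunities, then to player id.
    """
    if not states:
        return []
    ordered = sorted(
        states, key=lambda s: (-s.points, s.total_opportunities, s.player_id)
    )
    ranks = {s.player_id: i + 1 for i, s in enumerate(ordered)}
    views = []
    for s in ordered:
        rank = ranks[s.player_id]
        if previous_ranks is None or s.player_id not in previous_ranks:
            movement = "SAME"
        else:
            prev = previous_ranks[s.player_id]
            movement = "UP" if rank < prev else ("DOWN" if rank > prev else "SAME")
        neighbors: tuple = ()
        if ADJACENT_RANKS_ITEM in s.owned_items:
            neighbors = tuple(
                (i + 1, ordered[i].player_id)
                for i in (rank - 2, rank)
                if 0 <= i < len(ordered)
            )
        views.append(LeaderboardView(s.player_id, rank, movement, neighbors))
    return views


# ---------------------------------------------------------------------------
# Feedback payloads
# ---------------------------------------------------------------------------


def dashboard_payload(summaries: Mapping[str, ShiftSummary]) -> dict:
    """The ward-screen shift view: one bar per active sensor, leader flagged.

    Sensors are shown by cap colour only — no real names on the ward
    screen.  A sensor with no opportunities yet has no score and its bar
    carries no value.
    """
    scores = {tag: shift_score(s) for tag, s in summaries.items()}
    defined = [v for v in scores.values() if v is not None]
    best = max(defined) if defined else None
    bars = [
        {
            "sensor": tag,
            "score": scores[tag],
            "is_leader": scores[tag] is not None and scores[tag] == best,
        }
        for tag in sorted(summaries)
    ]
    return {"bars": bars}


def encode_stats_token(player_id: str, shift_date: str) -> str:
    raw = json.dumps({"player_id": player_id, "shift_date": shift_date},
                     sort_keys=True).encode()
    return base64.urlsafe_b64encode(raw).decode()


def decode_stats_token(token: str) -> dict:
    return json.loads(base64.urlsafe_b64decode(token.encode()).decode())


def email_payload(summary: ShiftSummary, player: PlayerState, shift_date: str,
                  shift_open: bool = False) -> dict:
    """End-of-shift e-mail: own compliance rate and a deep link, nothing else."""
    if shift_open:
        raise RuntimeError("e-mail feedback is sent only after the shift closes")
    score = shift_score(summary)
    return {
        "player_id": player.player_id,
        "shift_date": shift_date,
        "compliance_percent": f"{score:.1f}%" if score is not None else None,
        "stats_link_token": encode_stats_token(player.player_id, shift_date),
    }


# ---------------------------------------------------------------------------
# Catalogs
# ---------------------------------------------------------------------------


def default_badge_catalog() -> list[BadgeSpec]:
    return [
        BadgeSpec(badge_id="clean_hands", trigger="WARD_ACTION",
                  predicate_id="compliant_shift"),
        BadgeSpec(badge_id="shift_champion", trigger="WARD_ACTION",
                  predicate_id="highest_compliance_in_shift",
                  currency_reward_per_tier=[15, 40, 90, 200]),
        BadgeSpec(badge_id="spotless", trigger="WARD_ACTION",
                  predicate_id="perfect_shift",
                  currency_reward_per_tier=[20, 50, 120, 250]),
        BadgeSpec(badge_id="helping_voice", trigger="GAME_ACTION",
                  predicate_id="suggestion_sent"),
    ]


def default_shop_catalog() -> list[ShopItem]:
    return [
        ShopItem(item_id="avatar_hat", name="Avatar hat", price=30),
        ShopItem(item_id="avatar_frame", name="Avatar frame", price=25),
        ShopItem(item_id="stats_score_evolution", name="Score-evolution stats view",
                 price=40),
        ShopItem(item_id=ADJACENT_RANKS_ITEM, name="See adjacent leaderboard ranks",
                 price=60),
    ]


def _load_catalog(path: str | Path) -> list:
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, list):
        raise CatalogError(f"{path}: catalog must be a list")
    return raw


def load_badge_catalog(path: str | Path) -> list[BadgeSpec]:
    return [BadgeSpec.model_validate(x) for x in _load_catalog(path)]


def load_shop_catalog(path: str | Path) -> list[ShopItem]:
    return [ShopItem.model_validate(x) for x in _load_catalog(path)]
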