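"""Ward spatial model: rooms, facilities and beacon placements.

A ward is a set of rectangular rooms.  Each room contains *facilities* —
patient beds, sinks, alcohol-based-hand-rub (ABHR) dispensers, a central
reference point, optionally a marked entrance — at room-local coordinates
(metres, origin at the room's door corner).  Bluetooth beacons are fixed to
facilities; a wearable tag carried by a healthcare worker reports proximity
to these beacons, which is the raw signal every downstream stage consumes.

The bundled default layout models a three-room intensive-care unit: one
four-bed room and two two-bed rooms, each room equipped with one sink, one
ABHR dispenser near the entrance and one ABHR dispenser at the foot of each
bed, plus one beacon per bed, per sink, per dispenser and one at a central
point of the room.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Iterable

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "FacilityKind",
    "Facility",
    "BeaconPlacement",
    "Room",
    "WardLayout",
    "LayoutError",
    "LayoutFormatError",
    "load_layout",
    "write_layout",
    "default_icu_layout",
    "facility_of_beacon",
    "DEFAULT_LAYOUT_PATH",
]

DEFAULT_ASSOCIATE_RADIUS_M = 1.5

DEFAULT_LAYOUT_PATH = Path(__file__).parent / "data" / "default_icu.yaml"


class LayoutError(ValueError):
    """A structurally valid file that violates a ward-layout invariant."""


class LayoutFormatError(ValueError):
    """The file could not be parsed at all."""


class FacilityKind(str, enum.Enum):
    BED = "BED"
    SINK = "SINK"
    DISPENSER = "DISPENSER"
    CENTRAL = "CENTRAL"
    ENTRANCE = "ENTRANCE"


class Facility(BaseModel):
    """A fixed point of interest inside one room."""

    id: str
    kind: FacilityKind
    room_id: str
    position: tuple[float, float]  # room-local metres


class BeaconPlacement(BaseModel):
    """A beacon fixed at a facility, with its nominal detection range."""

    beacon_id: str
    facility_id: str
    range_m: float = Field(gt=0)


class Room(BaseModel):
    """Rectangular room: local coordinates span [0, width) x [0, height)."""

    id: str
    width_m: float = Field(gt=0)
    height_m: float = Field(gt=0)
    origin: tuple[float, float] = (0.0, 0.0)  # ward-global offset of the door corner

    @field_validator("id")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("room id must be non-empty")
        return v


class WardLayout(BaseModel):
    rooms: list[Room]
    facilities: list[Facility]
    beacons: list[BeaconPlacement]
    associate_radius_m: float = DEFAULT_ASSOCIATE_RADIUS_M

    # -- lookup helpers -------------------------------------------------

    def room(self, room_id: str) -> Room:
        for r in self.rooms:
            if r.id == room_id:
                return r
        raise KeyError(f"unknown room {room_id!r}")

    def facility(self, facility_id: str) -> Facility:
        for f in self.facilities:
            if f.id == facility_id:
                return f
        raise KeyError(f"unknown facility {facility_id!r}")

    def facilities_of_kind(self, kind: FacilityKind) -> list[Facility]:
        return [f for f in self.facilities if f.kind == kind]

    def beacons_in_room(self, room_id: str) -> list[BeaconPlacement]:
        return [b for b in self.beacons if self.facility(b.facility_id).room_id == room_id]

    def room_of_beacon(self, beacon_id: str) -> str:
        return facility_of_beacon(self, beacon_id).room_id

    def global_position(self, facility_id: str) -> tuple[float, float]:
        """Facility position in ward-global coordinates (metres)."""
        f = self.facility(facility_id)
        r = self.room(f.room_id)
        return (r.origin[0] + f.position[0], r.origin[1] + f.position[1])

    # -- validation -----------------------------------------------------

    def validate_invariants(self) -> None:
        """Raise :class:`LayoutError` on the first violated invariant."""
        if not self.rooms:
            raise LayoutError("layout has no rooms")
        room_ids = [r.id for r in self.rooms]
        if len(set(room_ids)) != len(room_ids):
            raise LayoutError("duplicate room ids")

        fac_ids = [f.id for f in self.facilities]
        if len(set(fac_ids)) != len(fac_ids):
            dup = sorted({i for i in fac_ids if fac_ids.count(i) > 1})
            raise LayoutError(f"duplicate facility ids: {dup}")

        by_room_central: dict[str, int] = {}
        for f in self.facilities:
            if f.room_id not in room_ids:
                raise LayoutError(f"facility {f.id!r} references unknown room {f.room_id!r}")
            room = self.room(f.room_id)
            x, y = f.position
            if not (0 <= x <= room.width_m and 0 <= y <= room.height_m):
                raise LayoutError(
                    f"facility {f.id!r} at {f.position} lies outside room "
                    f"{room.id!r} ({room.width_m} x {room.height_m} m)"
                )
            if f.kind == FacilityKind.CENTRAL:
                by_room_central[f.room_id] = by_room_central.get(f.room_id, 0) + 1
        for rid, n in by_room_central.items():
            if n > 1:
                raise LayoutError(f"room {rid!r} has {n} CENTRAL facilities (at most 1)")

        beacon_ids = [b.beacon_id for b in self.beacons]
        if len(set(beacon_ids)) != len(beacon_ids):
            dup = sorted({i for i in beacon_ids if beacon_ids.count(i) > 1})
            raise LayoutError(f"duplicate beacon ids: {dup}")
        for b in self.beacons:
            if b.facility_id not in fac_ids:
                raise LayoutError(
                    f"beacon {b.beacon_id!r} references unknown facility {b.facility_id!r}"
                )

        # every bed must have an ABHR dispenser close enough to be "its" dispenser
        dispensers = self.facilities_of_kind(FacilityKind.DISPENSER)
        for bed in self.facilities_of_kind(FacilityKind.BED):
            near = [
                d
                for d in dispensers
                if d.room_id == bed.room_id
                and _dist(d.position, bed.position) <= self.associate_radius_m
            ]
            if not near:
                raise LayoutError(
                    f"bed {bed.id!r} has no DISPENSER within "
                    f"{self.associate_radius_m} m"
                )


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return ((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2) ** 0.5


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def load_layout(path: str | Path, dialect: str | None = None) -> WardLayout:
    """Load and validate a ward layout from a YAML or JSON file.

    ``dialect`` is ``"YAML"`` or ``"JSON"``; if omitted it is inferred from
    the file suffix (YAML by default — JSON is a YAML subset anyway).

    Raises
    ------
    LayoutFormatError
        if the file cannot be parsed.
    LayoutError
        if a layout invariant is violated, naming the offending entity.
    """
    path = Path(path)
    text = path.read_text()
    dialect = (dialect or ("JSON" if path.suffix.lower() == ".json" else "YAML")).upper()
    try:
        if dialect == "JSON":
            raw = json.loads(text)
        elif dialect == "YAML":
            raw = yaml.safe_load(text)
        else:
            raise ValueError(f"unknown layout dialect {dialect!r}")
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise LayoutFormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise LayoutFormatError(f"{path}: top level must be a mapping")
    try:
        layout = WardLayout.model_validate(raw)
    except Exception as exc:  # pydantic validation error
        raise LayoutError(f"{path}: {exc}") from exc
    layout.validate_invariants()
    return layout


def write_layout(layout: WardLayout, path: str | Path, dialect: str | None = None) -> None:
    """Write a layout so that :func:`load_layout` round-trips it."""
    path = Path(path)
    dialect = (dialect or ("JSON" if path.suffix.lower() == ".json" else "YAML")).upper()
    data = layout.model_dump(mode="json")
    if dialect == "JSON":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Default ICU layout
# ---------------------------------------------------------------------------

# (room id, width, height, global origin, bed x positions)
_DEFAULT_ROOMS: list[tuple[str, float, float, tuple[float, float], list[float]]] = [
    ("R1", 8.0, 6.0, (0.0, 0.0), [1.0, 3.0, 5.0, 7.0]),
    ("R2", 5.0, 6.0, (9.0, 0.0), [1.5, 3.5]),
    ("R3", 5.0, 6.0, (15.0, 0.0), [1.5, 3.5]),
]


def default_icu_layout() -> WardLayout:
    """The three-room ICU ward: one four-bed room and two two-bed rooms.

    Per room: one sink, one ABHR dispenser near the entrance and one at the
    foot of each bed; a beacon at a central point of the room, one (wider
    range) beacon per bed and one beacon per sink and per dispenser.
    Room dimensions and coordinates are modelling choices that make
    distances physically plausible; only facility identity and room
    membership matter to the event-processing rules.
    """
    rooms: list[Room] = []
    facilities: list[Facility] = []
    beacons: list[BeaconPlacement] = []

    def add_beacon(fac: Facility, range_m: float) -> None:
        beacons.append(
            BeaconPlacement(beacon_id=f"B-{fac.id}", facility_id=fac.id, range_m=range_m)
        )

    for room_id, w, h, origin, bed_xs in _DEFAULT_ROOMS:
        rooms.append(Room(id=room_id, width_m=w, height_m=h, origin=origin))

        for i, x in enumerate(bed_xs, start=1):
            bed = Facility(
                id=f"{room_id}-BED{i}", kind=FacilityKind.BED, room_id=room_id, position=(x, 5.0)
            )
            facilities.append(bed)
            add_beacon(bed, range_m=3.0)  # wider range per bed
            disp = Facility(
                id=f"{room_id}-DISP-BED{i}",
                kind=FacilityKind.DISPENSER,
                room_id=room_id,
                position=(x, 4.0),  # foot of the bed
            )
            facilities.append(disp)
            add_beacon(disp, range_m=1.5)

        entrance_disp = Facility(
            id=f"{room_id}-DISP-DOOR",
            kind=FacilityKind.DISPENSER,
            room_id=room_id,
            position=(0.5, 0.5),
        )
        facilities.append(entrance_disp)
        add_beacon(entrance_disp, range_m=1.5)

        sink = Facility(
            id=f"{room_id}-SINK", kind=FacilityKind.SINK, room_id=room_id, position=(w - 1.0, 0.5)
        )
        facilities.append(sink)
        add_beacon(sink, range_m=1.5)

        central = Facility(
            id=f"{room_id}-CENTRAL",
            kind=FacilityKind.CENTRAL,
            room_id=room_id,
            position=(w / 2, 2.5),
        )
        facilities.append(central)
        add_beacon(central, range_m=4.0)

    layout = WardLayout(rooms=rooms, facilities=facilities, beacons=beacons)
    layout.validate_invariants()
    return layout


def facility_of_beacon(layout: WardLayout, beacon_id: str) -> Facility:
    """The facility a beacon marks.  Raises ``KeyError`` for an unknown id."""
    for b in layout.beacons:
        if b.beacon_id == beacon_id:
            return layout.facility(b.facility_id)
    raise KeyError(f"unknown beacon {beacon_id!r}")


def beacon_of_facility(layout: WardLayout, facility_id: str) -> BeaconPlacement:
    """Inverse of :func:`facility_of_beacon` for layouts with one beacon per facility."""
    for b in layout.beacons:
        if b.facility_id == facility_id:
            return b
    raise KeyError(f"no beacon at facility {facility_id!r}")


def iter_beacon_ids(layout: WardLayout) -> Iterable[str]:
    return (b.beacon_id for b in layout.beacons)
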