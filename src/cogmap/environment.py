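"""Virtual-room geometry, stimulus conditions and physical distance measures.

The experimental environment is a square room whose eight camera positions
(*places* P1-P8) lie on the perimeter (four corners plus four side midpoints).
Each snapshot is taken from a place while aiming the camera at one of the same
eight locations used as a target (*view* V1-V8, view != place); the camera's
allocentric compass direction (*heading*) is the 45-degree-quantized bearing
from place to view. Eight wall-mounted *landmarks* (L1-L8) make the four walls
distinguishable; which landmarks appear in a snapshot follows from the camera
position, aiming direction and horizontal field of view.

All metric structure used downstream as regressors or model dissimilarity
matrices -- Euclidean distances between places and between views, angular
heading displacement, shared-landmark similarity and per-place / per-view
landmark distributions -- is derived here from the room model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "COMPASS",
    "RoomModel",
    "SnapshotSpec",
    "StimulusSet",
    "heading_of",
    "place_distance",
    "view_distance",
    "heading_distance",
    "visible_landmarks",
    "landmark_similarity",
    "landmark_distribution",
    "load_room",
    "default_room",
    "default_stimulus_set",
]

#: Compass labels in clockwise order starting from north (+y).
COMPASS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

_COMPASS_DEG = {label: 45.0 * i for i, label in enumerate(COMPASS)}


class UndefinedBearingError(ValueError):
    """Raised when a bearing is requested between coincident points."""


@dataclass(frozen=True)
class RoomModel:
    """Geometry of the square room: places, views, landmarks, headings.

    Parameters
    ----------
    side_length:
        Wall length in room units.
    place_coords:
        Mapping ``P1..P8`` -> 2-D coordinate on the room perimeter.
    view_coords:
        Mapping ``V1..V8`` -> 2-D coordinate; same eight locations as the
        places (a view is a place used as a camera target).
    landmark_positions:
        Mapping ``L1..L8`` -> wall-anchored 2-D coordinate.
    fov:
        Horizontal x vertical field of view of the simulated camera, degrees.
    """

    side_length: float
    place_coords: Mapping[str, np.ndarray]
    view_coords: Mapping[str, np.ndarray]
    landmark_positions: Mapping[str, np.ndarray]
    fov: tuple[float, float] = (74.0, 59.0)
    heading_labels: tuple[str, ...] = COMPASS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        s = self.side_length
        if s <= 0:
            raise ValueError("side_length must be positive")
        p_labels = {lbl[1:] for lbl in self.place_coords}
        v_labels = {lbl[1:] for lbl in self.view_coords}
        if p_labels != v_labels:
            raise ValueError("place and view label sets differ")
        corners = {(0.0, 0.0), (s, 0.0), (s, s), (0.0, s)}
        mids = {(s / 2, 0.0), (s, s / 2), (s / 2, s), (0.0, s / 2)}
        pts = {tuple(np.asarray(c, float)) for c in self.place_coords.values()}
        if pts != corners | mids:
            raise ValueError("places must occupy the 4 corners and 4 side midpoints")
        for lbl, pos in self.landmark_positions.items():
            x, y = np.asarray(pos, float)
            if not (math.isclose(x, 0) or math.isclose(x, s) or math.isclose(y, 0) or math.isclose(y, s)):
                raise ValueError(f"landmark {lbl} does not lie on a wall")

    def heading_degrees(self, label: str) -> float:
        return _COMPASS_DEG[label]


def _bearing(origin: np.ndarray, target: np.ndarray) -> float:
    """Clockwise-from-north bearing from ``origin`` to ``target``, degrees."""
    d = np.asarray(target, float) - np.asarray(origin, float)
    if np.allclose(d, 0):
        raise UndefinedBearingError("bearing undefined for coincident points")
    return float(np.degrees(np.arctan2(d[0], d[1])) % 360.0)


def _quantize_heading(bearing_deg: float) -> str:
    # Round to the nearest 45-degree bin; exact midpoints go to the lower
    # bin index (round-half-down in degree order), deterministically.
    idx = int(math.ceil(bearing_deg / 45.0 - 0.5)) % 8
    return COMPASS[idx]


def heading_of(place: str, view: str, room: RoomModel) -> str:
    """Compass heading of the camera at ``place`` aimed at ``view``.

    Raises
    ------
    UndefinedBearingError
        If ``place`` and ``view`` denote the same location.
    """
    if place[1:] == view[1:]:
        raise UndefinedBearingError(f"heading undefined for {place} -> {view}")
    b = _bearing(room.place_coords[place], room.view_coords[view])
    return _quantize_heading(b)


def place_distance(p: str, q: str, room: RoomModel) -> float:
    """Euclidean distance between two places, in room units."""
    return float(np.linalg.norm(np.asarray(room.place_coords[p], float) - np.asarray(room.place_coords[q], float)))


def view_distance(v: str, w: str, room: RoomModel) -> float:
    """Euclidean distance between two viewed locations, in room units."""
    return float(np.linalg.norm(np.asarray(room.view_coords[v], float) - np.asarray(room.view_coords[w], float)))


def heading_distance(h1: str, h2: str) -> float:
    """Angular displacement between two compass headings, degrees in [0, 180]."""
    d = abs(_COMPASS_DEG[h1] - _COMPASS_DEG[h2]) % 360.0
    return min(d, 360.0 - d)


def visible_landmarks(place: str, view: str, room: RoomModel, fov: float | None = None) -> frozenset[str]:
    """Landmarks inside the camera's horizontal field of view.

    A landmark is visible when its bearing from the camera deviates from the
    aiming direction by at most ``fov / 2``. For any realistic field of view
    (< 180 degrees) this also excludes landmarks behind the camera plane; the
    room is convex and landmarks are wall-mounted, so no further occlusion
    geometry is needed. A landmark coincident with the camera position is
    never visible.
    """
    if fov is None:
        fov = room.fov[0]
    cam = np.asarray(room.place_coords[place], float)
    direction = _bearing(cam, room.view_coords[view])
    half = fov / 2.0
    out = set()
    for lbl, pos in room.landmark_positions.items():
        pos = np.asarray(pos, float)
        if np.allclose(pos, cam):
            continue
        dev = abs(_bearing(cam, pos) - direction) % 360.0
        dev = min(dev, 360.0 - dev)
        if dev <= half:
            out.add(lbl)
    return frozenset(out)


@dataclass(frozen=True)
class SnapshotSpec:
    """One of the 32 stimulus conditions: a (place, view, heading) snapshot."""

    place_id: str
    view_id: str
    heading: str
    visible_landmarks: frozenset[str]
    fov: tuple[float, float] = (74.0, 59.0)

    @property
    def label(self) -> str:
        """Printed-style label, e.g. ``P1V6HS``."""
        return f"{self.place_id}{self.view_id}H{self.heading}"

    @classmethod
    def from_pair(cls, place: str, view: str, room: RoomModel) -> "SnapshotSpec":
        return cls(
            place_id=place,
            view_id=view,
            heading=heading_of(place, view, room),
            visible_landmarks=visible_landmarks(place, view, room),
            fov=(room.fov[0], room.fov[1]),
        )


@dataclass(frozen=True)
class StimulusSet:
    """The ordered collection of stimulus conditions (condition ids 1..n)."""

    snapshots: tuple[SnapshotSpec, ...]
    room: RoomModel = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        pairs = [(s.place_id, s.view_id) for s in self.snapshots]
        if len(set(pairs)) != len(pairs):
            dup = [pv for pv in pairs if pairs.count(pv) > 1][0]
            raise ValueError(f"duplicate snapshot {dup[0]}{dup[1]}")
        places = {s.place_id for s in self.snapshots}
        views = {s.view_id for s in self.snapshots}
        headings = {s.heading for s in self.snapshots}
        if self.room is not None:
            if places != set(self.room.place_coords):
                raise ValueError("not every place appears in the stimulus set")
            if views != set(self.room.view_coords):
                raise ValueError("not every view appears in the stimulus set")
            if headings != set(COMPASS):
                raise ValueError("not every heading appears in the stimulus set")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, condition_id: int) -> SnapshotSpec:
        """Snapshot for a 1-based condition id."""
        return self.snapshots[condition_id - 1]

    @property
    def n_conditions(self) -> int:
        return len(self.snapshots)

    def condition_of(self, place: str, view: str) -> int:
        for i, s in enumerate(self.snapshots, start=1):
            if s.place_id == place and s.view_id == view:
                return i
        raise KeyError(f"no snapshot {place}{view}")

    def groups(self, feature: str) -> dict[str, list[int]]:
        """Condition ids grouped by ``place``, ``view`` or ``heading``."""
        key = {"place": "place_id", "view": "view_id", "heading": "heading"}[feature]
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.snapshots, start=1):
            out.setdefault(getattr(s, key), []).append(i)
        return out

    def pairwise(self, measure: str, texture_table: np.ndarray | None = None) -> np.ndarray:
        """Square condition-by-condition matrix of a pairwise measure.

        ``measure`` is one of ``place``, ``view``, ``heading`` (physical
        distances), ``landmark`` (proportion of non-shared visible landmarks)
        or ``texture`` (requires ``texture_table``).
        """
        n = len(self.snapshots)
        if measure == "texture":
            if texture_table is None:
                raise ValueError("texture measure requires a texture_table")
            return np.asarray(texture_table, float)
        out = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            a, b = self.snapshots[i], self.snapshots[j]
            if measure == "place":
                d = place_distance(a.place_id, b.place_id, self.room)
            elif measure == "view":
                d = view_distance(a.view_id, b.view_id, self.room)
            elif measure == "heading":
                d = heading_distance(a.heading, b.heading)
            elif measure == "landmark":
                d = 1.0 - landmark_similarity(a, b, variant="proportion")
            else:
                raise ValueError(f"unknown measure {measure!r}")
            out[i, j] = out[j, i] = d
        return out


def landmark_similarity(a: SnapshotSpec, b: SnapshotSpec, variant: str = "count") -> float:
    """Shared-visible-landmark similarity between two snapshots.

    ``count`` is the number of shared visible landmarks; ``proportion``
    normalizes by the union of landmarks visible in either image; ``binary``
    is 1 when at least one landmark is shared.
    """
    inter = a.visible_landmarks & b.visible_landmarks
    if variant == "count":
        return float(len(inter))
    if variant == "proportion":
        union = a.visible_landmarks | b.visible_landmarks
        return float(len(inter)) / len(union) if union else 0.0
    if variant == "binary":
        return 1.0 if inter else 0.0
    raise ValueError(f"unknown variant {variant!r}")


def landmark_distribution(entity: str, stimuli: StimulusSet) -> np.ndarray:
    """8-vector of how often each landmark is visible in an entity's snapshots.

    ``entity`` is a place id (``P*``: snapshots taken from there) or a view
    id (``V*``: snapshots aimed there). Element ``k`` counts the snapshots in
    which landmark ``L{k+1}`` is visible.
    """
    if entity.startswith("P"):
        subset = [s for s in stimuli if s.place_id == entity]
    elif entity.startswith("V"):
        subset = [s for s in stimuli if s.view_id == entity]
    else:
        raise KeyError(f"unknown entity id {entity!r}")
    if not subset:
        raise KeyError(f"entity {entity!r} does not appear in the stimulus set")
    out = np.zeros(8)
    for s in subset:
        for lbl in s.visible_landmarks:
            out[int(lbl[1:]) - 1] += 1
    return out


def load_room(path: str | Path | None = None) -> tuple[RoomModel, StimulusSet]:
    """Load a room/stimulus configuration file and validate its invariants.

    The YAML schema has keys ``side_length``, ``fov``, ``places`` (label ->
    [x, y]), ``landmarks`` (label -> [x, y]) and ``snapshots`` (list of
    [place, view] pairs; view labels reuse the place coordinates).
    """
    if path is None:
        with resources.files("cogmap.data").joinpath("room.yaml").open() as fh:
            cfg = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    places = {k: np.asarray(v, float) for k, v in cfg["places"].items()}
    views = {"V" + k[1:]: v.copy() for k, v in places.items()}
    room = RoomModel(
        side_length=float(cfg["side_length"]),
        place_coords=places,
        view_coords=views,
        landmark_positions={k: np.asarray(v, float) for k, v in cfg["landmarks"].items()},
        fov=tuple(cfg.get("fov", (74.0, 59.0))),
    )
    snaps = tuple(SnapshotSpec.from_pair(p, v, room) for p, v in cfg["snapshots"])
    return room, StimulusSet(snapshots=snaps, room=room)


def default_room() -> RoomModel:
    """The packaged reference room."""
    return load_room()[0]


def default_stimulus_set() -> StimulusSet:
    """The packaged reference 32-condition stimulus set."""
    return load_room()[1]
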