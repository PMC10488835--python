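"""Data model for electroanatomical maps.

An electroanatomical map is a triangulated surface reconstruction of a
heart chamber's endocardium with electrical measurements attached to the
surface points: the local activation time (when the depolarisation
wavefront passed the point) and the unipolar voltage amplitude.  Units
are fixed throughout the package: coordinates in mm, activation in ms,
voltage in mV.  With these units a conduction velocity computed as a
length over a time comes out in mm/ms, which is numerically identical to
m/s, so no conversion factors appear anywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

CHAMBERS = ("RA", "LA", "RV", "LV")
WALL_LABELS = ("unlabeled", "anterior", "posterior", "lateral", "septal", "superior")

#: integer codes used when wall labels are stored in numeric scalar arrays
WALL_CODES = {name: i for i, name in enumerate(WALL_LABELS)}


@dataclass
class MapMeta:
    """Acquisition metadata for one map."""

    animal_id: str = ""
    chamber: str = ""
    heart_rate: float = float("nan")  # mean rate over the recording, bpm
    map_id: str = ""
    sex: str = ""

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "chamber": self.chamber,
            "heart_rate": self.heart_rate,
            "map_id": self.map_id,
            "sex": self.sex,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MapMeta":
        return cls(
            animal_id=str(d.get("animal_id", "")),
            chamber=str(d.get("chamber", "")),
            heart_rate=float(d.get("heart_rate", float("nan"))),
            map_id=str(d.get("map_id", "")),
            sex=str(d.get("sex", "")),
        )


class SchemaError(ValueError):
    """A required field is missing or malformed in an on-disk map."""


@dataclass
class SurfaceMap:
    """A triangulated chamber surface with per-vertex scalar fields.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices (0-based)
    activation : (n,) float array, local activation time in ms
    voltage : (n,) float array, unipolar amplitude in mV (non-negative)
    cutout : (n,) bool array; True marks vertices in excluded transition
        zones (vessel ostia, valves, neighbouring chambers)
    wall_label : (n,) array of strings from ``WALL_LABELS``
    meta : MapMeta
    """

    vertices: np.ndarray
    triangles: np.ndarray
    activation: np.ndarray
    voltage: np.ndarray
    cutout: np.ndarray = None
    wall_label: np.ndarray = None
    meta: MapMeta = field(default_factory=MapMeta)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.activation = np.asarray(self.activation, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        n = len(self.vertices)
        if self.cutout is None:
            self.cutout = np.zeros(n, dtype=bool)
        self.cutout = np.asarray(self.cutout, dtype=bool)
        if self.wall_label is None:
            self.wall_label = np.full(n, "unlabeled", dtype=object)
        self.wall_label = np.asarray(self.wall_label, dtype=object)
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        n = len(self.vertices)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise SchemaError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise SchemaError("vertex coordinates must be finite")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise SchemaError("triangles must be an (m, 3) index array")
        t = self.triangles
        if t.size:
            if t.min() < 0 or t.max() >= n:
                raise SchemaError("triangle indices out of range")
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise SchemaError("triangles must reference three distinct vertices")
            if np.any(triangle_areas(self.vertices, t) <= 0):
                raise SchemaError("all triangles must have positive area")
        for name in ("activation", "voltage", "cutout", "wall_label"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise SchemaError(f"{name} must have exactly one value per vertex")
        if not np.all(np.isfinite(self.activation)):
            raise SchemaError("activation values must be finite")
        if np.any(~np.isfinite(self.voltage)) or np.any(self.voltage < 0):
            raise SchemaError("voltage must be finite and non-negative")
        bad = set(np.unique(self.wall_label)) - set(WALL_LABELS)
        if bad:
            raise SchemaError(f"unknown wall labels: {sorted(bad)}")
        if self.meta.chamber and self.meta.chamber not in CHAMBERS:
            raise SchemaError(f"chamber must be one of {CHAMBERS}")

    # -- convenience --------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def cutout_triangles(self) -> np.ndarray:
        """Boolean mask of triangles touching any cutout vertex.

        A triangle is excluded as soon as one of its corners lies in a
        cutout zone: exclusion near transitions is deliberately
        conservative.
        """
        return self.cutout[self.triangles].any(axis=1)

    def transformed(self, rotation: np.ndarray = None, translation=None) -> "SurfaceMap":
        """Return a rigidly transformed copy (scalars unchanged)."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, float).T
        if translation is not None:
            v = v + np.asarray(translation, float)
        return replace(self, vertices=v)


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Areas (mm^2) of each triangle."""
    p = np.asarray(vertices, float)[np.asarray(triangles)]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(cr, axis=1)


def surface_area(surface: SurfaceMap, restrict_to_non_cutout: bool = False) -> float:
    """Total surface area in mm^2.

    With ``restrict_to_non_cutout`` only triangles whose three vertices
    are outside cutout zones are counted (the analysable surface).
    """
    areas = triangle_areas(surface.vertices, surface.triangles)
    if restrict_to_non_cutout:
        areas = areas[~surface.cutout_triangles()]
    return float(areas.sum())


def is_closed(surface: SurfaceMap) -> bool:
    """True iff every edge is shared by exactly two triangles."""
    t = surface.triangles
    if t.size == 0:
        return False
    edges = np.sort(
        np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def enclosed_volume(surface: SurfaceMap) -> float:
    """Volume enclosed by the surface, in mL.

    Uses the divergence theorem (sum of signed tetrahedron volumes
    against the origin) and returns the absolute value, so the result
    does not depend on triangle orientation.  Chamber maps exported from
    mapping systems are not guaranteed to be watertight; for an open
    mesh a warning is emitted and the best-effort value returned.
    """
    if not is_closed(surface):
        warnings.warn(
            "mesh is not closed; enclosed_volume is a best-effort estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    p = surface.vertices[surface.triangles]
    signed_mm3 = np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0
    return abs(float(signed_mm3)) / 1000.0  # mm^3 -> mL
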