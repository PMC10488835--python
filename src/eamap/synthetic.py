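"""Synthetic electroanatomical maps with known ground truth.

The in-vivo maps this pipeline targets are not publicly deposited, so
every stage is exercised against generated data whose generative
parameters are known exactly.  Three layers are provided:

* **Geometry** — flat triangulated sheets (analytic oracles) and
  ellipsoid chambers (icosphere-based closed surfaces standing in for
  atria/ventricles; anatomical realism is a non-goal).
* **Single maps** — activation fields are closed-form wavefronts
  (planar, focal, or two colliding planar fronts), so the true local
  speed is known everywhere; voltage is a per-wall mean plus Gaussian
  noise; cutout disks and wall labels are planted.
* **Studies** — a multi-animal hierarchy matching the mixed model:
  per-animal random intercepts (multiplicative on speed, additive on
  voltage), a linear heart-rate effect, and chamber/wall fixed effects.
  The default design (which animal mapped which chamber at which heart
  rate) follows the reference study overview table.

Default chamber speeds (m/s at 90 bpm) and wall voltage means (mV)
echo the reference study's reported estimates, so a "paper-like"
synthetic study has LA > LV > RV > RA conduction velocities and
LV > RV > LA > RA voltages by construction.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .overview import load_map_overview
from .surface import MapMeta, SurfaceMap
from .walls import allowed_walls

# ---------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------

@dataclass
class FlatSheet:
    """Planar rectangular sheet centred at the origin (z = 0)."""

    width: float = 40.0        # mm, x extent
    height: float = 40.0       # mm, y extent
    edge_length: float = 0.5   # mm, target triangle edge

    kind: str = "flat_sheet"

    def build(self):
        nx = max(int(round(self.width / self.edge_length)), 1)
        ny = max(int(round(self.height / self.edge_length)), 1)
        xs = np.linspace(-self.width / 2, self.width / 2, nx + 1)
        ys = np.linspace(-self.height / 2, self.height / 2, ny + 1)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        idx = np.arange((nx + 1) * (ny + 1)).reshape(nx + 1, ny + 1)
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[1:, 1:].ravel()
        d = idx[:-1, 1:].ravel()
        triangles = np.concatenate(
            [np.column_stack([a, b, c]), np.column_stack([a, c, d])]
        )
        return vertices, triangles


@dataclass
class EllipsoidChamber:
    """Closed ellipsoidal surface standing in for a heart chamber."""

    semi_axes: tuple = (18.0, 20.0, 24.0)  # mm
    subdivisions: int = 4                  # icosphere refinement level

    kind: str = "ellipsoid_chamber"

    def build(self):
        sphere = trimesh.creation.icosphere(subdivisions=self.subdivisions, radius=1.0)
        vertices = np.asarray(sphere.vertices, float) * np.asarray(self.semi_axes, float)
        return vertices, np.asarray(sphere.faces, np.int64)


#: default chamber geometries, sized to juvenile-pig map surface areas
CHAMBER_GEOMETRY = {
    "RA": EllipsoidChamber((18.0, 20.0, 24.0)),
    "LA": EllipsoidChamber((15.0, 16.0, 19.0)),
    "RV": EllipsoidChamber((16.0, 18.0, 22.0)),
    "LV": EllipsoidChamber((15.0, 16.0, 20.0)),
}


# ---------------------------------------------------------------------
# Wavefronts
# ---------------------------------------------------------------------

@dataclass
class PlanarWave:
    """Plane wave: t(x) = (x . n) / v + t0."""

    direction: tuple = (1.0, 0.0, 0.0)
    speed: float = 0.6          # m/s == mm/ms
    t0: float = 0.0             # ms

    kind: str = "planar"

    def activation(self, vertices: np.ndarray) -> np.ndarray:
        n = np.asarray(self.direction, float)
        n = n / np.linalg.norm(n)
        return vertices @ n / self.speed + self.t0


@dataclass
class FocalWave:
    """Focal source: straight-line distance over speed.

    Chord (not geodesic) distance is used, which is exact on flat
    sheets and an approximation on curved geometry — adequate on the
    near-developable patches the circles sample.
    """

    origin: tuple = (0.0, 0.0, 0.0)
    speed: float = 0.6
    t0: float = 0.0

    kind: str = "focal"

    def activation(self, vertices: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(vertices - np.asarray(self.origin, float), axis=1)
        return d / self.speed + self.t0


@dataclass
class CollidingWaves:
    """Two planar fronts; each point takes the earlier arrival.

    Near the collision line the activation spread inside a circle
    collapses, inflating the diameter-over-spread velocity estimate —
    the stress case the >6 m/s outlier rule exists for.
    """

    first: PlanarWave = field(default_factory=lambda: PlanarWave((1, 0, 0), 0.6))
    second: PlanarWave = field(default_factory=lambda: PlanarWave((-1, 0, 0), 0.6))

    kind: str = "colliding"

    def activation(self, vertices: np.ndarray) -> np.ndarray:
        return np.minimum(self.first.activation(vertices), self.second.activation(vertices))


_GEOMETRIES = {"flat_sheet": FlatSheet, "ellipsoid_chamber": EllipsoidChamber}
_WAVES = {"planar": PlanarWave, "focal": FocalWave, "colliding": CollidingWaves}


# ---------------------------------------------------------------------
# Single-map scenario
# ---------------------------------------------------------------------

@dataclass
class MapScenario:
    """Everything needed to generate one map with known truth."""

    geometry: object = field(default_factory=FlatSheet)
    wave: object = field(default_factory=PlanarWave)
    chamber: str = "LA"
    voltage_means: dict = None          # wall -> mV; None = chamber defaults
    voltage_noise_sd: float = 1.0       # mV, iid per vertex
    activation_noise_sd: float = 0.0    # ms, iid per vertex
    cutouts: tuple = ()                 # ((center_xyz, radius_mm), ...)
    label_walls: bool = True
    animal_id: str = "sim"
    map_id: str = "sim-1"
    heart_rate: float = 90.0
    sex: str = "female"
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "MapScenario":
        d = json.loads(text)
        d["geometry"] = _revive(d["geometry"], _GEOMETRIES)
        d["wave"] = _revive(d["wave"], _WAVES)
        if d.get("cutouts"):
            d["cutouts"] = tuple((tuple(c), float(r)) for c, r in d["cutouts"])
        return cls(**d)


def _jsonify(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def _revive(d: dict, registry: dict):
    kind = d.pop("kind")
    cls = registry[kind]
    if cls is CollidingWaves:
        d["first"] = _revive(d["first"], _WAVES)
        d["second"] = _revive(d["second"], _WAVES)
    for key in ("semi_axes", "direction", "origin"):
        if key in d:
            d[key] = tuple(d[key])
    return cls(**d)


#: default wall voltage means (mV), echoing reported chamber/wall levels:
#: uniform within the atria, regionally structured within the ventricles
DEFAULT_VOLTAGE_MEANS = {
    "RA": {"septal": 3.35, "lateral": 3.35, "posterior": 3.35, "superior": 3.35},
    "LA": {"septal": 4.81, "lateral": 4.81, "posterior": 4.81, "anterior": 4.81,
           "superior": 4.81},
    "RV": {"septal": 10.64, "lateral": 6.73, "posterior": 9.59, "anterior": 5.95},
    "LV": {"septal": 11.30, "lateral": 13.48, "posterior": 8.89, "anterior": 11.30},
}


def plant_wall_labels(vertices: np.ndarray, chamber: str, geometry_kind: str) -> np.ndarray:
    """Partition a surface into the chamber's allowed wall segments.

    Ellipsoids: the superior segment (atria only) is the +z polar cap;
    the remaining walls are equal azimuthal sectors.  Flat sheets: equal
    azimuthal sectors around the sheet centre for all allowed walls.
    """
    walls = list(allowed_walls(chamber))
    labels = np.full(len(vertices), "unlabeled", dtype=object)
    azimuth = np.mod(np.arctan2(vertices[:, 1], vertices[:, 0]), 2 * np.pi)
    remaining = np.ones(len(vertices), bool)
    if geometry_kind == "ellipsoid_chamber" and "superior" in walls:
        zmax = np.abs(vertices[:, 2]).max()
        cap = vertices[:, 2] > 0.55 * zmax
        labels[cap] = "superior"
        remaining &= ~cap
        walls = [w for w in walls if w != "superior"]
    k = len(walls)
    sector = np.minimum((azimuth / (2 * np.pi) * k).astype(int), k - 1)
    for i, w in enumerate(walls):
        labels[remaining & (sector == i)] = w
    return labels


def generate_map(scenario: MapScenario):
    """Generate one synthetic map.

    Returns ``(surface, truth)`` where ``truth`` records every
    generative parameter (true wave speed, wall voltage means, noise
    levels, cutout definition).
    """
    vertices, triangles = scenario.geometry.build()
    rng = np.random.default_rng(scenario.seed)
    activation = scenario.wave.activation(vertices)
    if scenario.activation_noise_sd > 0:
        activation = activation + rng.normal(0, scenario.activation_noise_sd, len(vertices))

    if scenario.label_walls:
        wall_label = plant_wall_labels(vertices, scenario.chamber, scenario.geometry.kind)
    else:
        wall_label = np.full(len(vertices), "unlabeled", dtype=object)

    means = scenario.voltage_means or DEFAULT_VOLTAGE_MEANS[scenario.chamber]
    fallback = float(np.mean(list(means.values())))
    mu = np.array([means.get(w, fallback) for w in wall_label], float)
    voltage = mu + rng.normal(0, scenario.voltage_noise_sd, len(vertices))
    voltage = np.clip(voltage, 0.0, None)

    cutout = np.zeros(len(vertices), bool)
    for center, radius in scenario.cutouts:
        cutout |= np.linalg.norm(vertices - np.asarray(center, float), axis=1) < radius
    if cutout.all():
        raise ValueError("cutouts cover every vertex; scenario is inconsistent")

    surface = SurfaceMap(
        vertices=vertices,
        triangles=triangles,
        activation=activation,
        voltage=voltage,
        cutout=cutout,
        wall_label=wall_label,
        meta=MapMeta(
            animal_id=scenario.animal_id,
            chamber=scenario.chamber,
            heart_rate=scenario.heart_rate,
            map_id=scenario.map_id,
            sex=scenario.sex,
        ),
    )
    truth = {
        "map_id": scenario.map_id,
        "animal_id": scenario.animal_id,
        "chamber": scenario.chamber,
        "heart_rate": scenario.heart_rate,
        "sex": scenario.sex,
        "wave_kind": scenario.wave.kind,
        "true_speed": getattr(scenario.wave, "speed", float("nan")),
        "voltage_means": dict(means),
        "voltage_noise_sd": scenario.voltage_noise_sd,
        "activation_noise_sd": scenario.activation_noise_sd,
        "n_cutouts": len(scenario.cutouts),
        "seed": scenario.seed,
    }
    return surface, truth


# ---------------------------------------------------------------------
# Multi-animal study
# ---------------------------------------------------------------------

#: chamber mean conduction velocities (m/s at 90 bpm) planted by default
DEFAULT_CV_MEANS = {"LA": 0.79, "LV": 0.59, "RV": 0.54, "RA": 0.50}


@dataclass
class StudyScenario:
    """A multi-animal mapping study with a planted hierarchy.

    Per-map wave speed is ``chamber mean * exp(animal intercept) *
    exp(slope_log_cv * (HR - 90))``; wall voltage means are shifted
    additively by the animal intercept and the heart-rate effect.  The
    default design table replays the reference study layout (animal,
    chamber, heart rate, sex per map).
    """

    design: pd.DataFrame = None         # columns: animal_id, chamber, heart_rate, map_id, sex
    cv_means: dict = field(default_factory=lambda: dict(DEFAULT_CV_MEANS))
    voltage_means: dict = None          # chamber -> wall -> mV
    animal_sd_log_cv: float = 0.10      # random-intercept sd, log m/s
    animal_sd_va: float = 0.80          # random-intercept sd, mV
    slope_log_cv: float = -0.002        # per bpm (mild rate-dependent slowing)
    slope_va: float = -0.010            # mV per bpm
    voltage_noise_sd: float = 1.0       # mV per vertex
    activation_noise_sd: float = 0.0    # ms per vertex
    subdivisions: int = 4
    with_cutouts: bool = True
    wave_direction: tuple | None = None  # None: a fresh direction per map
    seed: int = 0

    def resolved_design(self) -> pd.DataFrame:
        if self.design is not None:
            d = self.design.copy()
        else:
            ov = load_map_overview()
            d = ov[["animal_id", "chamber", "heart_rate", "map_id", "sex"]].copy()
        if d["animal_id"].nunique() < 2:
            raise ValueError("study needs at least 2 animals for the mixed model")
        return d.reset_index(drop=True)


def generate_study(scenario: StudyScenario):
    """Generate every map of a study plus its ground-truth table.

    Returns ``(maps, truth_table)``: a list of :class:`SurfaceMap` and a
    DataFrame with one row per map listing every generative parameter
    (planted speed, animal intercepts, effective voltage means).
    """
    design = scenario.resolved_design()
    rng = np.random.default_rng(scenario.seed)
    animals = sorted(design["animal_id"].astype(str).unique())
    b_cv = {a: rng.normal(0, scenario.animal_sd_log_cv) for a in animals}
    b_va = {a: rng.normal(0, scenario.animal_sd_va) for a in animals}
    vmeans = scenario.voltage_means or DEFAULT_VOLTAGE_MEANS

    maps, truth_rows = [], []
    for _, row in design.iterrows():
        chamber = str(row["chamber"])
        animal = str(row["animal_id"])
        hr = float(row["heart_rate"])
        speed = (
            scenario.cv_means[chamber]
            * np.exp(b_cv[animal])
            * np.exp(scenario.slope_log_cv * (hr - 90.0))
        )
        shift = b_va[animal] + scenario.slope_va * (hr - 90.0)
        wall_means = {w: max(m + shift, 0.1) for w, m in vmeans[chamber].items()}
        geom = CHAMBER_GEOMETRY[chamber]
        geom = EllipsoidChamber(geom.semi_axes, scenario.subdivisions)
        if scenario.wave_direction is not None:
            direction = np.asarray(scenario.wave_direction, float)
        else:
            direction = rng.normal(size=3)
        direction = direction / np.linalg.norm(direction)
        cutouts = ()
        if scenario.with_cutouts:
            pole = np.array([0.0, 0.0, geom.semi_axes[2]])
            cutouts = ((tuple(pole), 6.0),)
        map_seed = int(rng.integers(0, 2**31 - 1))
        ms = MapScenario(
            geometry=geom,
            wave=PlanarWave(tuple(direction), float(speed)),
            chamber=chamber,
            voltage_means=wall_means,
            voltage_noise_sd=scenario.voltage_noise_sd,
            activation_noise_sd=scenario.activation_noise_sd,
            cutouts=cutouts,
            animal_id=animal,
            map_id=str(row.get("map_id", f"{animal}-{chamber}")),
            heart_rate=hr,
            sex=str(row.get("sex", "")),
            seed=map_seed,
        )
        surface, truth = generate_map(ms)
        truth["animal_intercept_log_cv"] = b_cv[animal]
        truth["animal_intercept_va"] = b_va[animal]
        truth["chamber_cv_mean_90bpm"] = scenario.cv_means[chamber]
        truth["slope_log_cv"] = scenario.slope_log_cv
        truth["slope_va"] = scenario.slope_va
        maps.append(surface)
        truth_rows.append(truth)
    return maps, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------
# Measurement-level sampler (statistics oracles)
# ---------------------------------------------------------------------

def sample_measurement_table(
    design: pd.DataFrame = None,
    circles_per_map: int = 40,
    cv_means: dict = None,
    va_means: dict = None,
    slope_log_cv: float = -0.002,
    slope_va: float = -0.010,
    sex_effect_log_cv: float = 0.0,
    sex_effect_va: float = 0.0,
    animal_sd_log_cv: float = 0.10,
    animal_sd_va: float = 0.80,
    resid_sd_log_cv: float = 0.30,
    resid_sd_va: float = 2.0,
    seed: int = 0,
):
    """Draw circle measurements directly from the mixed model.

    Bypasses the mesh pipeline: each row is one circle with
    ``log cv = log(chamber mean) + slope*(HR-90) + sex effect + animal
    intercept + residual`` (and the additive analogue for voltage).
    This is the fast sampler used for parameter-recovery and coverage
    simulations, where thousands of model fits are needed.

    Returns ``(table, truth)``; ``truth`` maps every generative
    parameter name to its value.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = load_map_overview()[["animal_id", "chamber", "heart_rate", "map_id", "sex"]]
    design = design.reset_index(drop=True)
    cv_means = dict(cv_means or DEFAULT_CV_MEANS)
    va_means = dict(
        va_means or {c: float(np.mean(list(w.values()))) for c, w in DEFAULT_VOLTAGE_MEANS.items()}
    )
    animals = sorted(design["animal_id"].astype(str).unique())
    b_cv = {a: rng.normal(0, animal_sd_log_cv) for a in animals}
    b_va = {a: rng.normal(0, animal_sd_va) for a in animals}
    rows = []
    for _, m in design.iterrows():
        a, c, hr = str(m["animal_id"]), str(m["chamber"]), float(m["heart_rate"])
        sex = str(m.get("sex", "female"))
        s = 1.0 if sex == "male" else 0.0
        mu_log = np.log(cv_means[c]) + slope_log_cv * (hr - 90) + s * sex_effect_log_cv + b_cv[a]
        mu_va = va_means[c] + slope_va * (hr - 90) + s * sex_effect_va + b_va[a]
        log_cv = mu_log + rng.normal(0, resid_sd_log_cv, circles_per_map)
        va = np.clip(mu_va + rng.normal(0, resid_sd_va, circles_per_map), 0.0, None)
        for j in range(circles_per_map):
            rows.append(
                {
                    "map_id": str(m.get("map_id", f"{a}-{c}")),
                    "animal_id": a,
                    "chamber": c,
                    "wall_assignment": None,
                    "heart_rate": hr,
                    "sex": sex,
                    "cv": float(np.exp(log_cv[j])),
                    "va": float(va[j]),
                    "valid": True,
                    "exclusion_reason": "none",
                }
            )
    truth = {
        "cv_means": cv_means,
        "va_means": va_means,
        "slope_log_cv": slope_log_cv,
        "slope_va": slope_va,
        "sex_effect_log_cv": sex_effect_log_cv,
        "sex_effect_va": sex_effect_va,
        "animal_sd_log_cv": animal_sd_log_cv,
        "animal_sd_va": animal_sd_va,
        "resid_sd_log_cv": resid_sd_log_cv,
        "resid_sd_va": resid_sd_va,
    }
    return pd.DataFrame(rows), truth
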