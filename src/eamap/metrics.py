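"""Per-circle conduction velocity and voltage amplitude.

The local conduction velocity of a circular patch is estimated as the
theoretical circle diameter — recovered from the *actual* clipped
surface area as ``2 * sqrt(area / pi)`` — divided by the spread of
activation times within the patch::

    cv = 2 * sqrt(area / pi) / (t_last - t_first)

With areas in mm^2 and times in ms this is mm/ms, numerically equal to
m/s.  For a planar wavefront crossing a flat circular patch the first
and last activations sit at opposite ends of the diameter along the
propagation direction, so the estimator is exact in the continuum
limit; colliding wavefronts inside a patch compress the activation
spread and inflate the estimate, which is what the >6 m/s outlier rule
screens for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .circles import CirclePatch
from .surface import MapMeta

#: circles faster than this are physiologically implausible and dropped
CV_OUTLIER_THRESHOLD = 6.0  # m/s


@dataclass
class CircleMeasurement:
    """The analysis unit: one circle's CV and VA with its grouping keys."""

    map_id: str
    animal_id: str
    chamber: str
    wall_assignment: str | None
    heart_rate: float
    sex: str
    cv: float          # m/s (nan when undefined)
    va: float          # mV
    area_mm2: float
    n_points: int
    valid: bool = True
    exclusion_reason: str = "none"   # none | cv_outlier | zero_dt | empty


def conduction_velocity(area: float, dt: float) -> float:
    """Circle-diameter-over-activation-spread velocity estimate (m/s).

    ``area`` is the clipped patch area in mm^2 and ``dt`` the first-to-
    last activation difference in ms.  ``dt == 0`` yields ``nan`` (the
    circle is excluded downstream with reason ``zero_dt``), never an
    infinity.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return float("nan")
    return 2.0 * math.sqrt(area / math.pi) / dt


def measure_circles(patches: list[CirclePatch], meta: MapMeta) -> list[CircleMeasurement]:
    """Turn clipped patches into per-circle measurements.

    One measurement per non-empty patch; map metadata is copied onto
    every row.  Circles with zero activation spread are flagged invalid
    (``zero_dt``); the velocity outlier rule is applied separately by
    :func:`apply_outlier_filter`.
    """
    out = []
    for patch in patches:
        if patch.is_empty:
            continue
        dt = patch.dt
        cv = conduction_velocity(patch.area, dt)
        valid = dt > 0
        out.append(
            CircleMeasurement(
                map_id=meta.map_id,
                animal_id=meta.animal_id,
                chamber=meta.chamber,
                wall_assignment=patch.wall_assignment,
                heart_rate=meta.heart_rate,
                sex=meta.sex,
                cv=cv,
                va=patch.mean_voltage,
                area_mm2=patch.area,
                n_points=patch.n_points,
                valid=valid,
                exclusion_reason="none" if valid else "zero_dt",
            )
        )
    return out


def apply_outlier_filter(measurements: list[CircleMeasurement],
                         threshold: float = CV_OUTLIER_THRESHOLD):
    """Flag circles with cv strictly above ``threshold`` as outliers.

    Returns ``(flagged_measurements, exclusion_log)`` where the log is a
    DataFrame counting exclusions per map and reason.  Measurements at
    exactly the threshold are kept (the rule is a strict ``>``).
    """
    flagged = []
    for m in measurements:
        if m.valid and m.cv > threshold:
            flagged.append(replace(m, valid=False, exclusion_reason="cv_outlier"))
        else:
            flagged.append(m)
    log = (
        pd.DataFrame(
            [(m.map_id, m.exclusion_reason) for m in flagged],
            columns=["map_id", "exclusion_reason"],
        )
        .value_counts()
        .rename("n_circles")
        .reset_index()
        .sort_values(["map_id", "exclusion_reason"])
        .reset_index(drop=True)
    )
    return flagged, log


def measurements_to_frame(measurements: list[CircleMeasurement]) -> pd.DataFrame:
    """Tabulate measurements (one row per circle) for stats and export."""
    return pd.DataFrame(
        {
            "map_id": [m.map_id for m in measurements],
            "animal_id": [m.animal_id for m in measurements],
            "chamber": [m.chamber for m in measurements],
            "wall_assignment": [m.wall_assignment for m in measurements],
            "heart_rate": [m.heart_rate for m in measurements],
            "sex": [m.sex for m in measurements],
            "cv": [m.cv for m in measurements],
            "va": [m.va for m in measurements],
            "area_mm2": [m.area_mm2 for m in measurements],
            "n_points": [m.n_points for m in measurements],
            "valid": [m.valid for m in measurements],
            "exclusion_reason": [m.exclusion_reason for m in measurements],
        }
    )
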