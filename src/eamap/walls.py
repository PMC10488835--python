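"""Stratification of circles by anatomical wall segment.

Each chamber is partitioned into wall segments — septal, lateral,
posterior and anterior, plus a superior segment for the atria (the
right atrium has no anterior segment).  Wall labels are an input
annotation carried per vertex; this module only decides which segment,
if any, a circle belongs to.
"""

from __future__ import annotations

import warnings

import numpy as np

from .circles import CirclePatch
from .surface import SurfaceMap

ALLOWED_WALLS = {
    "RA": ("septal", "lateral", "posterior", "superior"),
    "LA": ("septal", "lateral", "posterior", "anterior", "superior"),
    "RV": ("septal", "lateral", "posterior", "anterior"),
    "LV": ("septal", "lateral", "posterior", "anterior"),
}


def allowed_walls(chamber: str) -> tuple[str, ...]:
    """Wall segments defined for a chamber."""
    try:
        return ALLOWED_WALLS[chamber]
    except KeyError:
        raise ValueError(f"unknown chamber {chamber!r}") from None


def assign_wall(patch: CirclePatch, surface: SurfaceMap, rule: str = "strict") -> str | None:
    """Assign a wall segment to a circle, or ``None``.

    ``strict`` (default): the circle gets label W iff *every* covered
    vertex carries wall label W — the circle lies entirely within one
    segment, and straddling circles take part in whole-map analysis
    only.  ``majority``: the label of more than half the covered
    vertices, else ``None``.
    """
    if rule not in ("strict", "majority"):
        raise ValueError(f"unknown wall rule {rule!r}")
    ids = patch.covered_vertex_ids
    if len(ids) == 0:
        return None
    labels = surface.wall_label[ids]
    if np.all(labels == "unlabeled"):
        return None
    if rule == "strict":
        first = labels[0]
        if first != "unlabeled" and np.all(labels == first):
            return _checked(first, surface)
        return None
    values, counts = np.unique(labels.astype(str), return_counts=True)
    best = counts.argmax()
    if values[best] != "unlabeled" and counts[best] > len(ids) / 2:
        return _checked(values[best], surface)
    return None


def _checked(label: str, surface: SurfaceMap) -> str | None:
    chamber = surface.meta.chamber
    if chamber and label not in allowed_walls(chamber):
        raise ValueError(f"wall label {label!r} is not defined for chamber {chamber}")
    return str(label)


def assign_walls(patches: list[CirclePatch], surface: SurfaceMap,
                 rule: str = "strict") -> list[CirclePatch]:
    """Assign wall segments in place for a list of patches.

    Emits a single warning (and assigns ``None`` throughout) when the
    map carries no wall labels at all.
    """
    if np.all(surface.wall_label == "unlabeled"):
        warnings.warn(
            "map carries no wall labels; all wall assignments are None",
            RuntimeWarning,
            stacklevel=2,
        )
    for p in patches:
        p.wall_assignment = assign_wall(p, surface, rule=rule)
    return patches
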