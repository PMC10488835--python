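"""Circular sampling regions on the mapped surface.

Local conduction velocity and voltage are estimated over overlapping,
roughly circular patches of the curved chamber surface: the intersection
of the triangulated surface with a Euclidean ball of radius ~5 mm.  The
intersection is computed as an iso-clip of the linearly interpolated
distance-to-centre field at level = radius — triangle edges crossing the
level are split at the interpolated point, and all scalar fields are
linearly interpolated at the split points.  On the low-curvature patches
of a chamber wall this clipped region is close to a geodesic disk, and
its area is close to pi r^2 (a flat sheet recovers pi r^2 exactly in the
fine-mesh limit).

Circle centres are placed by greedy farthest-point sampling over the
non-cutout vertices: a deterministic covering whose density is set by a
single ``spacing`` parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surface import SurfaceMap


@dataclass
class CirclePatch:
    """One sphere-clipped circular region of the analysable surface.

    ``area`` is the clipped surface area (mm^2); ``t_first``/``t_last``
    are the activation extrema over the covered vertices and the
    interpolated clip-boundary points; ``mean_voltage`` is the
    area-weighted mean of the linearly interpolated voltage over the
    clipped patch; ``n_points`` counts original measurement points
    (vertices) strictly inside the ball.
    """

    center: np.ndarray
    radius: float
    area: float = 0.0
    covered_vertex_ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    t_first: float = float("nan")
    t_last: float = float("nan")
    mean_voltage: float = float("nan")
    n_points: int = 0
    wall_assignment: str | None = None

    @property
    def is_empty(self) -> bool:
        return self.area <= 0.0

    @property
    def dt(self) -> float:
        """Activation spread t_last - t_first (ms)."""
        return self.t_last - self.t_first


class CutoutCenterError(ValueError):
    """The requested circle centre lies on a cutout vertex."""


def clip_ball(surface: SurfaceMap, center, radius: float,
              voltage_aggregation: str = "area_weighted") -> CirclePatch:
    """Clip the non-cutout surface with a Euclidean ball.

    Parameters
    ----------
    center : 3-vector (mm)
    radius : ball radius (mm), > 0
    voltage_aggregation : ``"area_weighted"`` (integral of the linear
        voltage field over the clipped patch divided by its area) or
        ``"vertex_mean"`` (plain mean over covered vertices).

    Returns an empty-patch marker (``area == 0``) when the ball misses
    the surface entirely; raises :class:`CutoutCenterError` when the
    centre coincides with a cutout vertex.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if voltage_aggregation not in ("area_weighted", "vertex_mean"):
        raise ValueError(f"unknown voltage_aggregation {voltage_aggregation!r}")
    center = np.asarray(center, float)
    v = surface.vertices
    d = np.linalg.norm(v - center, axis=1)
    on_vertex = d < 1e-9
    if np.any(on_vertex & surface.cutout):
        raise CutoutCenterError("circle centre lies on a cutout vertex")

    keep = ~surface.cutout_triangles()
    tri = surface.triangles[keep]
    if tri.size == 0:
        return CirclePatch(center=center, radius=radius)

    s = d[tri] - radius                      # signed level-set value per corner
    inside = s <= 0.0
    n_in = inside.sum(axis=1)

    act = surface.activation
    volt = surface.voltage

    total_area = 0.0
    volt_integral = 0.0
    t_values: list[np.ndarray] = []

    # fully inside triangles contribute whole
    full = tri[n_in == 3]
    if len(full):
        a, vi = _tri_area_and_integral(v[full], volt[full])
        total_area += a.sum()
        volt_integral += vi.sum()

    # partially covered triangles: clip to polygon
    for count in (1, 2):
        mask = n_in == count
        if not mask.any():
            continue
        t3 = tri[mask]
        s3 = s[mask]
        in3 = inside[mask]
        # rotate each triangle so that the "odd" vertex is first:
        # count==1 -> the single inside vertex first; count==2 -> the
        # single outside vertex first.
        odd = in3 if count == 1 else ~in3
        first = np.argmax(odd, axis=1)
        rot = (first[:, None] + np.arange(3)[None, :]) % 3
        rows = np.arange(len(t3))[:, None]
        t3 = t3[rows, rot]
        s3 = s3[rows, rot]
        pa, pb, pc = v[t3[:, 0]], v[t3[:, 1]], v[t3[:, 2]]
        sa, sb, sc = s3[:, 0], s3[:, 1], s3[:, 2]
        # crossing points on edges a-b and a-c
        tab = sa / (sa - sb)
        tac = sa / (sa - sc)
        p_ab = pa + tab[:, None] * (pb - pa)
        p_ac = pa + tac[:, None] * (pc - pa)
        for arr, name in ((act, "t"), (volt, "v")):
            f_ab = arr[t3[:, 0]] + tab * (arr[t3[:, 1]] - arr[t3[:, 0]])
            f_ac = arr[t3[:, 0]] + tac * (arr[t3[:, 2]] - arr[t3[:, 0]])
            if name == "t":
                t_ab, t_ac = f_ab, f_ac
            else:
                v_ab, v_ac = f_ab, f_ac
        t_values.extend([t_ab, t_ac])
        if count == 1:
            # inside corner + two crossing points
            pts = np.stack([pa, p_ab, p_ac], axis=1)
            vv = np.stack([volt[t3[:, 0]], v_ab, v_ac], axis=1)
            a, vi = _tri_area_and_integral(pts, vv)
            total_area += a.sum()
            volt_integral += vi.sum()
        else:
            # quad (b, c, p_ac, p_ab) split into two triangles
            for corners, vcorn in (
                ((pb, pc, p_ac), (volt[t3[:, 1]], volt[t3[:, 2]], v_ac)),
                ((pb, p_ac, p_ab), (volt[t3[:, 1]], v_ac, v_ab)),
            ):
                pts = np.stack(corners, axis=1)
                vv = np.stack(vcorn, axis=1)
                a, vi = _tri_area_and_integral(pts, vv)
                total_area += a.sum()
                volt_integral += vi.sum()

    if total_area <= 0.0:
        return CirclePatch(center=center, radius=radius)

    used = np.zeros(surface.n_vertices, bool)
    used[tri[n_in > 0].ravel()] = True
    covered = np.flatnonzero(used & (d <= radius) & ~surface.cutout)
    strictly_inside = covered[d[covered] < radius]
    t_all = np.concatenate([act[covered]] + t_values) if len(covered) else np.concatenate(t_values)
    if voltage_aggregation == "area_weighted":
        mean_voltage = volt_integral / total_area
    else:
        mean_voltage = float(volt[covered].mean()) if len(covered) else float("nan")
    return CirclePatch(
        center=center,
        radius=radius,
        area=float(total_area),
        covered_vertex_ids=covered,
        t_first=float(t_all.min()),
        t_last=float(t_all.max()),
        mean_voltage=float(mean_voltage),
        n_points=int(len(strictly_inside)),
    )


def _tri_area_and_integral(pts: np.ndarray, corner_vals: np.ndarray):
    """Areas and linear-field integrals for stacked triangles.

    ``pts``: (k, 3, 3) corner coordinates; ``corner_vals``: (k, 3).
    For a linear field on a triangle, integral = area * mean(corners).
    """
    cr = np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0])
    areas = 0.5 * np.linalg.norm(cr, axis=1)
    return areas, areas * corner_vals.mean(axis=1)


def sample_centers(surface: SurfaceMap, radius: float = 5.0, spacing: float = 5.0,
                   seed: int = 0) -> np.ndarray:
    """Greedy farthest-point sampling of circle centres.

    Starting from a seed-chosen non-cutout vertex, repeatedly picks the
    vertex farthest from all chosen centres, until that farthest
    distance drops below ``spacing``.  The result is a deterministic
    covering: every non-cutout vertex lies within ``spacing`` of some
    centre, and centres are pairwise at least ``spacing`` apart.  The
    seed picks the initial vertex and breaks exact distance ties.

    Returns an (k, 3) array of centre coordinates (a subset of the mesh
    vertices); empty when every vertex is a cutout.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    candidates = np.flatnonzero(~surface.cutout)
    if len(candidates) == 0:
        return np.empty((0, 3))
    pts = surface.vertices[candidates]
    rng = np.random.default_rng(seed)
    # tie-break priority: random permutation rank per candidate
    priority = rng.permutation(len(candidates))
    chosen = [int(priority.argmin())]
    mind = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    while True:
        far = mind.max()
        if far < spacing:
            break
        tied = np.flatnonzero(mind >= far - 1e-12)
        nxt = int(tied[priority[tied].argmin()])
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[np.array(chosen)]


def cover_map(surface: SurfaceMap, radius: float = 5.0, spacing: float = 5.0,
              seed: int = 0, voltage_aggregation: str = "area_weighted"):
    """Cover the analysable surface with overlapping circular patches.

    Runs :func:`sample_centers` then :func:`clip_ball` per centre,
    dropping empty patches.  Returns ``(patches, summary)`` where
    ``summary`` holds per-map aggregates (circle count, mean patch area,
    mean points per circle).
    """
    centers = sample_centers(surface, radius=radius, spacing=spacing, seed=seed)
    patches = []
    for c in centers:
        p = clip_ball(surface, c, radius, voltage_aggregation=voltage_aggregation)
        if not p.is_empty:
            patches.append(p)
    summary = {
        "n_circles": len(patches),
        "mean_circle_area_mm2": float(np.mean([p.area for p in patches])) if patches else float("nan"),
        "mean_points_per_circle": float(np.mean([p.n_points for p in patches])) if patches else float("nan"),
    }
    return patches, summary
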