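"""The reference study overview table.

A packaged per-map overview of the porcine mapping study this pipeline
was designed around: 21 sinus-rhythm maps from four animals, with the
mapped chamber, mean heart rate (bpm), number of recorded measurement
points, map volume (mL) and circle counts for the whole map and per
wall segment.  It serves two purposes: study-level aggregates are
recomputed from it through the same summary code path used for any
analysed map set, and it provides the default multi-animal design
(animal, chamber, heart rate) for the synthetic study generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: animals known to be female in the reference study
FEMALE_ANIMALS = ("3", "5")

WALL_COUNT_COLUMNS = [
    "circles_lateral",
    "circles_septal",
    "circles_posterior",
    "circles_anterior",
    "circles_superior",
]


def load_map_overview() -> pd.DataFrame:
    """Per-map overview table (one row per map)."""
    with resources.files("eamap.data").joinpath("map_overview.csv").open() as fh:
        df = pd.read_csv(fh)
    df["animal_id"] = df["animal_id"].astype(str)
    df["map_id"] = df["animal_id"] + "-" + df["map_nr"].astype(str)
    df["sex"] = ["female" if a in FEMALE_ANIMALS else "male" for a in df["animal_id"]]
    return df


def summarize_maps(per_map: pd.DataFrame) -> dict:
    """Study-level aggregates from a per-map summary table.

    Expects at least ``n_points`` and ``n_circles`` columns (the shape
    produced both by :func:`load_map_overview` and by the analysis
    pipeline's per-map summaries) and averages whatever of the known
    summary columns are present.
    """
    out = {"n_maps": int(len(per_map))}
    for col, name in [
        ("n_points", "mean_points_per_map"),
        ("n_circles", "mean_circles_per_map"),
        ("volume_ml", "mean_volume_ml"),
        ("mean_circle_area_mm2", "mean_circle_area_mm2"),
        ("mean_points_per_circle", "mean_points_per_circle"),
    ]:
        if col in per_map.columns:
            out[name] = float(per_map[col].mean())
            out[name + "_sd"] = float(per_map[col].std(ddof=1))
    if {"mean_points_per_circle", "mean_circle_area_mm2"} <= set(per_map.columns):
        # resolution: points per mm^2 of mapped surface
        out["resolution_points_per_mm2"] = float(
            per_map["mean_points_per_circle"].mean()
            / per_map["mean_circle_area_mm2"].mean()
        )
    return out
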