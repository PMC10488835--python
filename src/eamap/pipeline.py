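"""End-to-end orchestration: maps in, measurement tables and reports out.

`analyze_map` runs the geometric stage for one map (circle placement,
sphere clipping, wall assignment, CV/VA measurement, outlier rule) and
`analyze_study` concatenates many maps into the analysis table the
statistics stage consumes.  `run_stats` fits the chamber-level mixed
models, EMMs, contrasts and correlations, and renders them as JSON plus
a human-readable text report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import circles, metrics, overview, stats, walls
from .surface import SurfaceMap, enclosed_volume, is_closed, surface_area


@dataclass
class PipelineConfig:
    """Analysis knobs; the defaults are the reference protocol."""

    radius_mm: float = 5.0
    spacing_mm: float = 5.0
    cv_outlier_threshold: float = 6.0       # m/s, strict >
    reference_heart_rate: float = 90.0      # bpm
    cv_correlation_cap: float = 1.5         # m/s
    wall_rule: str = "strict"               # strict | majority
    voltage_aggregation: str = "area_weighted"
    df_method: str = "between_within"       # between_within | normal
    seed: int = 0

    def __post_init__(self):
        for name in ("radius_mm", "spacing_mm", "cv_outlier_threshold",
                     "reference_heart_rate", "cv_correlation_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def analyze_map(surface: SurfaceMap, config: PipelineConfig = None):
    """Circle-based analysis of one map.

    Returns ``(measurements, summary)``: a list of
    :class:`~eamap.metrics.CircleMeasurement` (outlier rule applied) and
    a per-map summary dict (point/circle counts, mean circle area,
    resolution in points/mm^2, enclosed volume).
    """
    config = config or PipelineConfig()
    patches, cover_summary = circles.cover_map(
        surface,
        radius=config.radius_mm,
        spacing=config.spacing_mm,
        seed=config.seed,
        voltage_aggregation=config.voltage_aggregation,
    )
    walls.assign_walls(patches, surface, rule=config.wall_rule)
    measurements = metrics.measure_circles(patches, surface.meta)
    measurements, exclusion_log = metrics.apply_outlier_filter(
        measurements, threshold=config.cv_outlier_threshold
    )
    mean_ppc = cover_summary["mean_points_per_circle"]
    mean_area = cover_summary["mean_circle_area_mm2"]
    summary = {
        "map_id": surface.meta.map_id,
        "animal_id": surface.meta.animal_id,
        "chamber": surface.meta.chamber,
        "heart_rate": surface.meta.heart_rate,
        "n_points": surface.n_vertices,
        "n_circles": cover_summary["n_circles"],
        "mean_circle_area_mm2": mean_area,
        "mean_points_per_circle": mean_ppc,
        "resolution_points_per_mm2": (
            mean_ppc / mean_area if mean_area and np.isfinite(mean_area) else float("nan")
        ),
        "surface_area_mm2": surface_area(surface, restrict_to_non_cutout=True),
        "volume_ml": enclosed_volume(surface) if is_closed(surface) else float("nan"),
        "n_excluded": int(sum(not m.valid for m in measurements)),
    }
    return measurements, summary, exclusion_log


def analyze_study(maps: list[SurfaceMap], config: PipelineConfig = None):
    """Analyse a set of maps into one measurement table.

    Returns ``(table, per_map_summaries, study_summary)``.
    """
    if not maps:
        raise ValueError("no maps to analyse")
    config = config or PipelineConfig()
    all_measurements, summaries = [], []
    for surface in maps:
        m, s, _ = analyze_map(surface, config)
        all_measurements.extend(m)
        summaries.append(s)
    table = metrics.measurements_to_frame(all_measurements)
    per_map = pd.DataFrame(summaries)
    return table, per_map, overview.summarize_maps(per_map)


def run_stats(table: pd.DataFrame, config: PipelineConfig = None) -> dict:
    """Chamber-level statistics on a measurement table.

    Fits the log-CV and VA mixed models, EMMs at the reference heart
    rate, Tukey-adjusted all-pairs contrasts, the sex test (when both
    sexes are present) and the correlation layer (overall, per chamber,
    and per chamber below the CV cap).
    """
    config = config or PipelineConfig()
    if table["animal_id"].nunique() < 2:
        raise stats.IdentifiabilityError(
            "statistics need maps from at least 2 animals"
        )
    report: dict = {"config": asdict(config)}
    for response in ("log_cv", "va"):
        model = stats.fit_mixed_model(table, response, df_method=config.df_method)
        emm = stats.emm_at(model, heart_rate=config.reference_heart_rate)
        contrasts = stats.pairwise_contrasts(
            model, heart_rate=config.reference_heart_rate
        )
        report[response] = {
            "fixed_effects": {
                k: {"estimate": float(model.params[k]),
                    "se": float(np.sqrt(model.cov_params.loc[k, k]))}
                for k in model.params.index
            },
            "random_intercept_var": model.random_intercept_var,
            "residual_var": model.residual_var,
            "singular": model.singular,
            "converged": model.converged,
            "emm": emm.to_dict(orient="records"),
            "contrasts": contrasts.to_dict(orient="records"),
        }
    if table["sex"].astype(str).nunique() >= 2:
        report["sex_effect_p"] = {
            resp: stats.sex_effect_test(table, resp, df_method=config.df_method)[0]
            for resp in ("log_cv", "va")
        }
    chambers = sorted(table["chamber"].astype(str).unique())
    corr: dict = {}
    for scope in ["overall"] + chambers:
        try:
            corr[scope] = vars(stats.pearson_correlation(table, scope))
            corr[scope]["interpretation"] = stats.pearson_correlation(
                table, scope
            ).interpretation
        except ValueError:
            continue
        try:
            res = stats.pearson_correlation(table, scope, cv_cap=config.cv_correlation_cap)
            corr[f"{scope}_cv<{config.cv_correlation_cap:g}"] = {
                **vars(res), "interpretation": res.interpretation
            }
        except ValueError:
            pass
    report["correlations"] = corr
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering: estimate ± SE (p) throughout."""
    lines = []
    for response, label, unit in (("log_cv", "Conduction velocity", "m/s"),
                                  ("va", "Voltage amplitude", "mV")):
        if response not in report:
            continue
        block = report[response]
        hr = report["config"]["reference_heart_rate"]
        lines.append(f"{label} (EMMs at {hr:g} bpm):")
        for row in block["emm"]:
            loc = row.get("chamber") or row.get("wall_assignment")
            lines.append(f"  {loc}: {row['estimate']:.2f} ± {row['se']:.2f} {unit}")
        lines.append(f"  pairwise contrasts ({'ratios' if response == 'log_cv' else 'differences'}):")
        for row in block["contrasts"]:
            sym = "×" if response == "log_cv" else "Δ"
            lines.append(
                f"    {row['level_a']} vs {row['level_b']}: {sym}{row['estimate']:.3f}"
                f" ± {row['se']:.3f}, p = {row['p_adj']:.3g} ({row['adjust']})"
            )
    if "sex_effect_p" in report:
        p = report["sex_effect_p"]
        lines.append(
            f"Sex effect: cv p = {p['log_cv']:.2f}, va p = {p['va']:.2f}"
        )
    if "correlations" in report:
        lines.append("Correlations (cv vs va):")
        for scope, c in report["correlations"].items():
            lines.append(
                f"  {scope}: r({c['df']}) = {c['r']:.2f}, p = {c['p_value']:.3g}"
                f" [{c['interpretation']}]"
            )
    return "\n".join(lines)
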