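import numpy as np
import pandas as pd
import pytest

from eamap import (
    CollidingWaves,
    EllipsoidChamber,
    FlatSheet,
    MapScenario,
    PlanarWave,
    StudyScenario,
    cover_map,
    generate_map,
    generate_study,
    measure_circles,
    sample_measurement_table,
)
from eamap.synthetic import DEFAULT_CV_MEANS, FocalWave, plant_wall_labels


class TestWavefronts:
    def test_planar_zero_on_wavefront_plane(self):
        w = PlanarWave((0, 0, 1), 1.0)
        pts = np.array([[3.0, -4.0, 0.0], [0.0, 100.0, 0.0]])
        assert np.allclose(w.activation(pts), 0.0)

    def test_doubling_speed_halves_activation(self):
        pts = np.random.default_rng(0).normal(size=(50, 3)) * 10
        t1 = PlanarWave((1, 2, 0), 0.5).activation(pts)
        t2 = PlanarWave((1, 2, 0), 1.0).activation(pts)
        assert np.allclose(t1, 2 * t2)
        f1 = FocalWave((1, 1, 1), 0.5).activation(pts)
        f2 = FocalWave((1, 1, 1), 1.0).activation(pts)
        assert np.allclose(f1, 2 * f2)

    def test_colliding_is_pointwise_minimum(self):
        pts = np.random.default_rng(1).normal(size=(40, 3)) * 15
        a = PlanarWave((1, 0, 0), 0.4, t0=5.0)
        b = PlanarWave((0, 1, 0), 0.8)
        cw = CollidingWaves(a, b)
        assert np.allclose(
            cw.activation(pts), np.minimum(a.activation(pts), b.activation(pts))
        )


class TestGenerateMap:
    def test_deterministic_given_seed(self):
        sc = MapScenario(geometry=FlatSheet(15, 15, 0.5), voltage_noise_sd=1.5, seed=12)
        m1, t1 = generate_map(sc)
        m2, t2 = generate_map(sc)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.activation, m2.activation)
        assert np.array_equal(m1.voltage, m2.voltage)
        assert t1 == t2

    def test_cutouts_planted_and_total_cutout_rejected(self):
        sc = MapScenario(geometry=FlatSheet(15, 15, 0.5),
                         cutouts=(((0.0, 0.0, 0.0), 3.0),), seed=1)
        m, truth = generate_map(sc)
        inside = np.linalg.norm(m.vertices, axis=1) < 3.0
        assert np.array_equal(m.cutout, inside)
        assert truth["n_cutouts"] == 1
        with pytest.raises(ValueError, match="cutouts cover"):
            generate_map(MapScenario(geometry=FlatSheet(4, 4, 1.0),
                                     cutouts=(((0.0, 0.0, 0.0), 100.0),)))

    def test_voltage_means_respected_per_wall(self):
        sc = MapScenario(
            geometry=EllipsoidChamber((18, 20, 24), 3),
            chamber="RV",
            voltage_noise_sd=0.0,
            seed=4,
        )
        m, truth = generate_map(sc)
        for wall, mu in truth["voltage_means"].items():
            sel = m.wall_label == wall
            assert sel.any()
            assert np.allclose(m.voltage[sel], mu)

    def test_wall_partition_respects_chamber_scheme(self):
        v = EllipsoidChamber((18, 20, 24), 3).build()[0]
        ra = set(plant_wall_labels(v, "RA", "ellipsoid_chamber"))
        assert "anterior" not in ra and "superior" in ra
        lv = set(plant_wall_labels(v, "LV", "ellipsoid_chamber"))
        assert "superior" not in lv

    def test_scenario_json_round_trip(self):
        sc = MapScenario(
            geometry=EllipsoidChamber((15, 16, 19), 3),
            wave=CollidingWaves(PlanarWave((1, 0, 0), 0.5), PlanarWave((0, 1, 0), 0.7)),
            chamber="LA",
            cutouts=(((0.0, 0.0, 19.0), 5.0),),
            seed=9,
        )
        sc2 = MapScenario.from_json(sc.to_json())
        m1, _ = generate_map(sc)
        m2, _ = generate_map(sc2)
        assert np.array_equal(m1.activation, m2.activation)
        assert np.array_equal(m1.voltage, m2.voltage)

    def test_end_to_end_speed_recovery(self):
        """Full pipeline on a planar-wave sheet recovers the true speed."""
        sc = MapScenario(
            geometry=FlatSheet(36, 36, 0.5),
            wave=PlanarWave((1, 1, 0), 0.6),
            chamber="LV",
            seed=2,
        )
        m, _ = generate_map(sc)
        patches, _ = cover_map(m, radius=5.0, spacing=5.0, seed=0)
        interior = [p for p in patches if np.all(np.abs(p.center[:2]) <= 18 - 5.01)]
        cvs = [x.cv for x in measure_circles(interior, m.meta) if x.valid]
        assert np.median(cvs) == pytest.approx(0.6, rel=0.02)


class TestGenerateStudy:
    def test_default_design_matches_reference_layout(self):
        maps, truth = generate_study(StudyScenario(subdivisions=2, seed=3))
        assert len(maps) == 21
        chambers = pd.Series([m.meta.chamber for m in maps]).value_counts()
        assert chambers.to_dict() == {"RA": 7, "RV": 6, "LV": 4, "LA": 4}
        assert truth["animal_id"].nunique() == 4
        assert len(truth) == 21

    def test_fixed_seed_is_reproducible(self):
        m1, t1 = generate_study(StudyScenario(subdivisions=2, seed=11))
        m2, t2 = generate_study(StudyScenario(subdivisions=2, seed=11))
        for a, b in zip(m1, m2):
            assert np.array_equal(a.activation, b.activation)
            assert np.array_equal(a.voltage, b.voltage)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_variability_makes_replicate_maps_identical(self):
        design = pd.DataFrame(
            [
                {"animal_id": a, "chamber": "LV", "heart_rate": 100.0,
                 "map_id": f"{a}-{i}", "sex": "female"}
                for a in ("p1", "p2") for i in (1, 2)
            ]
        )
        sc = StudyScenario(
            design=design, animal_sd_log_cv=0.0, animal_sd_va=0.0,
            voltage_noise_sd=0.0, subdivisions=2,
            wave_direction=(1.0, 0.5, 0.2), seed=5,
        )
        maps, truth = generate_study(sc)
        assert np.array_equal(maps[0].activation, maps[3].activation)
        assert np.array_equal(maps[0].voltage, maps[3].voltage)
        assert truth["true_speed"].nunique() == 1

    def test_truth_table_lists_generative_parameters(self):
        _, truth = generate_study(StudyScenario(subdivisions=2, seed=7))
        for col in ("true_speed", "animal_intercept_log_cv", "chamber_cv_mean_90bpm",
                    "slope_log_cv", "voltage_means", "seed"):
            assert col in truth.columns
        # planted speed follows the stated composition law exactly
        row = truth.iloc[0]
        expected = (
            row["chamber_cv_mean_90bpm"]
            * np.exp(row["animal_intercept_log_cv"])
            * np.exp(row["slope_log_cv"] * (row["heart_rate"] - 90.0))
        )
        assert row["true_speed"] == pytest.approx(expected, rel=1e-12)

    def test_single_animal_design_rejected(self):
        design = pd.DataFrame(
            [{"animal_id": "p1", "chamber": "LA", "heart_rate": 90.0,
              "map_id": "m1", "sex": "female"}]
        )
        with pytest.raises(ValueError, match="at least 2 animals"):
            generate_study(StudyScenario(design=design))


class TestMeasurementSampler:
    def test_chamber_means_recovered_at_scale(self):
        tab, truth = sample_measurement_table(circles_per_map=400, seed=0,
                                              animal_sd_log_cv=0.0)
        got = np.exp(
            np.log(tab["cv"]).groupby(tab["chamber"]).mean()
            - truth["slope_log_cv"]
            * (tab["heart_rate"].groupby(tab["chamber"]).mean() - 90)
        )
        for c, mu in DEFAULT_CV_MEANS.items():
            assert got[c] == pytest.approx(mu, rel=0.05)

    def test_sampler_is_seed_deterministic(self):
        t1, _ = sample_measurement_table(seed=77)
        t2, _ = sample_measurement_table(seed=77)
        pd.testing.assert_frame_equal(t1, t2)
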