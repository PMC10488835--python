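import numpy as np
import pytest

from eamap import FlatSheet, MapMeta, MapScenario, PlanarWave, SurfaceMap, generate_map


def make_flat_map(width=20.0, height=20.0, edge=0.5, speed=0.6, direction=(1, 0, 0),
                  chamber="LV", voltage_noise=0.0, seed=0, **kwargs) -> SurfaceMap:
    """Flat-sheet map with a planar wave; the workhorse analytic fixture."""
    scenario = MapScenario(
        geometry=FlatSheet(width, height, edge),
        wave=PlanarWave(direction, speed),
        chamber=chamber,
        voltage_noise_sd=voltage_noise,
        seed=seed,
        **kwargs,
    )
    surface, _ = generate_map(scenario)
    return surface


@pytest.fixture
def flat_map():
    return make_flat_map()


@pytest.fixture
def tiny_mesh_map():
    """A 10-vertex, hand-built open fan mesh with distinctive scalars."""
    rng = np.random.default_rng(42)
    vertices = np.column_stack(
        [rng.uniform(-5, 5, 10), rng.uniform(-5, 5, 10), rng.uniform(-1, 1, 10)]
    )
    triangles = np.array(
        [[0, 1, 2], [1, 3, 2], [2, 3, 4], [3, 5, 4], [4, 5, 6], [5, 7, 6], [6, 7, 8], [7, 9, 8]]
    )
    wall = np.array(
        ["anterior"] * 4 + ["posterior"] * 3 + ["unlabeled"] * 3, dtype=object
    )
    return SurfaceMap(
        vertices=vertices,
        triangles=triangles,
        activation=rng.uniform(0, 50, 10),
        voltage=rng.uniform(0.5, 12, 10),
        cutout=np.array([False] * 9 + [True]),
        wall_label=wall,
        meta=MapMeta(animal_id="7", chamber="LV", heart_rate=103.0,
                     map_id="7-test", sex="female"),
    )
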