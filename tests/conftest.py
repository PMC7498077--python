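import numpy as np
import pytest

from tuberoot import (
    DistributionSpec,
    ParameterDatabase,
    REQUIRED_PARAMETERS,
    ZAODABAI_CREEPING_ROOT_AXIAL,
    build_database,
    default_truth,
    generate_measurements,
)


@pytest.fixture(scope="session")
def zspec() -> DistributionSpec:
    """The published Zaodabai creeping-root axial-angle law."""
    return ZAODABAI_CREEPING_ROOT_AXIAL


@pytest.fixture(scope="session")
def truth1():
    """Complete Zaodabai truth configuration (50-plant campaign)."""
    return default_truth(1, n_plants=50, seed=0)


@pytest.fixture(scope="session")
def table1(truth1):
    return generate_measurements(truth1)


@pytest.fixture(scope="session")
def db1(table1):
    return build_database(table1, variety="Zaodabai")


def constant(v: float) -> DistributionSpec:
    """Degenerate spec that always samples v."""
    return DistributionSpec(kind="empirical", intervals=((v, v),),
                            probs=(1.0,))


def make_constant_db(
    n_seminal=2, n_creeping_root=2, n_creeping_stem=1, n_tuber=1
) -> ParameterDatabase:
    """Fully degenerate database: every parameter a point mass.

    Forces exact organ counts so node arithmetic is deterministic.
    """
    values = {
        "seed_potato": {"length_mm": 70, "width_mm": 55, "height_mm": 45,
                        "burial_depth_mm": 100},
        "underground_stem": {"bottom_radius_mm": 6, "top_radius_mm": 4,
                             "height_mm": 140},
        "seminal_root": {"axial_angle_deg": 150, "radial_angle_deg": 10,
                         "initial_radius_mm": 1.5, "tip_radius_mm": 0.5,
                         "length_mm": 150, "depth_mm": 230,
                         "total_deflection_deg": 30, "count": n_seminal},
        "creeping_root": {"axial_angle_deg": 110, "radial_angle_deg": 120,
                          "initial_radius_mm": 1.2, "tip_radius_mm": 0.4,
                          "length_mm": 180, "depth_mm": 140,
                          "total_deflection_deg": 40, "count": n_creeping_root,
                          "distance_to_seed_mm": 55},
        "creeping_stem": {"axial_angle_deg": 100, "radial_angle_deg": 240,
                          "initial_radius_mm": 2.5, "tip_radius_mm": 1.5,
                          "length_mm": 120, "depth_mm": 110,
                          "total_deflection_deg": 30, "count": n_creeping_stem,
                          "distance_to_seed_mm": 40},
        "tuber": {"length_mm": 75, "width_mm": 55, "height_mm": 45,
                  "count": n_tuber},
    }
    organs = {
        organ: {p: constant(values[organ][p])
                for p in REQUIRED_PARAMETERS[organ]}
        for organ in values
    }
    return ParameterDatabase(variety="Zaodabai", organs=organs)


@pytest.fixture()
def constant_db() -> ParameterDatabase:
    return make_constant_db()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
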