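import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from facesym.io import LandmarkConfiguration, SymmetryMap
from facesym.simulate import GroupSpec, SimulationSpec, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_map() -> SymmetryMap:
    """Smallest valid bilateral structure: one pair + one midline point."""
    return SymmetryMap(pairs=((0, 1),), midline=(2,))


@pytest.fixture(scope="session")
def small_map() -> SymmetryMap:
    """k=13 layout (p=5, m=3) used by most simulation-backed tests."""
    from facesym.simulate import make_template

    return make_template(5, 3)[1]


def small_sim(
    seed: int = 0,
    n: int = 40,
    fa_scale: float = 0.01,
    fa_scale_b: float | None = None,
    da_scale: float = 0.05,
    da_offset_b: float = 0.0,
    noise_scale: float = 0.001,
    nuisance: bool = True,
    two_groups: bool = False,
):
    """Convenience wrapper around `simulate_dataset` on the k=13 layout."""
    groups = [GroupSpec("A", "DB1", n, n // 2, 0.02, fa_scale)]
    if two_groups:
        groups.append(
            GroupSpec(
                "B", "DB2", n, n // 2, 0.02,
                fa_scale_b if fa_scale_b is not None else fa_scale,
                da_offset_scale=da_offset_b,
            )
        )
    spec = SimulationSpec(
        p=5, m=3, groups=tuple(groups), da_scale=da_scale,
        noise_scale=noise_scale, nuisance=nuisance, seed=seed,
    )
    return simulate_dataset(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_configs(
    rng: np.random.Generator, smap: SymmetryMap, n: int, spread: float = 0.1
) -> list[LandmarkConfiguration]:
    """n random perturbations of a symmetric base shape."""
    from facesym.simulate import make_template

    base, _ = make_template(smap.p, smap.m, seed=99, symmetry=smap)
    return [
        LandmarkConfiguration(
            f"s{i}", base.coords + spread * rng.standard_normal((smap.k, 2))
        )
        for i in range(n)
    ]
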