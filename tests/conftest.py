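import functools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import memclust as mc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session", autouse=True)
def warm_kernel():
    """Trigger JIT compilation once so per-test timings are meaningful."""
    cfg = mc.SimulationConfig.standard(
        20, n_agents=80, duration_s=0.5, record_every=None
    )
    mc.run_simulation(cfg)


@pytest.fixture(scope="session")
def csr_2000():
    return mc.generate_csr(2000, seed=11)


@pytest.fixture(scope="session")
def two_blob_fixture():
    """Two sigma=30 nm blobs of 100 molecules, 1500 nm apart, on 100 background."""
    spec = mc.BlobSpec(
        n_background=100,
        blobs=[((750.0, 1500.0), 30.0, 100), ((2250.0, 1500.0), 30.0, 100)],
        seed=5,
    )
    return mc.generate_blobs(spec)


@pytest.fixture(scope="session")
def condition_cache():
    """Session-wide cache of simulation ensembles, shared across tests.

    Ensembles at full study scale (2000 molecules, 5 simulated minutes)
    are expensive; every test requesting the same condition re-uses the
    same seeded ensemble.
    """

    @functools.lru_cache(maxsize=None)
    def get(
        target: float,
        n_reps: int = 5,
        d_max: float = mc.STANDARD_D_MAX,
        mesh_spacing: float | None = None,
        duration_s: float = 300.0,
        seed: int = 1,
    ) -> mc.EnsembleResult:
        cfg = mc.SimulationConfig.standard(
            target,
            d_max=d_max,
            mesh_spacing=mesh_spacing,
            duration_s=duration_s,
            seed=seed,
            record_every=None,
        )
        return mc.run_ensemble(cfg, n_reps)

    return get


@pytest.fixture(scope="session")
def sweep_cache():
    """Cached regime sweeps over target grids (no descriptors)."""

    @functools.lru_cache(maxsize=None)
    def get(
        targets: tuple,
        n_reps: int = 5,
        d_max: float = mc.STANDARD_D_MAX,
        mesh_spacing: float | None = None,
        seed: int = 1,
    ):
        def factory(tc):
            return mc.SimulationConfig.standard(
                tc, d_max=d_max, mesh_spacing=mesh_spacing, record_every=None
            )

        return mc.run_target_sweep(
            list(targets),
            n_reps=n_reps,
            seed=seed,
            config_factory=factory,
            descriptors=False,
        )

    return get


def assert_within(value, expected, rel):
    assert value == pytest.approx(expected, rel=rel), (
        f"{value} outside +/-{rel * 100:.0f}% of {expected}"
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
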