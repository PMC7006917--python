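"""Simulation engine: CSR initialisation, per-frame update, seeded ensembles.

A run starts from a completely spatially random (CSR) pattern and
iterates, every frame: local density (L) -> displacement rate ->
step proposal -> barrier reflection / toroidal wrap.  The update is
synchronous — all rates are computed from the same pre-move snapshot —
so results do not depend on molecule order.  The per-frame mean L
(the <L> series) is recorded from the pre-move density pass.

Two interchangeable engines advance the pattern: a numba kernel (the
default, used for production runs) and a pure-Python reference stepper.
Both consume the same seeded random stream draw-for-draw, so they can be
cross-checked against each other; an asynchronous random-order update is
additionally available in the Python engine for sensitivity checks.

Reference (Standard Condition) parameters: 2000 molecules on a
3 x 3 um^2 toroidal patch, 10 ms frames, 5 simulated minutes (30,000
frames), density radius R = 100 nm, linearly converging profile with
d_max = 3.5 nm/ms and full immobility at the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import engine
from .geometry import (
    Box,
    PointPattern,
    count_from_l,
    l_from_count,
    neighbour_counts,
)
from .motion import (
    STANDARD_D_MAX,
    ActinMesh,
    DisplacementProfile,
    propose_step,
    reflect_off_mesh,
    wrap_torus,
)

__all__ = [
    "SimulationConfig",
    "TrajectoryRecord",
    "EnsembleResult",
    "initialise_pattern",
    "step_frame",
    "run_simulation",
    "run_ensemble",
    "target_l_for_count",
]


def target_l_for_count(target_count: float, n_agents: int = 2000, box: Box | None = None) -> float:
    """L target (nm) equivalent to a target neighbour count."""
    box = box or Box()
    return l_from_count(target_count, n_agents, box.area)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one simulation experiment."""

    profile: DisplacementProfile
    box: Box = field(default_factory=Box)
    n_agents: int = 2000
    dt_ms: float = 10.0
    duration_s: float = 300.0
    density_radius: float = 100.0
    step_mode: str = "fixed"
    mesh: Optional[ActinMesh] = None
    seed: int = 0
    record_every: Optional[int] = 100
    update_mode: str = "synchronous"

    def __post_init__(self) -> None:
        if self.n_agents < 0:
            raise ValueError(f"n_agents must be non-negative, got {self.n_agents}")
        if self.dt_ms <= 0:
            raise ValueError(f"dt_ms must be positive, got {self.dt_ms}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        frames = self.duration_s * 1000.0 / self.dt_ms
        if abs(frames - round(frames)) > 1e-6:
            raise ValueError(
                f"duration ({self.duration_s} s) must be an integer number of "
                f"{self.dt_ms} ms frames"
            )
        if self.density_radius >= self.box.min_dimension / 2:
            raise ValueError(
                f"density radius {self.density_radius} must be below half the "
                f"smallest box dimension ({self.box.min_dimension / 2})"
            )
        if self.step_mode not in ("fixed", "gaussian"):
            raise ValueError(f"unknown step mode {self.step_mode!r}")
        if self.update_mode not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown update mode {self.update_mode!r}")
        if self.mesh is not None:
            self.mesh.validate_for_box(self.box)
            if self.step_mode == "fixed" and self.profile.d_max * self.dt_ms >= self.mesh.spacing:
                raise ValueError(
                    f"maximum step {self.profile.d_max * self.dt_ms} nm must stay "
                    f"below the mesh spacing {self.mesh.spacing} nm"
                )
        if self.record_every is not None and self.record_every < 1:
            raise ValueError("record_every must be a positive frame count or None")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * 1000.0 / self.dt_ms))

    @property
    def target_count(self) -> float:
        """Profile target expressed as encircled molecules."""
        return count_from_l(self.profile.l_target, self.n_agents, self.box.area)

    @classmethod
    def standard(
        cls,
        target_count: float,
        d_max: float = STANDARD_D_MAX,
        family: str = "linear_converging",
        d_min: float = 0.0,
        mesh_spacing: Optional[float] = None,
        **overrides,
    ) -> "SimulationConfig":
        """Standard Condition (or a named variant of it) at a target count."""
        box = overrides.pop("box", Box())
        n_agents = overrides.pop("n_agents", 2000)
        profile = DisplacementProfile(
            family=family,
            d_max=d_max,
            d_min=d_min,
            l_target=l_from_count(target_count, n_agents, box.area),
        )
        mesh = ActinMesh(mesh_spacing) if mesh_spacing else None
        return cls(profile=profile, box=box, n_agents=n_agents, mesh=mesh, **overrides)


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-frame <L> series (and optional thinned frames) of one run."""

    times: np.ndarray
    l_series: np.ndarray
    final_frame: PointPattern
    stored_times: np.ndarray
    stored_frames: tuple
    config: SimulationConfig
    engine: str


@dataclass(frozen=True)
class EnsembleResult:
    """Frame-wise mean/SD of <L> over seeded replicates."""

    times: np.ndarray
    mean_l: np.ndarray
    sd_l: np.ndarray
    records: tuple
    config: SimulationConfig
    seeds: tuple

    @property
    def final_patterns(self) -> list[PointPattern]:
        return [r.final_frame for r in self.records]


def _derive_seeds(seed: int) -> tuple[int, int]:
    """Split a replicate seed into initialisation and motion streams."""
    init_s, motion_s = np.random.SeedSequence(seed).generate_state(2)
    return int(init_s % 2**31), int(motion_s % 2**31)


def initialise_pattern(config: SimulationConfig, rng: np.random.RandomState) -> PointPattern:
    """CSR initial condition: n_agents i.i.d. uniform positions."""
    x = rng.random_sample(config.n_agents) * config.box.width
    y = rng.random_sample(config.n_agents) * config.box.height
    return PointPattern.from_xy(x, y, config.box)


def _frame_update(
    positions: np.ndarray, config: SimulationConfig, rng: np.random.RandomState
) -> tuple[np.ndarray, float]:
    """One synchronous frame (reference implementation); returns pre-move mean L."""
    pattern = PointPattern(positions, config.box)
    n = pattern.n
    counts = neighbour_counts(pattern, config.density_radius)
    l_vals = l_from_count(counts, n, config.box.area) if n > 1 else np.zeros(n)
    mean_l = float(np.mean(l_vals)) if n else 0.0
    rates = config.profile.rate(np.atleast_1d(l_vals))
    proposed = propose_step(positions, rates, config.dt_ms, rng, mode=config.step_mode)
    if config.mesh is not None:
        new_pos = reflect_off_mesh(positions, proposed, config.mesh)
    else:
        new_pos = wrap_torus(proposed, config.box)
    return new_pos, mean_l


def _frame_update_async(
    positions: np.ndarray, config: SimulationConfig, rng: np.random.RandomState
) -> tuple[np.ndarray, float]:
    """Random-order sequential update (sensitivity-check variant).

    Each molecule's L is measured on the partially updated pattern, so
    results are order-dependent; the visiting order is reshuffled every
    frame from the motion stream.
    """
    pos = positions.copy()
    n = pos.shape[0]
    box = config.box
    pre = PointPattern(pos, box)
    mean_l = (
        float(np.mean(l_from_count(neighbour_counts(pre, config.density_radius), n, box.area)))
        if n > 1
        else 0.0
    )
    for i in rng.permutation(n):
        pattern = PointPattern(pos, box)
        counts = neighbour_counts(pattern, config.density_radius)
        l_i = l_from_count(counts[i], n, box.area) if n > 1 else 0.0
        rate_i = config.profile.rate(l_i)
        prop = propose_step(pos[i], rate_i, config.dt_ms, rng, mode=config.step_mode)
        if config.mesh is not None:
            pos[i] = reflect_off_mesh(pos[i], prop, config.mesh)
        else:
            pos[i] = wrap_torus(prop, box)
    return pos, mean_l


def step_frame(
    pattern: PointPattern, config: SimulationConfig, rng: np.random.RandomState
) -> PointPattern:
    """Advance a pattern by one frame with the reference stepper."""
    update = _frame_update if config.update_mode == "synchronous" else _frame_update_async
    new_pos, _ = update(pattern.positions, config, rng)
    return PointPattern(new_pos, config.box)


def _store_schedule(config: SimulationConfig) -> int:
    if config.record_every is None:
        return 0
    return config.record_every


def run_simulation(config: SimulationConfig, sim_engine: str = "numba") -> TrajectoryRecord:
    """Run one seeded simulation and record the <L> time series.

    The series has one entry per frame time (0 .. n_frames), each
    measured on the pattern before that frame's moves; thinned snapshots
    are stored every ``config.record_every`` frames and the final frame
    is always retained.  Identical (config, seed) gives bit-identical
    output.
    """
    if sim_engine not in ("numba", "python"):
        raise ValueError(f"unknown engine {sim_engine!r}")
    if config.update_mode == "asynchronous" and sim_engine != "python":
        raise ValueError("asynchronous updates are only available in the python engine")
    init_seed, motion_seed = _derive_seeds(config.seed)
    pattern = initialise_pattern(config, np.random.RandomState(init_seed))
    n_frames = config.n_frames
    stride = _store_schedule(config)
    times = np.arange(n_frames + 1) * (config.dt_ms / 1000.0)

    if config.n_agents < 2:
        # Degenerate patterns have no defined L; hold the pattern fixed.
        return TrajectoryRecord(
            times=times,
            l_series=np.zeros(n_frames + 1),
            final_frame=pattern,
            stored_times=np.empty(0),
            stored_frames=(),
            config=config,
            engine=sim_engine,
        )

    if sim_engine == "numba":
        x = np.ascontiguousarray(pattern.positions[:, 0])
        y = np.ascontiguousarray(pattern.positions[:, 1])
        mean_l = np.empty(n_frames + 1)
        n_store = -(-n_frames // stride) if stride else 0
        frames_out = np.empty((n_store, config.n_agents, 2))
        engine.run_kernel(
            x,
            y,
            n_frames,
            config.box.width,
            config.box.height,
            config.density_radius,
            config.dt_ms,
            config.profile.family_code,
            config.profile.d_max,
            config.profile.d_min,
            config.profile.l_target,
            config.profile.l_anchor,
            config.step_mode == "gaussian",
            config.mesh.spacing if config.mesh is not None else 0.0,
            motion_seed,
            stride,
            frames_out,
            mean_l,
            True,
        )
        final = PointPattern.from_xy(x, y, config.box)
        stored = tuple(PointPattern(f, config.box) for f in frames_out)
        stored_times = np.arange(n_store) * stride * (config.dt_ms / 1000.0)
    else:
        rng = np.random.RandomState(motion_seed)
        update = _frame_update if config.update_mode == "synchronous" else _frame_update_async
        pos = pattern.positions.copy()
        mean_l = np.empty(n_frames + 1)
        stored_list = []
        stored_t = []
        for t in range(n_frames):
            if stride and t % stride == 0:
                stored_list.append(PointPattern(pos.copy(), config.box))
                stored_t.append(times[t])
            pos, mean_l[t] = update(pos, config, rng)
        final = PointPattern(pos, config.box)
        counts = neighbour_counts(final, config.density_radius)
        mean_l[n_frames] = float(
            np.mean(l_from_count(counts, config.n_agents, config.box.area))
        )
        stored = tuple(stored_list)
        stored_times = np.asarray(stored_t)

    return TrajectoryRecord(
        times=times,
        l_series=mean_l,
        final_frame=final,
        stored_times=stored_times,
        stored_frames=stored,
        config=config,
        engine=sim_engine,
    )


def ensemble_seeds(base_seed: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate seeds derived from a base seed."""
    return [int(s % 2**31) for s in np.random.SeedSequence(base_seed).generate_state(n_reps)]


def run_ensemble(
    config: SimulationConfig,
    n_reps: int,
    seeds: Optional[Sequence[int]] = None,
    record_frames: bool = False,
    sim_engine: str = "numba",
) -> EnsembleResult:
    """Run seeded replicates and average the <L> series frame-wise.

    Per-replicate trajectory records (with final frames, for cluster
    analysis) are retained.  When ``seeds`` is omitted they are derived
    deterministically from ``config.seed``.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be at least 1, got {n_reps}")
    if seeds is None:
        seeds = ensemble_seeds(config.seed, n_reps)
    elif len(seeds) != n_reps:
        raise ValueError(f"expected {n_reps} seeds, got {len(seeds)}")
    records = []
    for s in seeds:
        cfg = replace(config, seed=int(s), record_every=config.record_every if record_frames else None)
        records.append(run_simulation(cfg, sim_engine=sim_engine))
    series = np.stack([r.l_series for r in records])
    return EnsembleResult(
        times=records[0].times,
        mean_l=series.mean(axis=0),
        sd_l=series.std(axis=0, ddof=1) if n_reps > 1 else np.zeros_like(series[0]),
        records=tuple(records),
        config=config,
        seeds=tuple(int(s) for s in seeds),
    )
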