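"""Motion rules: the "desire for clustering" and its boundary conditions.

Each molecule's per-frame displacement is set by a profile mapping its
local clustering level L (nm) to a displacement rate (nm/ms): fast when
far below the target L, slow or immobile as the target is approached.
Four profile families cover the study conditions:

``linear_converging``
    The Standard Condition: rate decays linearly from ``d_max`` at the
    anchor to zero at the target; molecules at or above the target are
    fully immobile (d_min = 0).
``linear_floor``
    As above but floored at ``d_min`` > 0, so molecules never stop
    completely (residual cluster mobility).
``tent_nonconverging``
    Rate is zero only at exact equality with the target and rises on
    both sides (a tent around the target).
``quadratic``
    Quadratic decay of the linear-converging ramp.

Steps are taken in a uniformly random direction with either a fixed
length (rate x dt) or a Gaussian length whose RMS equals rate x dt.
Reflective actin-mesh barriers (a regular grid of vertical/horizontal
lines) are applied by specular reflection, and the toroidal wrap keeps
the molecule count constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import engine
from .geometry import Box

__all__ = [
    "PROFILE_FAMILIES",
    "DisplacementProfile",
    "ActinMesh",
    "displacement_rate",
    "propose_step",
    "reflect_off_mesh",
    "wrap_torus",
]

PROFILE_FAMILIES = (
    "linear_converging",
    "linear_floor",
    "tent_nonconverging",
    "quadratic",
)

_FAMILY_CODE = {
    "linear_converging": engine.PROFILE_LINEAR,
    "linear_floor": engine.PROFILE_FLOOR,
    "tent_nonconverging": engine.PROFILE_TENT,
    "quadratic": engine.PROFILE_QUAD,
}

#: Standard Condition maximum displacement rate (nm/ms).
STANDARD_D_MAX = 3.5
#: Fast / slow variants scale the step length by sqrt(10) either way,
#: mapping a x10 / /10 change in effective diffusion coefficient.
FAST_D_MAX = STANDARD_D_MAX * math.sqrt(10.0)
SLOW_D_MAX = STANDARD_D_MAX / math.sqrt(10.0)


@dataclass(frozen=True)
class DisplacementProfile:
    """Displacement-rate-versus-L rule applied to every molecule.

    Parameters
    ----------
    family:
        One of :data:`PROFILE_FAMILIES`.
    d_max:
        Maximum displacement rate, nm/ms (rate at ``l_anchor``).
    d_min:
        Rate floor, nm/ms (only meaningful for ``linear_floor``).
    l_target:
        Target clustering level, nm.
    l_anchor:
        L at which the rate equals ``d_max``; the profile decays
        linearly (or quadratically) between anchor and target.
    """

    family: str
    d_max: float
    l_target: float
    d_min: float = 0.0
    l_anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in PROFILE_FAMILIES:
            raise ValueError(
                f"unknown profile family {self.family!r}; expected one of {PROFILE_FAMILIES}"
            )
        if not (self.d_max >= self.d_min >= 0):
            raise ValueError(
                f"need d_max >= d_min >= 0, got d_max={self.d_max}, d_min={self.d_min}"
            )
        if not (self.l_target > self.l_anchor >= 0):
            raise ValueError(
                f"need l_target > l_anchor >= 0, got l_target={self.l_target}, "
                f"l_anchor={self.l_anchor}"
            )

    @property
    def family_code(self) -> int:
        return _FAMILY_CODE[self.family]

    def rate(self, L):
        """Displacement rate (nm/ms) at clustering level(s) ``L``."""
        L = np.asarray(L, dtype=np.float64)
        if np.any(L < 0):
            raise ValueError("L must be non-negative")
        u = (self.l_target - L) / (self.l_target - self.l_anchor)
        if self.family == "tent_nonconverging":
            r = self.d_max * np.minimum(1.0, np.abs(u))
        else:
            u = np.clip(u, 0.0, 1.0)
            if self.family == "quadratic":
                r = self.d_max * u * u
            else:
                r = self.d_max * u
            if self.family == "linear_floor":
                r = np.maximum(r, self.d_min)
        return float(r) if r.ndim == 0 else r


def displacement_rate(profile: DisplacementProfile, L):
    """Functional alias for :meth:`DisplacementProfile.rate`."""
    return profile.rate(L)


@dataclass(frozen=True)
class ActinMesh:
    """Regular grid of reflective barriers (cortical actin picket fence).

    The mesh is the set of vertical lines x = m * spacing and horizontal
    lines y = m * spacing.  Barriers obstruct motion only; they are
    transparent to density counting.
    """

    spacing: float

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError(f"mesh spacing must be positive, got {self.spacing}")

    def validate_for_box(self, box: Box) -> None:
        for dim in (box.width, box.height):
            m = dim / self.spacing
            if abs(m - round(m)) > 1e-9:
                raise ValueError(
                    f"mesh spacing {self.spacing} must divide the box "
                    f"dimensions ({box.width} x {box.height})"
                )


def propose_step(position, rate, dt: float, rng, mode: str = "fixed") -> np.ndarray:
    """Propose unbounded step(s) from ``position`` at the given rate(s).

    ``fixed`` mode takes a step of length exactly ``rate * dt`` in a
    uniformly random direction; ``gaussian`` mode draws each coordinate
    increment from a zero-mean normal with per-axis variance
    ``(rate * dt)^2 / 2`` so the RMS step length equals ``rate * dt``.
    Molecules with zero rate do not draw from ``rng`` and stay put,
    mirroring the simulation kernel's random stream.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if mode not in ("fixed", "gaussian"):
        raise ValueError(f"unknown step mode {mode!r}")
    pos = np.atleast_2d(np.asarray(position, dtype=np.float64)).copy()
    rate = np.broadcast_to(np.asarray(rate, dtype=np.float64), pos.shape[:1]).copy()
    if np.any(rate < 0):
        raise ValueError("rates must be non-negative")
    mov = rate > 0
    m = int(mov.sum())
    if m:
        step = rate[mov] * dt
        if mode == "gaussian":
            u = rng.random_sample((m, 2))
            rad = (step / math.sqrt(2.0)) * np.sqrt(-2.0 * np.log(1.0 - u[:, 0]))
            ang = 2.0 * math.pi * u[:, 1]
        else:
            rad = step
            ang = 2.0 * math.pi * rng.random_sample(m)
        delta = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        pos[mov] += delta
    if np.asarray(position).ndim == 1:
        return pos[0]
    return pos


def _fold(v: np.ndarray, old: np.ndarray, spacing: float) -> np.ndarray:
    """Specular reflection of ``v`` into the mesh interval containing ``old``.

    Folding with period 2 x spacing applies the mirrors about each
    crossed line in order of crossing.
    """
    lo = np.floor(old / spacing) * spacing
    period = 2.0 * spacing
    y = (v - lo) % period
    y = np.where(y > spacing, period - y, y)
    return lo + y


def reflect_off_mesh(old, proposed, mesh: Optional[ActinMesh]) -> np.ndarray:
    """Reflect a proposed move off the actin-mesh barriers.

    Vertical lines mirror the x component, horizontal lines the y
    component; the result lies in the same mesh cell as ``old``.  Step
    lengths of a mesh spacing or more are rejected as ambiguous
    multi-cell traversals (never produced by the study parameter sets).
    """
    old_a = np.asarray(old, dtype=np.float64)
    prop_a = np.asarray(proposed, dtype=np.float64)
    if mesh is None:
        return prop_a.copy()
    step = np.hypot(*(prop_a - old_a).reshape(-1, 2).T)
    if np.any(step >= mesh.spacing):
        raise ValueError(
            f"step length {np.max(step):.3g} nm must stay below the mesh "
            f"spacing {mesh.spacing} nm"
        )
    out = np.empty_like(prop_a)
    out[..., 0] = _fold(prop_a[..., 0], old_a[..., 0], mesh.spacing)
    out[..., 1] = _fold(prop_a[..., 1], old_a[..., 1], mesh.spacing)
    return out


def wrap_torus(position, box: Box) -> np.ndarray:
    """Reduce coordinates modulo the box into [0, width) x [0, height)."""
    pos = np.asarray(position, dtype=np.float64)
    out = np.empty_like(pos)
    out[..., 0] = np.mod(pos[..., 0], box.width)
    out[..., 1] = np.mod(pos[..., 1], box.height)
    return out
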