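"""Seeded generators of ground-truth patterns and <L> curves.

These let every analysis stage (density statistics, cluster calling,
regime classification) be exercised against known ground truth without
running full simulations: CSR patterns for null calibration, Gaussian
blob mixtures with per-molecule labels for cluster recovery, and
parametric <L> curves (flat / saturating / ramp) with known convergence
behaviour for the regime classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clusters import NOISE
from .geometry import Box, PointPattern

__all__ = ["BlobSpec", "generate_csr", "generate_blobs", "generate_l_curve"]


def generate_csr(n: int, box: Box | None = None, seed: int = 0) -> PointPattern:
    """Uniform i.i.d. pattern of ``n`` molecules (deterministic per seed)."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    box = box or Box()
    rng = np.random.RandomState(seed)
    x = rng.random_sample(n) * box.width
    y = rng.random_sample(n) * box.height
    return PointPattern.from_xy(x, y, box)


@dataclass(frozen=True)
class BlobSpec:
    """Blueprint for a clustered fixture: Gaussian blobs on a CSR background.

    ``blobs`` is a sequence of (centre, sigma_nm, size) tuples; blob
    members are drawn from isotropic Gaussians and wrapped onto the
    torus (not truncated), the background is uniform.
    """

    n_background: int
    blobs: Sequence[tuple[tuple[float, float], float, int]] = ()
    box: Box = field(default_factory=Box)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        for centre, sigma, size in self.blobs:
            if sigma <= 0:
                raise ValueError(f"blob sigma must be positive, got {sigma}")
            if size < 0:
                raise ValueError(f"blob size must be non-negative, got {size}")


def generate_blobs(spec: BlobSpec) -> tuple[PointPattern, np.ndarray]:
    """Generate the blob fixture with ground-truth labels.

    Returns the pattern and an integer label per molecule: blob index
    for members, NOISE (-1) for background.
    """
    rng = np.random.RandomState(spec.seed)
    chunks = []
    labels = []
    for b, (centre, sigma, size) in enumerate(spec.blobs):
        pts = np.asarray(centre, dtype=float) + rng.normal(0.0, sigma, size=(size, 2))
        chunks.append(pts)
        labels.append(np.full(size, b, dtype=np.int64))
    bg = np.column_stack(
        [
            rng.random_sample(spec.n_background) * spec.box.width,
            rng.random_sample(spec.n_background) * spec.box.height,
        ]
    )
    chunks.append(bg)
    labels.append(np.full(spec.n_background, NOISE, dtype=np.int64))
    pos = np.vstack(chunks) if chunks else np.empty((0, 2))
    pos[:, 0] %= spec.box.width
    pos[:, 1] %= spec.box.height
    return PointPattern(pos, spec.box), np.concatenate(labels)


def generate_l_curve(
    family: str,
    n_frames: int = 30000,
    dt_ms: float = 10.0,
    base: float = 100.0,
    amplitude: float = 80.0,
    tau_s: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric <L> curve (times in s, values in nm) with seeded noise.

    Families: ``flat`` stays at ``base``; ``saturating`` relaxes from
    ``base`` to ``base + amplitude`` with time constant ``tau_s``
    (known closed-form plateau time); ``ramp`` rises linearly by
    ``amplitude`` over the run (elevated and still rising at the end).
    """
    times = np.arange(n_frames + 1) * (dt_ms / 1000.0)
    if family == "flat":
        series = np.full_like(times, base)
    elif family == "saturating":
        series = base + amplitude * (1.0 - np.exp(-times / tau_s))
    elif family == "ramp":
        series = base + amplitude * times / times[-1]
    else:
        raise ValueError(f"unknown curve family {family!r}")
    if noise_sd > 0:
        series = series + np.random.RandomState(seed).normal(0.0, noise_sd, times.size)
    return times, series
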