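"""Convergence analytics: plateau time, error, regime taxonomy, cut-off.

Three regimes are distinguished from a <L> time series (typically the
ensemble mean over replicates):

``converged``
    The series reached a horizontal asymptote distinct from the CSR
    level within the run.  Operationalised as: the series stays within
    ``plateau_tol`` (relative) of its final value for at least the last
    ``plateau_window`` seconds, and the final value exceeds the CSR
    level by more than ``csr_margin``.
``csr``
    The final value is within ``csr_margin`` of the CSR level and the
    end-window trend is flat (|slope| below ``trend_tol``) — the
    molecules still form a completely spatially random pattern.
``converging``
    Elevated above CSR but the plateau has not been reached (or the
    series is still rising).

Sweeping the clustering target across these regimes exposes the
digitization cut-off: the smallest target at (and beyond) which the
system no longer aggregates at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RegimeParams",
    "RegimeSummary",
    "convergence_time",
    "convergence_error",
    "classify_regime",
    "summarize_regime",
    "detect_cutoff",
]


@dataclass(frozen=True)
class RegimeParams:
    """Thresholds operationalising 'horizontal asymptote' and 'CSR band'.

    csr_level:
        Baseline <L> of a CSR pattern (the density radius R), nm.
    plateau_tol:
        Relative half-width of the plateau band around the final value.
    csr_margin:
        Elevation (nm) above ``csr_level`` required to count as clustered.
    plateau_window:
        Minimum time (s) the series must dwell in the plateau band for
        the asymptote to count as reached.
    trend_window / trend_tol:
        Window (s) and |slope| bound (nm/s) of the end-of-run linearised
        trend used to call a flat CSR series.
    """

    csr_level: float = 100.0
    plateau_tol: float = 0.02
    csr_margin: float = 5.0
    plateau_window: float = 60.0
    trend_window: float = 60.0
    trend_tol: float = 0.02


@dataclass(frozen=True)
class RegimeSummary:
    """Per-target classification of one <L> series."""

    regime: str
    convergence_time: Optional[float]
    error: Optional[float]
    final_mean_l: float
    l_target: Optional[float] = None
    target_count: Optional[float] = None


def _validate_series(l_series, times) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(l_series, dtype=np.float64)
    t = np.asarray(times, dtype=np.float64)
    if s.size == 0:
        raise ValueError("empty <L> series")
    if s.shape != t.shape:
        raise ValueError("l_series and times must have equal length")
    return s, t


def convergence_time(
    l_series, times, params: RegimeParams = RegimeParams()
) -> Optional[float]:
    """Earliest time from which the series stays within the plateau band.

    Returns the first time t* such that |<L>(t) - <L>(end)| stays within
    ``plateau_tol`` x <L>(end) for all t >= t*, provided the final value
    is elevated above the CSR band and the plateau lasts at least
    ``plateau_window`` seconds; None otherwise.
    """
    s, t = _validate_series(l_series, times)
    l_end = s[-1]
    if l_end <= params.csr_level + params.csr_margin:
        return None
    outside = np.abs(s - l_end) > params.plateau_tol * l_end
    idx = np.flatnonzero(outside)
    t_star = t[0] if idx.size == 0 else t[min(idx[-1] + 1, t.size - 1)]
    if t_star > t[-1] - params.plateau_window:
        return None
    return float(t_star)


def convergence_error(final_mean_l: float, l_target: float) -> float:
    """Relative overshoot (<L>(end) - L_target) / L_target (sign preserved)."""
    if l_target <= 0:
        raise ValueError(f"l_target must be positive, got {l_target}")
    return (final_mean_l - l_target) / l_target


def _end_slope(s: np.ndarray, t: np.ndarray, window: float) -> float:
    mask = t >= t[-1] - window
    if mask.sum() < 2:
        mask[-2:] = True
    coef = np.polyfit(t[mask], s[mask], 1)
    return float(coef[0])


def classify_regime(l_series, times, params: RegimeParams = RegimeParams()) -> str:
    """Assign one of the three regimes to a <L> series."""
    s, t = _validate_series(l_series, times)
    if convergence_time(s, t, params) is not None:
        return "converged"
    l_end = s[-1]
    if (
        l_end <= params.csr_level + params.csr_margin
        and abs(_end_slope(s, t, params.trend_window)) <= params.trend_tol
    ):
        return "csr"
    return "converging"


def summarize_regime(
    l_series,
    times,
    l_target: float,
    params: RegimeParams = RegimeParams(),
    target_count: Optional[float] = None,
) -> RegimeSummary:
    """Full per-target summary: regime, convergence time, error, final <L>."""
    s, t = _validate_series(l_series, times)
    regime = classify_regime(s, t, params)
    t_star = convergence_time(s, t, params) if regime == "converged" else None
    err = convergence_error(float(s[-1]), l_target) if regime != "csr" else None
    return RegimeSummary(
        regime=regime,
        convergence_time=t_star,
        error=err,
        final_mean_l=float(s[-1]),
        l_target=l_target,
        target_count=target_count,
    )


def detect_cutoff(
    sweep: Sequence[tuple[float, str]], trivial_max_target: float = 10.0
) -> Optional[float]:
    """Digitization cut-off from an ascending (target, regime) sweep.

    The cut-off is the smallest target classified ``csr`` such that all
    larger tested targets are also ``csr``; targets at or below
    ``trivial_max_target`` (the CSR calibration level itself, ~7
    encircled molecules) are ignored, as remaining CSR there is the
    trivial non-clustering case rather than a failure to aggregate.
    Returns None when every (non-trivial) target aggregates.
    """
    targets = [t for t, _ in sweep]
    if any(b < a for a, b in zip(targets, targets[1:])):
        raise ValueError("sweep targets must be sorted ascending")
    cutoff = None
    for target, regime in sweep:
        if target <= trivial_max_target:
            continue
        if regime == "csr":
            if cutoff is None:
                cutoff = float(target)
        else:
            cutoff = None
    return cutoff
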