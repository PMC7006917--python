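"""Sweep drivers: target grids, ensemble descriptors, regime tables.

This module glues the simulator to the analytics the experiments
report: run a seeded ensemble per clustering target, classify the
ensemble-mean <L> series, average the cluster descriptors of the final
frames, and locate the digitization cut-off over the sweep.  Results
come back as tidy pandas tables, one row per target.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .clusters import analyze_pattern
from .regimes import RegimeParams, detect_cutoff, summarize_regime
from .simulate import EnsembleResult, SimulationConfig, run_ensemble

__all__ = [
    "ensemble_descriptors",
    "run_target_sweep",
    "sweep_cutoff",
]


def ensemble_descriptors(
    ensemble: EnsembleResult,
    linking_radius: float = 50.0,
    min_neighbors: int = 5,
    min_size: int = 5,
) -> dict:
    """Cluster descriptors of the ensemble's final frames, averaged per ROI.

    Cluster count and % clustered are averaged over every replicate;
    molecules-per-cluster and radius are averaged over replicates that
    contain at least one cluster (they are undefined otherwise).
    """
    reports = [
        analyze_pattern(p, linking_radius, min_neighbors, min_size)
        for p in ensemble.final_patterns
    ]
    sizes = [r.mean_molecules_per_cluster for r in reports if r.n_clusters > 0]
    radii = [r.mean_cluster_radius for r in reports if r.n_clusters > 0]
    return {
        "n_clusters": float(np.mean([r.n_clusters for r in reports])),
        "pct_clustered": float(np.mean([r.pct_clustered for r in reports])),
        "molecules_per_cluster": float(np.mean(sizes)) if sizes else None,
        "cluster_radius_nm": float(np.mean(radii)) if radii else None,
        "n_replicates": len(reports),
    }


def run_target_sweep(
    target_counts: Sequence[float],
    n_reps: int = 5,
    seed: int = 0,
    config_factory: Optional[Callable[[float], SimulationConfig]] = None,
    regime_params: Optional[RegimeParams] = None,
    descriptors: bool = True,
    cluster_kwargs: Optional[dict] = None,
    sim_engine: str = "numba",
) -> pd.DataFrame:
    """Run an ensemble per target and tabulate regimes and descriptors.

    ``config_factory`` maps a target count to a
    :class:`~memclust.simulate.SimulationConfig` (defaults to the
    Standard Condition); each target's ensemble seeds derive from
    ``seed`` and the target so replicates are independent across the
    sweep.  Returns one row per target with the regime classification
    of the ensemble-mean <L> series, convergence time, error, final
    <L>, and (optionally) the averaged final-frame cluster descriptors.
    """
    if config_factory is None:
        config_factory = SimulationConfig.standard
    cluster_kwargs = cluster_kwargs or {}
    rows = []
    for k, target in enumerate(target_counts):
        config = config_factory(target)
        if regime_params is None:
            params = RegimeParams(csr_level=config.density_radius)
        else:
            params = regime_params
        ens = run_ensemble(
            replace(config, seed=int((seed + 1) * 100003 + k) % 2**31),
            n_reps,
            sim_engine=sim_engine,
        )
        summary = summarize_regime(
            ens.mean_l, ens.times, config.profile.l_target, params, target_count=target
        )
        row = {
            "target_count": float(target),
            "target_l_nm": config.profile.l_target,
            "regime": summary.regime,
            "convergence_time_s": summary.convergence_time,
            "error": summary.error,
            "final_mean_l_nm": summary.final_mean_l,
        }
        if descriptors:
            row.update(ensemble_descriptors(ens, **cluster_kwargs))
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_cutoff(sweep_table: pd.DataFrame, trivial_max_target: float = 10.0) -> Optional[float]:
    """Digitization cut-off from a :func:`run_target_sweep` table."""
    pairs = list(
        zip(sweep_table["target_count"].tolist(), sweep_table["regime"].tolist())
    )
    return detect_cutoff(pairs, trivial_max_target=trivial_max_target)
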