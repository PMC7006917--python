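"""Regime taxonomy and the digitization cut-off (reduced-scale sweep).

Sweeps the clustering target across the three regimes with small
ensembles (n = 3 replicates; the full study uses 30) and locates the
cut-off: the smallest target beyond which the molecules simply refuse
to aggregate.  Takes a few minutes on one CPU.
"""

import memclust as mc

targets = [25.0, 45.0, 55.0, 65.0, 69.0]
print(f"sweeping targets {targets} with n = 3 replicates each ...")
table = mc.run_target_sweep(
    targets,
    n_reps=3,
    seed=1,
    config_factory=lambda tc: mc.SimulationConfig.standard(tc, record_every=None),
    descriptors=False,
)
cols = ["target_count", "regime", "convergence_time_s", "error", "final_mean_l_nm"]
print(table[cols].to_string(index=False))
print(f"\ncut-off target: {mc.sweep_cutoff(table)}")
print("-> low targets converge (with positive overshoot error), intermediate "
      "ones are still rising after 5 min, and beyond the cut-off the "
      "pattern stays CSR: aggregation switches off digitally.")
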