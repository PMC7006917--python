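"""Effect of a cortical-actin picket fence on clustering.

Runs the target-25 condition without a mesh and with a dense 250 nm
grid of reflective barriers (n = 3 replicates each) and compares the
cluster descriptors: the fence compartmentalises diffusion, giving
more, smaller clusters.
"""

import memclust as mc

for spacing in (None, 250.0):
    cfg = mc.SimulationConfig.standard(
        target_count=25, mesh_spacing=spacing, seed=1, record_every=None
    )
    ens = mc.run_ensemble(cfg, 3)
    d = mc.ensemble_descriptors(ens)
    label = "no mesh " if spacing is None else f"{spacing:.0f} nm mesh"
    print(f"{label}: {d['n_clusters']:5.1f} clusters of "
          f"{d['molecules_per_cluster']:5.1f} molecules "
          f"({d['pct_clustered']:.1f}% clustered)")
print("-> denser actin mesh: more but smaller clusters, as in the "
      "picket-fence picture of membrane compartmentalisation.")
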