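# memclust

Agent-based simulation of molecular aggregation at the plasma membrane,
with the point-pattern analytics to quantify it.

## The scientific problem

Signalling proteins in the plasma membrane form nanoscale clusters, and
small changes in their spatio-temporal organisation can gate downstream
signalling ("digitization").  The biophysical drivers — lipid domains,
self-affinity, size exclusion, the cortical-actin picket fence — are
numerous, intertwined and hard to model mechanistically.  `memclust`
takes the abstracted route: every molecule is an agent whose Brownian
step size depends only on its *local* clustering level, a single
"desire for clustering" rule.  Molecules diffuse on a toroidal
3 × 3 µm² membrane patch and slow down as their neighbourhood
approaches a target density; at the target they stop (or keep a
residual mobility, depending on the profile variant).  That one rule is
enough to recapitulate nanocluster formation, sharp digitization
cut-offs, and the characteristic effects of diffusion speed and actin
meshwork density seen in single-molecule localization microscopy.

The package is aimed at membrane biophysicists and SMLM analysts who
want a desk-scale sandbox for clustering hypotheses: every experiment
runs in seconds-to-minutes on one CPU.

## The model

- 2000 agent-molecules on a 3 × 3 µm² region of interest with toroidal
  (periodic) boundaries; completely spatially random (CSR) initial
  condition; 10 ms frames for 5 simulated minutes (30 000 frames).
- Local density of molecule *i* is the localized, linearised Ripley's L:

      L_i = sqrt( A · k_i / (π (n − 1)) )

  with `k_i` the number of other molecules within R = 100 nm (toroidal
  distance), `A` the patch area, `n` the molecule count.  At CSR the
  mean L equals R (~7 molecules encircled within 100 nm).
- Each frame, every molecule's displacement rate follows a profile
  D(L_i) that decays from `D_max` (3.5 nm/ms in the Standard Condition)
  to zero at the target L — molecules at or above target are immobile.
  Variants: a rate floor `D_min` > 0, a tent profile immobile only at
  exact equality, quadratic decay, Gaussian instead of fixed-length
  steps, and ×√10 / ÷√10 step scalings for fast / slow diffusion.
- Optional cortical-actin meshwork: a regular grid of reflective
  barriers (250/500/1000 nm pitch) that obstructs motion but is
  transparent to density sensing.
- Analytics: per-frame ⟨L⟩ series; regime classification
  (converged / converging / csr) with convergence time and relative
  overshoot error; digitization cut-off detection over target sweeps;
  density-based cluster calling with per-ROI descriptors (cluster
  count, % clustered, molecules per cluster, cluster radius).

## Worked example

```python
import memclust as mc

# Standard Condition, target 25 encircled molecules, one replicate
cfg = mc.SimulationConfig.standard(target_count=25, seed=1)
rec = mc.run_simulation(cfg)
print(f"<L100> start {rec.l_series[0]:.1f} nm -> end {rec.l_series[-1]:.1f} nm "
      f"(target {cfg.profile.l_target:.1f} nm)")

report = mc.analyze_pattern(rec.final_frame)
print(f"{report.n_clusters} clusters, {report.pct_clustered:.1f}% clustered, "
      f"{report.mean_molecules_per_cluster:.1f} molecules/cluster, "
      f"radius {report.mean_cluster_radius:.1f} nm")
```

prints (exact values depend on the seed):

```
<L100> start 98.7 nm -> end 225.9 nm (target 189.3 nm)
28 clusters, 100.0% clustered, 71.4 molecules/cluster, radius 56.0 nm
```

The ⟨L⟩ series starts at the CSR level (~100 nm), rises as nucleation
sites appear within seconds, and plateaus *above* the 189 nm target —
the systematic overshoot characteristic of the freeze-at-target rule.
The final frame holds ~30 clusters of ~70 molecules, a few tens of nm
in radius: nanoclusters at SMLM scale.

Longer narrative scripts live in `examples/` (one per capability:
density maps, single runs, cluster descriptors, regime sweeps and the
cut-off, actin meshes).  A thin CLI wraps the same functions:
`memclust simulate|sweep|clusters|analyze|fixtures --help`.

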