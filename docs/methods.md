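# Methods

## Model

Each of `n` agent-molecules carries a position on a rectangular patch
with periodic (toroidal) boundaries, so the molecule count is conserved
and no edge correction is needed.  Per frame (Δt = 10 ms by default)
the update is synchronous:

1. every molecule's neighbour count `k_i` within radius R (default
   100 nm, toroidal metric, ties at exactly R included) is measured on
   the pre-move snapshot;
2. its local clustering level is the localized linearised Ripley's L,
   `L_i = sqrt(A k_i / (π (n − 1)))`, normalised so a CSR pattern has
   mean L ≈ R (at the reference scale, 2000 molecules on 3 × 3 µm²,
   R = 100 nm encircles ~7 molecules);
3. its displacement rate follows the profile `D(L_i)` (below);
4. it takes one step of length `D · Δt` in a uniformly random direction
   (or, in Gaussian mode, with independent normal coordinate increments
   whose RMS step length equals `D · Δt`);
5. reflective mesh barriers are applied, then the toroidal wrap.

The synchronous update — all rates from the same pre-move pattern — was
chosen over sequential updating because it is order-independent and
exactly reproducible; an asynchronous random-order variant is available
in the pure-Python engine for sensitivity checks, and at the default
scale the two agree qualitatively (the per-frame displacement is tiny
relative to R).

The per-frame mean of the `L_i` (the ⟨L⟩ series) is recorded from the
same pre-move density pass, one value per frame time.

### Displacement profiles ("desire for clustering")

All profiles interpolate between `d_max` at `l_anchor` (default 0) and
a minimum at the target `l_target`, expressed equivalently as a target
neighbour count through the L↔count bijection:

| family | D(L) for L in [anchor, target] | at/above target |
|---|---|---|
| `linear_converging` | `d_max (l_target − L)/(l_target − l_anchor)` | 0 (immobile) |
| `linear_floor` | same, floored at `d_min` | `d_min` |
| `tent_nonconverging` | `d_max · min(1, |l_target − L|/span)` | 0 only at exact equality, rising again above |
| `quadratic` | linear ramp squared | 0 |

Standard Condition: `linear_converging`, `d_max = 3.5 nm/ms`
(35 nm/frame), `d_min = 0`.  The anchor at L = 0 makes the profile a
straight line from `d_max` at zero density to zero at the target; it is
configurable because the literature leaves the intercept open.  Fast
and slow variants scale the step length by √10 and 1/√10, mapping a
×10 / ÷10 change of the effective diffusion coefficient
(`D_eff = step² / (4 Δt)`).

Units: rates are nm/ms; a rate of 3.5 nm/ms at 10 ms frames means
35 nm per frame, i.e. an effective `D_eff ≈ 0.03 µm²/s` — within the
span reported for transmembrane proteins.  Published figures sometimes
quote such motion as "~0.1 µm²/s"; the step length is the primitive
here and the diffusion-coefficient label is treated as descriptive.

### Actin mesh

Cortical actin is modelled as a static regular grid of reflective line
barriers (pitch 250/500/1000 nm; the pitch must divide the box).
Reflection is specular per axis, implemented as a triangular fold with
period twice the pitch, which applies the mirrors in crossing order;
agents therefore never leave their mesh cell.  Barriers obstruct motion
only — density sensing crosses them, since a fence below the membrane
does not change in-plane distances.  Fixed-length steps must be shorter
than the pitch (validated); Gaussian steps are folded by the same rule.

### Known behaviour at the trivial target

With the target at the CSR calibration level (~7 encircled molecules)
the freeze-at-or-above rule acts as a weak ratchet: molecules stop once
their neighbourhood reaches the target, so ⟨L⟩ creeps a few percent
above R (to ~115 nm) before the pattern freezes, without forming
clusters.  Regime analysis therefore treats targets at or below ~10
encircled molecules as the trivial CSR case rather than a cut-off.

## Numerics

- Neighbour counting uses a cell list (bin width ≥ max(R, 1 nm)); each
  unordered pair is examined once via a half-neighbourhood sweep with
  per-cell wrap shifts.  Below 4 bins per axis the minimum image is not
  grid-resolvable and an exact all-pairs sweep is used instead.  Both
  routes agree integer-for-integer (property-tested against each other
  and against a periodic KD-tree oracle).
- During a run the counts are maintained incrementally: pairs involving
  molecules that moved are removed at the old position and re-inserted
  at the new one (each pair touched once per phase), falling back to a
  full recount whenever most molecules are mobile.  This makes
  converged runs — where nearly everyone is frozen inside dense
  clusters — orders of magnitude cheaper than re-scanning the
  quadratic intra-cluster pairs each frame.
- Once every molecule is immobile under a freezing profile the pattern
  is provably static and the remaining frames are filled without
  simulation.
- Random numbers: one MT19937 stream per replicate, split (via
  `SeedSequence`) into an initialisation stream and a motion stream, so
  changing the step mode never perturbs the initial pattern.  The numba
  kernel and the pure-Python reference stepper consume the motion
  stream draw-for-draw (one uniform per fixed step, two per Gaussian
  step, molecule-index order) and agree to ≤1e-9 nm — strict bit
  equality is not asserted because libm/compiler ulp differences in
  cos/sin are amplified by the chaotic dynamics.
- Coordinates are doubles in nm on the half-open box `[0, w) × [0, h)`.

## Cluster analysis

The reference cluster engines used on SMLM data (Bayesian engines with
topographic prominence thresholding) are separate published methods;
here a deterministic density-based caller stands in: molecules with at
least `min_neighbors = 5` others within `linking_radius = 50 nm`
(periodic KD-tree) are cores, density-connected cores form clusters,
non-core molecules join their nearest core within reach, and components
below `min_size = 5` are noise.  Consequences, measured on fixtures and
simulations: well-separated blobs are recovered exactly, but a CSR
background of 2000 molecules yields ~35–40 spurious small clusters
(~16% of molecules) where a Bayesian engine reports essentially none —
descriptor comparisons therefore carry a ±30% band, and ensembles
mixing CSR and collapsed replicates (the fast condition near its
cut-off) are dominated by this caller artifact.

Cluster radius: the default statistic is the per-axis standard
deviation of members about the wrap-aware (circular-mean) centroid —
σ of the matching isotropic Gaussian, i.e. RMS distance/√2.  The
equivalent-uniform-disc radius (√2 × RMS, exactly 2σ) is available as
`kind="disc"`.  σ was adopted as the default after the disc form proved
systematically twice the cluster radii reported for comparable
simulated data, while σ matches them and their overall 25–160 nm range;
the choice is documented so either convention can be selected.

Per-ROI descriptors (cluster count, % clustered, molecules per cluster,
mean radius) are averaged across replicate ROIs; size and radius means
skip replicates with no clusters (undefined there).

## Regime analysis

"Horizontal asymptote" is operationalised with explicit, configurable
thresholds (`RegimeParams`): the plateau band is ±2% of the final ⟨L⟩,
a plateau must last ≥ 60 s, the CSR band is `csr_level + 5 nm`
(csr_level defaults to R), and a flat end-trend means |slope| ≤
0.02 nm/s over the final 60 s.  `converged` = plateau reached and
elevated; `csr` = final value in the CSR band with a flat trend;
`converging` = the rest.  Classification runs on the ensemble-mean
series (per-replicate classification is available for dispersion).  The
cut-off over a target sweep is the smallest non-trivial target
classified csr with all larger tested targets also csr.

On synthetic saturating curves the plateau time matches the closed-form
band-crossing time to within one frame, by construction of the scan.

## Problem sizes and tolerances

Full-scale study conditions (2000 molecules, 30 000 frames) are used
throughout; stochastic reproductions run 5–10 replicates per condition
instead of 30, a deliberate desk-scale choice.  Ensemble means of
cluster descriptors at n = 5–10 have relative standard errors of a few
to ~15%, and near-cut-off conditions are bimodal across seeds (collapse
versus CSR), so descriptor checks use ±30% bands and cut-off checks a
~20% band on the target count.  The long-run persistence check runs the
beyond-cut-off target at 3× the standard duration.

## What the synthetic fixtures do and do not show

The fixture generators produce CSR patterns, wrapped-Gaussian blob
mixtures with ground-truth labels, and parametric ⟨L⟩ curves.  They
validate the analysis stack (counting, calling, classification) against
closed forms — they do not emulate SMLM localization error, blinking or
multiple detections, so passing them says nothing about robustness to
those acquisition artifacts; the cluster caller's thresholds would need
recalibration for real localization tables with appreciable noise.

## Limitations

- The caller substitution above is the main source of disagreement with
  Bayesian-engine descriptor values; counts and sizes agree to tens of
  percent, CSR false positives do not.
- The environment is static: no actin remodelling, no semi-permeable
  (hop-diffusion) barriers, no birth/death or binding kinetics, and
  clusters do not diffuse as rigid bodies once frozen.
- Density sensing at tens of nm has no molecular mechanism; the model
  is deliberately phenomenological ("as if" sensing).
- Near the cut-off, outcomes are strongly seed-dependent (nucleation is
  rare-event-like); ensemble sizes of 5–10 locate the cut-off only to
  about one grid step (±2 encircled molecules).
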