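# Methods

## Physical model

A treatment is a sequence of independent electrode-pair activations.
During one activation, pulse timescales (µs) are far below charge
relaxation at tissue scale, so the field is quasi-electrostatic and the
potential obeys current conservation

    div( sigma * grad(phi) ) = 0

on a cubic tissue domain of edge 7.5 cm — large enough that the outer
boundary (zero normal current, i.e. electrical insulation) does not
influence the field near the electrodes. The active electrodes are the
exposed cylinders of two needles: the source is held at the applied
voltage, the sink at ground. Needles not in the active pair remain in the
tissue as passive conductive inclusions.

Two conductivity laws are supported:

* **static** — sigma = sigma0 everywhere;
* **dynamic** — sigma(|E|) rises from sigma0 to sigma_max across a
  transition zone, modeling the conductivity increase caused by membrane
  permeabilization.

The dynamic law is a quintic smoothstep s(t) = 6t^5 − 15t^4 + 10t^3
mapped onto the transition: sigma0 below E_center − E_width/2, sigma_max
above E_center + E_width/2. The quintic is the minimal-order polynomial
step with vanishing first *and* second derivatives at both ends, giving
the law C² continuity (the smoothing family is an implementation detail;
any C² step with the same edges is equivalent at the fidelity of this
model). The law is applied to the whole tissue domain, and
sigma(E_center) = (sigma0 + sigma_max)/2 exactly.

Key parameters (units, defaults, origin):

| parameter | default | meaning |
|---|---|---|
| sigma0 | 0.284 S/m | baseline prostate conductivity (low-voltage pre-pulse measurement; not identifiable from NanoKnife data, hence fixed) |
| sigma_max | calibrated per patient | fully electroporated conductivity ceiling |
| E_center, E_width | 500, 800 V/cm | transition zone of the dynamic law |
| voltage rule | min(1500 V/cm × spacing, 3000 V) | clinical voltage-to-distance protocol with generator cap |
| electrode radius | 0.05 cm | 1 mm-diameter needle (not stated in trial records; configurable) |
| electrode conductivity | 2e6 S/m | stainless steel |
| pulses | 90 × 70 µs per pair | carried as metadata; no electrostatic consequence in this model |

## Discretization and solver

Cell-centered finite volumes on a regular isotropic voxel grid (default
64³ over 7.5 cm; minimum 16), 7-point stencil, **harmonic-mean face
conductivities**. The scheme is locally conservative, so delivered
current is computed exactly as the discrete flux through the closed
surface of voxel faces around an electrode, and source/sink currents
agree to solver tolerance rather than discretization error.

Electrode handling:

* Rasterization is center-inside against an effective radius
  max(radius, 0.71·h): the physical radius (0.5 mm) is below the default
  grid spacing (1.2 mm), so the electrode is represented as a contiguous
  ≥1-voxel column.
* Active electrodes are equipotential Dirichlet voxel sets. The imposed
  potential is placed on the *faces* bounding the electrode (half-cell
  conductance doubling), i.e. the conductor surface is the voxel-face
  surface. This removes an O(h) staircase offset that otherwise biases
  currents by ~2–3% at clinically relevant radii.
* **Sub-grid wire correction**: the current of a needle electrode depends
  logarithmically on its radius, so a rasterized column one voxel wide
  overestimates it grid-dependently. For electrodes with radius r_w < h,
  the lateral Dirichlet-face conductances are replaced by the conductance
  of radial flow through a quarter annulus from the wire surface to the
  neighbor cell center, g = σ·h·(π/2)/ln(h/r_w) — the same device as
  Peaceman well indices in reservoir simulation. This reduces the
  inter-resolution current spread from ~26% to ~4% over 48³–96³ grids;
  the per-patient conductivity calibration absorbs the remainder
  consistently between forward and inverse runs.
* Inactive electrodes keep their metallic conductivity capped at
  1e4 × sigma0. Beyond contrast ~1e3 the solution is insensitive to the
  cap (verified by a sensitivity test) while conditioning stays benign.

Linear solves: matrix-free conjugate gradients (relative tolerance 1e-6,
configurable) preconditioned by the spectrally exact inverse of the
constant-coefficient Neumann Laplacian via type-II DCTs, with Dirichlet
voxels handled by subspace embedding and the constant mode regularized.
Typical iteration counts are 20–90 at 64³ regardless of conductivity
contrast, and the operator is applied with shifted-array arithmetic so
Picard updates cost no matrix re-assembly. Solves are deterministic for
fixed inputs.

Nonlinear (dynamic) solves use under-relaxed Picard iteration:
sigma_k+1 = sigma_k + ω(sigma(|E_k|) − sigma_k) with ω = 0.8 by default
(ω = 0.5 converges to the same currents in more iterations), stopping
when the source current changes by < 1e-3 relatively, cap 100 iterations;
non-convergence is flagged on the returned solution, never silently
accepted. Warm starts (previous potential and conductivity field) are
used across Picard steps, bisection steps and the static→dynamic chain;
they affect only the iteration path.

|E| is the magnitude of the central-difference gradient (one-sided at the
boundary), reported in V/cm.

## Inversions

**Conductivity calibration.** The forward first-pair current is monotone
non-decreasing in sigma_max (asserted by test), so the match to the
measured current is found by bisection on [sigma0, 2.0] S/m, terminating
at relative current mismatch < 1e-3 or bracket width < 1e-4 S/m. A
parametric grid sweep (default step 0.01 S/m) is available behind the
`grid_step` argument for fidelity runs. The first activation (largest
spacing) is used because it is clinically delivered first, before
preceding pulses have permeabilized the tissue. Measured currents outside
the achievable interval raise an error naming that interval.

**Threshold extraction.** Super-level-set volumes of the voxelwise
maximum field are evaluated for every integer threshold (1 V/cm grid, one
sort + vectorized search). The reported threshold minimizes the absolute
volume mismatch; exact matching is impossible on a discrete grid. Ties —
which arise on plateaus where a 1 V/cm bin contains no voxel value — are
broken toward the lower threshold, i.e. the larger (conservative)
predicted kill zone. The volume integral runs over the whole tissue
domain, not only the observed mask.

## Synthetic patients

The generator emulates the trial's treatment records: four parallel
needles on a square grid with side sampled uniformly in [1.4, 2.2] cm,
exposure length from {1.5, 2.0} cm, sigma_max_true uniform in
[0.55, 1.0] S/m, threshold_true uniform in [412, 614] V/cm. Pre-treatment
PSA is drawn in [3.8, 10.03] ng/mL through a Gaussian copula with the
threshold (copula correlation −0.624 by default) — the association is
planted, not modeled, so cohort-level correlation analyses have a known
effect to detect (with uniform marginals the induced Pearson r is
(6/π)·asin(ρ/2) ≈ −0.61 at the default). The "measured" current is the
forward dynamic first-pair current with multiplicative Gaussian noise
(1% relative by default); the ablation mask is the super-level set of
the forward maximum-field distribution at threshold_true; the change in
current is defined as dynamic-minus-static first-pair current (no
clinical definition of this column exists). Per-patient substreams of the
seed make cohorts bit-reproducible and extensible without reshuffling.

What the generator does *not* emulate: real lesion shapes (clinical
masks are MRI segmentations, not exact model level sets), segmentation
error, tissue heterogeneity (urethra, vessels, nerves), lesion evolution
between treatment and imaging, and pulse-number effects. Same-grid
closed-loop tests are therefore an *inverse crime* — they validate the
correctness and invertibility of the chain, not clinical accuracy; a
cross-resolution test (generate at 64³, infer at 48³) bounds the
discretization sensitivity at 5% instead.

## Problem sizes in the shipped tests

Unit and property tests run at 16³–32³. Analytic solver oracles
(parallel plate exact; concentric cylinders within 2%, measured 0.3%)
run at 128³. The closed-loop recovery suite uses 5 noise-free synthetic
patients at 64³ (sigma_max within 2%, threshold within 2 V/cm, dynamic ≥
static threshold) and 10 patients with 1% current noise at 48³ with
first-pair-only forward simulation (median sigma_max error ≤ 5%); the
noise-robustness of the calibration is a property of the current match,
not of the grid.

## Statistics

Pearson r with the exact two-sided t-transform p-value (scipy). The
power column reproduces *retrospective (observed) power*: the
noncentral-F exceedance probability at the α = 0.05 critical value with
noncentrality equal to the observed F = (n−2)r²/(1−r²) on (1, n−2)
degrees of freedom — this matches the published power values to ≈0.1
percentage point, whereas a prospective Fisher-z calculation (also
provided, `method="fisher"`) differs by up to ~6 pp. The change-in-PSA
correlation row cannot be recomputed because post-treatment PSA values
are not tabulated; the reproduction flags it as missing rather than
imputing. No multiple-testing correction is applied (none was used in
the source analysis). The Schwan utility TMP_max = 1.5·E·r supplies the
cell-size argument linking larger cells to lower lethal thresholds.

## Known limitations

* Homogeneous tissue; no urethra/vessel/nerve heterogeneity, no thermal
  or pulse-train dynamics, no inter-pair permeabilization memory.
* sigma0 is fixed, not jointly inverted (pre-pulse currents are not
  reported by the clinical generator).
* The voxel rasterization of sub-voxel electrode radii makes absolute
  currents weakly resolution-dependent; calibrated inversions are
  self-consistent, but comparing raw currents across resolutions shows
  O(h) drift.
* Thresholds are reported on the 1 V/cm scan grid as integers.
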