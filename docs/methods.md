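# Methods

## The generative model

Each T2*-weighted volume, resampled to a 1.5 mm isotropic working grid,
is modelled as a mixture of Gaussians over six tissue classes with
voxel-wise spatial priors and a multiplicative bias field:

```
p(y(x) | θ) = (1/ρ(x)) Σ_k b_k(x) Σ_j w_kj N( y(x)/ρ(x) ; μ_kj, σ²_kj )
```

* Classes and components: GWM 3, CSF 2, CMB 2, skull 3, scalp 2,
  background ("other") 4. Grey and white matter are merged because T2*
  contrast barely separates them at clinical field strength.
* Priors `b_k(x)` sum to one per voxel. The CMB class is a *rejection
  class* with a flat prior — 0.1 inside the brain mask, exactly 0
  outside — because microbleeds carry essentially no spatial prior
  information.
* `ρ(x) = exp(Σ_m c_m P_m(x))` with `P_m` the 3D monomials up to total
  degree 3 (20 terms) on grid coordinates normalised to [-1, 1]. The
  log-field is mean-centred over the brain, which fixes the
  scale-ambiguity between field and class means.

### Constraints

After every M-step the class means are projected (clipped) onto

* `min_j μ_CSF,j > μ̄_GWM (1 + ε)` and
* `max_j μ_CMB,j < 0.5 μ̄_GWM (1 − ε)`, with `ε = 1e-3`,

where `μ̄_GWM = Σ_j w_GWM,j μ_GWM,j`. This hard-codes the T2* intensity
ordering (CSF bright; microbleeds darker than half of parenchyma) and
confines the CMB search to the dark half of the histogram. Projection
can in principle reduce the EM objective; every projection iteration is
recorded in `MixtureModel.projection_events` and the monotonicity test
exempts exactly those iterations.

### EM numerics

* Initialisation is deterministic: class means at prior-weighted
  intensity quantiles; the two CMB components at the 2nd and 10th
  percentile of in-brain intensities; uniform within-class weights;
  common initial variance (10% of the robust in-brain range)².
* Variance floor `(0.01 × in-brain 1–99% range)²`; convergence when the
  relative log-likelihood change falls below `tol = 1e-5`; `max_iter =
  100`. A non-converged fit warns and returns the best state. A class
  whose total responsibility falls below one voxel is left at its
  previous parameters and flagged in `collapsed_classes`.
* Parameters are estimated on a decimated voxel lattice (every 2nd voxel
  per axis, i.e. 3 mm sampling at the 1.5 mm grid — the standard
  sampling-distance device of unified-segmentation implementations);
  class posteriors are always recomputed on the full grid at the final
  parameters. Oracle tests that compare against closed-form sample
  moments set `sampling_step = 1`.
* The E-step runs in a fused single-pass kernel (numba when available,
  numpy otherwise; both are cross-checked in the test suite). Component
  contributions more than 15 log-units below the per-voxel maximum are
  truncated to zero (< 3e-7 relative error).

### Bias estimation

The field is refitted only when the mixture has nearly converged at the
current field (relative log-likelihood change < 100·tol), at most four
times per fit — the estimate → correct → refit pattern. Each refit is a
ridge-regularised weighted least squares of the per-component
log-residual `log y − log μ_kj` on the polynomial basis over brain
voxels, with weights `r_kj · μ²_kj / σ²_kj` (the within-component
precision of `log y`). Precision weighting is essential on thick-slice
data: partial-volume components have broad variances and would otherwise
bend the field by 10–30%; with it, a null field is recovered to < 1%
and an imposed 20% field to < 5% maximum error. Per-iteration coupling
of field and mixture was tested and is unstable on these data; the
staged schedule is both faster and more accurate.

## Two-iteration detection

1. Resample the subject volume (linear) and priors (linear +
   renormalisation; masks nearest-neighbour) to the 1.5 mm working grid.
2. First constrained fit with the flat CMB prior.
3. Refinement cascade on the CMB posterior, in fixed order: binarise at
   0.2 (inclusive ≥) → label 26-connected components → size filter
   (< 2 voxels: `too_small`; > 0.675 cm³, a cylinder two slices high by
   8 mm diameter: `too_large`) → remove voxels with skull posterior
   ≥ 0.5 (`skull`) → remove voxels with CSF posterior > 0.5 plus their
   6-connected nearest neighbours (`csf_neighbour`) → discard whole
   components overlapping the artefact mask (`artefact_mask`). Partially
   masked components are re-labelled and re-measured; the size filter is
   re-checked afterwards so no survivor violates the bounds.
4. The surviving *probabilistic* posterior values (not a binary mask)
   replace the CMB prior; zero elsewhere, so the second pass can never
   introduce new candidate territory — it is strictly more specific.
5. Second fit, warm-started from the first-pass parameters.
6. Final threshold 0.5 on the second-pass CMB posterior, re-labelling,
   size re-filtering; each survivor is assigned the region (lobar /
   deep / infratentorial) of its centroid voxel.

Design choices made where the procedure was genuinely open: component
connectivity 26 (diagonal-touching hypointensities on thick slices are
one lesion) with 6-connected neighbour dilation (conservative reading of
"nearest neighbours"); whole-component discard on any artefact-mask
overlap; the refined prior kept probabilistic rather than binarised;
size/skull filters re-applied after the second pass so the shipped
output honours the size invariant. All are configurable in
`MidasConfig`. The manual-editing step of the semi-automated workflow is
represented by the per-component discard/restore audit trail (no GUI).

The artefact mask is the union of final detections from running the full
pipeline (without the artefact-mask step) on healthy-control volumes; it
marks recurrent false-positive territory such as air-bone interfaces.
Registration to a common space is affine-only (12-parameter, normalised
mutual information, staged Powell optimisation at 2 mm working
resolution); nonlinear warping is out of scope, and phantom-based tests
run pre-aligned. An externally computed deformation can be applied
through `resample_like`.

## The phantom

The generator emulates the target acquisition: 0.938 × 0.938 × 6.5 mm
voxels (5 mm excitation + 1.5 mm gap treated as one 6.5 mm cell, the
same convention used when quoting voxel volume), a head of nested
ellipsoids (scalp > skull > brain > ventricular CSF) with mean
intensities background 5, skull 25, GWM 100, scalp 120, CSF 180
(arbitrary units; CSF > GWM > 2 × CMB), spherical lesions multiplied
toward a configurable fraction of the local intensity (default 0.3 — no
numeric lesion contrast is established for this sequence, so the value
is a free, documented choice) with sub-voxel partial-volume weighting,
mimic primitives (inferior edge band, vessel tube, macrobleed), a
random second-order polynomial bias field scaled so `max|ρ−1|` equals
the requested amplitude, and additive Gaussian noise. Additive (rather
than Rician) noise is deliberate: at clinical T2* SNR the difference is
immaterial for these tests and it keeps recovery analytics closed-form.
Everything is bit-reproducible from the seed.

Ground truth records every lesion's centre, diameter, rasterised volume
(voxels at ≥ 50% sphere occupancy) and region; a lesion with no voxel at
half occupancy is recorded as sub-voxel. Region labels: deep = central
ellipsoid (38% brain radius), infratentorial = inferior cap (below 55%
of the inferior semi-axis), lobar = the rest.

What the phantom does **not** model: susceptibility physics and
blooming, cortical folding, k-space acquisition, Rician noise floors,
motion, and real mimic morphology. Passing tests therefore demonstrate
the correctness of the estimation and filtering machinery under the
stated geometry and contrast, not clinical performance on patient data.

## Validation scale

The acceptance screen uses 20 phantoms (~145 mm field of view;
97 × 97 × 101 working grid at 1.5 mm) with 2–5 lobar lesions each,
diameters uniform on [4, 8] mm, residual intensity 0.3, noise 5% of the
GWM mean, bias amplitude 0.1. These sizes keep a full 20-subject screen
within a few minutes on one CPU while preserving the acquisition
anisotropy that drives partial-volume behaviour. Unit tests use a
compact 90 mm field of view with the same voxel geometry.

## Agreement statistics

Cohen's κ on per-subject presence (defined as 1 for identical constant
ratings; NaN when chance agreement is 1 with disagreement), interpreted
on the bands < 0.2 poor, 0.2–0.4 fair, 0.4–0.6 moderate, 0.6–0.8 good,
> 0.8 excellent (boundary values assigned upward). Counts are compared
with ICC(2,1) — two-way random effects, absolute agreement, single
measure — computed from the mean-squares decomposition and cross-checked
against pingouin's ICC(A,1) in the tests; the absolute-agreement
single-measure variant is the standard choice for method-versus-
reference counts. Detection matching is greedy nearest-centroid,
one-to-one, within 5 mm by default; `TP + FN = |reference|` and
`TP + FP = |detections|` always hold.

## Known limitations

* The CMB class is a constrained rejection class: its component means
  sit at the 0.5·GWM bound whenever the dark-voxel population is
  brighter than the bound, so they are not unbiased estimates of lesion
  intensity (the recovery tests therefore target the GWM and CSF
  classes).
* Affine-only registration; no multispectral mode (the method is
  monospectral by design); no population-informed regional CMB prior.
* Thick slices make sub-5 mm lesions genuinely hard: a 4 mm sphere
  centred between slices can leave no voxel above half occupancy and may
  be missed — the same partial-volume failure mode expected on real
  clinical data.
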