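# Methods

This note documents the models, numerical choices, and synthetic-data
design behind `parcelpvc`, and what the package's tests do and do not
establish about real data.

## Forward PET model

A parcellation `L` (integer labels on a 3-D grid, background 0) and a
per-parcel activity vector `T` define the modeled PET image

    PET_model(x) = Σ_j T_j · (1_j * G_σ)(x),

where `1_j` is parcel j's binary indicator and `G_σ` an isotropic Gaussian
with `σ = FWHM / (2√(2 ln 2))`. Because convolution is linear and the
parcels tile the labeled region, the implementation paints all activities
first and blurs once; `blur_parcel_indicator` exists separately for GTM
assembly. The FWHM is specified in mm and converted to per-axis voxel
sigmas, so anisotropic voxels are handled. Kernels are truncated at 4σ
(sub-1e-5 mass loss) and the boundary is zero-padded, modeling air around
the head. The background is an explicit zero-activity region: spill off
the brain edge is real signal loss, and the GTM accounts for it (below).

Typical amyloid-PET resolution is 6–8 mm FWHM; 8 mm is the default
throughout, combining hardware resolution with residual patient motion.

## Goodness of fit

    fit = sqrt(mean((PET − PET_model)²)) / (mean(PET + PET_model) / 2)

with both means over a mask. The metric is symmetric and invariant to a
common positive rescaling of both images; 0 is a perfect fit, and values
above 1 are possible for grossly mismatched images (e.g. disjoint
support gives fit = 2). Two masks are used: whole brain (the labeled
region dilated by 3 face-connected iterations — the dilation keeps
near-edge spill inside the mask) and cortex only (the union of cortical
parcels). The means are computed inside the dilated mask by default; a
flag on the pipeline could restrict to the strict labeled region, and the
choice matters little on phantoms because the dilation ring is thin.

## Label hygiene

`relabel_unsegmented` reassigns voxels carrying designated "unsegmented"
labels to the most frequent label among their 26-connected labeled
neighbors, with synchronous passes so labels propagate inward shell by
shell; ties break toward the lowest label id. Connectivity and tie rule
are fixed choices made for determinism — any consistent pair would do at
the voxel counts involved. A volume containing only unsegmented labels
(or an unsegmented region disconnected from all labels) is reported as
unresolvable.

## Registration

The clinical chain (PET→CT, CT→MRI, then PET↔PET-model fine-tuning) is
collapsed to the same-modality core: PET is registered to a PET model
built from the parcellation, first with the observed regional means as
model values, then (by default) one refinement pass in which the model is
rebuilt from the registered means and the registration re-estimated —
the first model's values are spill-biased, and the refinement removes
most of the resulting alignment bias.

The optimizer is a 3-level multi-resolution (downsample factors 4, 2, 1),
derivative-free Powell search. Costs: sum-of-squared differences
(default for the model-guided fine-tuning) and normalized mutual
information, `(H(A)+H(B))/H(A,B)` on 32-bin histograms. Rigid estimation
ends with a short cubic-spline-interpolation polish at full resolution:
trilinear resampling leaves a systematic ~0.5° bias at the SSD optimum
that the spline polish reduces to well under 0.1°, at modest cost (the
moving image is spline-prefiltered once per level). Translation bounds
default to ±40 mm for rigid and ±20 mm per axis for affine (the bounded
fine-tuning search; an optimum pinned at a bound triggers a warning);
rotations are bounded at ±30°. The affine bound is read in mm — the
plausible unit at brain scale — and is configurable.

Transforms are world-coordinate and push-forward (a +2 mm x-translation
moves content +2 mm); rotations act about the world origin, which
coincides with the volume center for package-generated grids.
Resampling supports nearest, linear, and cubic interpolation; recovery
experiments generate their known misregistrations with the cubic
resampler, since trilinear resampling smooths the moving image
anisotropically and would displace the true cost optimum by a few tenths
of a degree independent of the optimizer. Nonlinear
registration is never re-implemented: `nonlinear_adapter` delegates to a
named backend (identity and a SimpleITK demons wrapper are registered)
whose contract is a finite displacement field on the reference grid.

## GTM partial volume correction

`G_ij` is the mean over parcel i's voxels of parcel j's blurred
indicator (region-mean weighting, consistent with the mean-valued
observation vector). With the background included as an explicit parcel,
the indicators form a partition of unity, and each row of `G` sums to 1;
because the grid is finite, the background indicator is computed as the
complement of all real parcels' blurred indicators, i.e. the air is
treated as continuing beyond the grid. Background inclusion is the
default (rows then close to 1e-15; the recovered background activity on
phantoms is ~0) and can be disabled.

Inversion solves `min ‖G T − t‖²`:

- *unconstrained*: plain least squares; condition numbers above 1e8
  trigger an instability warning. On near-collinear systems this route
  reproduces the known failure mode — nonphysical negative parcel values.
- *constrained* (default): bounded least squares (`scipy.optimize
  .lsq_linear`, tolerance 1e-10) with lower bound 0; the upper bound
  defaults to +∞ with a hook, since only the lower bound is scientifically
  required. Initialization is the clipped unconstrained solution, and the
  result keeps whichever of the solver output and the clipped warm start
  has the smaller residual (a cheap guard against rare solver stalls).

The active-constraint set, residual norm, and condition number are
reported on the results object. Corrected values are normalized to the
brainstem (reference parcel flagged in the parcel table; cerebellum
selectable) to give SUVRs — normalization happens after PVC. Each
cortical parcel also gets its ratio to the paired subcortical WM parcel.

N is not fixed: clinical FreeSurfer parcellations give ~165 parcels,
phantoms use 15–25.

## Synthetic phantoms

The head phantom is concentric shells: outer CSF shell, a cortical ribbon
of configurable thickness split into `n` angular sectors, a WM shell
split into paired sectors, a deep-gray core, two ellipsoidal ventricles,
a brainstem cylinder, and a cerebellar blob; `ventricle_scale` drives the
negative-control family. The geometry is deliberately schematic: GTM
behavior depends on parcel adjacency and the ribbon-thickness-to-FWHM
ratio, which the shells reproduce, not on gyral anatomy. Defaults: 48³
voxels at 2 mm, 4 mm ribbon (two voxels), 8 sectors.

PET simulation paints per-parcel activities (defaults emulate an
amyloid-positive scan: cortex ≈ 1.4 with seeded ±0.25 spread, WM 0.9,
brainstem 0.85, CSF/ventricles 0.12), blurs with the PSF, and adds
independent additive Gaussian noise; a `scaled` option multiplies the
local SD by √signal for Poisson-like behavior. Noise magnitude is a free
parameter of the simulation (no clinical calibration is claimed); the
desk-scale default is 0.02 activity units.

What the phantoms do **not** capture: cortical folding (which makes real
GTMs worse-conditioned than shell GTMs), spatially varying or asymmetric
PSFs, scatter/randoms/attenuation artifacts, and inter-subject anatomical
variability. Passing recovery tests therefore demonstrates correctness of
the estimator chain, not clinical accuracy on real scans.

## Simulated cohorts

Per subject: a MoCA severity group (bins 0–10 / 11–19 / 20–30, default
proportions 11:31:33 as in a tertiary memory-clinic population), MoCA
uniform within its bin, age ~ N(74.5, 6.4), education ~ N(15.2, 3.5)
clipped at 0, sex Bernoulli(0.52) coded 0 = male / 1 = female. Parcel
thickness is `base + 0.008·(MoCA − 18) + ε_t`; parcel SUVR adds the
parcel-specific coupling `slope·(thickness − base)`, covariate terms
(age +0.008, education −0.03, sex −0.10, MoCA −0.035 per unit — signs
and magnitudes chosen to mimic a cohort in which low MoCA means thinner
cortex and higher amyloid), and noise ε_s. With independent ε the
population partial correlation of SUVR with thickness given the
covariates is `slope·sd(ε_t) / sqrt(slope²·sd(ε_t)² + sd(ε_s)²)`;
`coupling_slope_for_partial_r` inverts this so cohorts can be generated
at a stated effect size. Group proportions are realized exactly
(largest-remainder rounding) and shuffled; one global seed expands to
per-stage child generators via `SeedSequence.spawn` in a fixed order, so
every generator is bit-reproducible.

## Statistics

- Simple regression: OLS slope plus Pearson ρ, p from t with n−2 df.
- Multivariable model: OLS of SUVR on thickness, education, age, sex,
  MoCA with intercept; per-coefficient CIs (95% default, configurable)
  and p-values; the overall correlation is √R². Rank deficiency is
  detected before fitting and reported with the offending column.
- Partial correlation: residualize both variables on the covariates
  (with intercept), correlate residuals; p from t with n−2−k df, k = 4
  covariates by default. The df convention is stated explicitly because
  conventions differ; it matches pingouin's. If one variable is exactly
  a linear function of the covariates, r = 0 is returned by definition.
  Note a reference analysis of this kind maps a p-threshold of 0.037 at
  n = 75 to |r| = 0.23; the standard inversion implemented here
  (`r = t/√(t²+df)`, df = n−2−k) gives ≈ 0.25 — the package keeps the
  standard inversion rather than matching the rounder figure, whose df
  convention is unknown.
- BH-FDR: the step-up rule implemented directly (cross-checked against
  statsmodels in tests), reporting the realized p threshold alongside the
  rejection flags, since that threshold is itself a reported quantity in
  analyses of this kind.
- Group comparisons: two-sided independent t-test (continuous) and
  Fisher's exact test (binary categorical) between two named MoCA groups.
- Trajectory normalization: per parcel, group-mean SUVR is divided by the
  high-MoCA group's mean and group-mean thickness anchored to the
  high-MoCA mean, so the high-MoCA point maps to (1.0, 0.0); parcels are
  dichotomized as "thinner" when the middle-MoCA thickness is ≤ the
  high-MoCA thickness (ties count as thinner — a stated convention).

## Verification experiment sizes

The reproduction script and the acceptance-style tests run at sizes
chosen to exercise the estimators well inside a desk-scale compute
budget: GTM recovery on an 18-parcel 48³ phantom; registration recovery
with offsets up to 8 mm / 8°; a 50-phantom ventricle family at 32³; FDR
calibration with 200 repeats of n = 200 cohorts over 8 parcels; pipeline
ordering with 40 imaging subjects at 36³ and two-level affine search.
The detection-ordering experiment uses strong couplings (population
partial r = −0.6 in 6 of 8 parcels) so that the exact-registration
pipeline saturates and the ordering is driven by measurement degradation,
not sampling noise.

## Known limitations

- The constrained solution is exact for the phantom geometries tested;
  heavily overlapping real parcels can leave the bounded solver at a
  slightly suboptimal vertex (the warm-start guard mitigates this).
- The ventricle-control PVC correlation is a null quantity: across
  repeated families its magnitude fluctuates around zero, and individual
  seeds can land near the significance boundary.
- The registration module is built for smooth, same-modality images (PET
  vs modeled PET); it is not a general-purpose cross-modality registrar.
- MoCA group proportions below 1/n_subjects are rejected rather than
  silently dropped.
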