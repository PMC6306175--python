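# Methods

This note records the models, conventions and numerical choices behind
`fibersims`, and what the synthetic-data validation does and does not
demonstrate about real instrument data.

## Depth scaling and RSF calibration

Only the final sputter-crater depth D is measured (by profilometry), so
the depth axis assumes a uniform sputter rate: cycle i of n is assigned
the midpoint depth (i + 0.5)/n · D and the constant increment
Δz = D/n.  This is the standard SIMS convention for a single, chemically
uniform matrix; it is wrong near interfaces between materials with
different sputter yields, which do not occur within one HDPE fiber.

The relative sensitivity factor is defined so that the calibrated
implant profile integrates back to exactly the stated dose:

    RSF = φ / (Δz_cm · Σᵢ max(Iᵢ − B, 0))        [atoms/cm³ per count]

with B the mean count over a user-chosen range of trailing cycles past
the implant peak (a warning is logged if that range contains the
profile maximum).  Background subtraction truncates at zero so
concentrations are never negative.  Dose conservation therefore holds
by construction; the meaningful validation is that calibration on a
*generated* profile recovers the *generating* RSF, which it does to
<0.1% (the residual is the Gaussian tail mass outside the crater plus
midpoint-rule discretisation, both ≪10⁻³ for a peak 3σ inside the
crater).

The detection limit is RSF·(B + k·σ_B) with k = 3 by default (k = 0
gives the mean-only convention); k is exposed as `lod_k` because the
underlying instrument literature uses both conventions.  The RSFs of
³⁵Cl⁻ and ³⁷Cl⁻ are treated as identical.

## Stoichiometric conversion

Weight percent follows the dilute approximation (sample density equal
to the HDPE matrix density, 0.95 g/cm³) with permethrin C₂₁H₂₀Cl₂O₃
(391.29 g/mol, 2 Cl per molecule).  These defaults reproduce the
correspondence 1.5×10¹⁸ Cl atoms/cm³ ↔ 0.051 wt% permethrin; they are
constructor arguments (`MatrixModel`) for other analytes or matrices.
At percent-level loadings the dilute approximation biases wt% by well
under its own quoted precision.

## Surface summary statistics

Per-location ratios (analyte/reference intensity) are summarised with
the sample SD (n−1), the midpoint-rule median, RSD = 100·sd/mean, and a
*normal-approximation* 95% CI, mean ± 1.96·sd/√n.  The z interval (not
Student-t) is deliberate: it is the convention that exactly reproduces
the printed intervals of the measurement tables this mirrors
(e.g. 4.66 ± 1.96·2.22/√20 = 3.69–5.63; t would give 3.62–5.70).  With
n < 2 the spread statistics are reported as NaN, not zero.  Percent
change versus the initial condition is 100·(mean_c − mean_0)/mean_0.
No hypothesis tests are performed; the experimental design this serves
reports overlapping CIs only.

## Contribution analysis of ion cubes

For integer intensities x with voxel counts N_x, total Cl ∝ Σ N_x·x.
The contribution CDF (share of total intensity at levels ≤ x) is fitted
by the three-parameter log-logistic y = a/(1 + (x/x₀)^(−b)) with
unweighted least squares over x ≥ 1 (x = 0 carries no intensity and the
model is singular there).  Initialisation is deterministic — a = 1,
x₀ = the empirical contribution median, b = 2 — so fits are exactly
reproducible.  R² is computed on the fitted points.

Quantile solves use the closed form x_q = x₀·(1/q − 1)^(−1/b) after
normalising by the fitted asymptote a, so q is a true fraction of the
fitted total (a fits slightly above 1 on real-shaped data); the
unnormalised solve y(x) = q is available via `normalized=False` since
both conventions appear in practice and they differ by ~1% near the
median.  Threshold fractions ("share of Cl at x ≥ t") are always
computed from the empirical histogram, never the fit: the fitted tail
can disagree with the data by a factor of two at high thresholds, and
the empirical number is the physically meaningful one.

Mode and median tie-breaks go to the smallest qualifying level, for
determinism.

## Domain segmentation

High-intensity domains are connected components of voxels ≥ threshold
(default 50) under 26-connectivity (6-connectivity via config);
26-connectivity is the default because real domains are diffuse and
oriented, and face-only adjacency fragments them.  Physical metrics use
the anisotropic voxel geometry — lateral pitch `pixel_size_um`
(50/256 ≈ 0.195 µm for the reference scan), axial positions from
`level_depths_um` (1.89 µm/12 ≈ 0.158 µm spacing).  Orientation is the
leading principal axis of the domain's physical voxel coordinates
(sign fixed so the largest-magnitude component is positive); axis
lengths are full extents of voxel centres projected on the three
principal axes, so a single-voxel domain reports zero extent.

`min_voxels` discards components below a size cutoff.  Rationale: a
lognormal background with median 12 and mean 15.04 places ≈1.75% of
voxels at or above 50 purely by its upper tail.  These speckle voxels
are spatially independent, so at that density their clusters are
overwhelmingly of size 1–4 and essentially never reach 8 voxels,
whereas genuine domains span hundreds to thousands of voxels.  The
default is `min_voxels=1` (every suprathreshold voxel is assigned to a
domain, and domain voxel counts sum exactly to the suprathreshold
count); domain-abundance analyses use `min_voxels=8`, which separates
speckle from extended domains by a wide margin on both sides.  Without
speckle rejection the summed "domain" volume fraction of a 2%-planted
cube reads ≈3.7%; with it, 2.06%.

Surface connectivity flags a domain when any member voxel lies
shallower than a depth limit (default 0.5 µm); the flag depends only on
voxel depths, not labels.

## Synthetic-data generators: what they emulate

* **Implant profiles**: Gaussian concentration-depth profile of stated
  dose (default 5×10¹⁵ atoms/cm², peak 200 nm, σ 50 nm, crater 800 nm,
  80 cycles) converted to counts by a true RSF, plus constant
  background and optional Poisson noise.  Not emulated: channelling
  tails, sputter-rate transients, crater-edge effects.
* **Ion cubes**: background intensities i.i.d. from the lognormal whose
  *continuous* law has median 12 and mean 15.04 (µ = ln 12,
  σ² = 2·ln(15.04/12)), rounded and clipped to [0, 125].  The
  (median, mean) pair is used rather than the reported mode because the
  three reported statistics are mutually inconsistent with any exact
  lognormal; the resulting discretised mode is 8.  Domains are
  non-overlapping ellipsoids with uniformly drawn semi-axes (long
  in-plane axis 2–10 µm, i.e. extents up to ~3 µm × 20 µm), random
  in-plane orientation, and voxel intensities uniform on [50, 125],
  planted until the target volume fraction (default 2%) is reached;
  the final ellipsoid is rescaled to land on the target and placement
  failures beyond a retry budget raise.  Not emulated: spatial
  correlation of the background, diffuse domain boundaries, detector
  saturation.  Consequently, recovery tests demonstrate the
  correctness of the bookkeeping and segmentation, not robustness to
  correlated noise.
* **Wash series**: single-compartment first-order kinetics.  Washing
  multiplies the initial surface level (default 5.0) by
  1 − wash_efficiency (default 0.8); incubation relaxes towards a
  plateau (default 0.72 of initial, capped by the reservoir) at rate
  1/day, so day 4 sits within 2% of the plateau — matching the
  observation that regeneration essentially completes within 4 days.
  Per-location ratios scatter lognormally at 35% RSD (the mid-range of
  the 18–55% RSDs seen across real specimens), n = 20 locations per
  condition.  A diffusion-PDE blooming model is out of scope.
* **Surface maps**: smoothed white noise thresholded at the quantile
  giving the requested patch area fraction, with the suprathreshold
  excess scaled into intensity; smoothing is unnormalised so larger
  patch scales give weaker, more diffuse patches (lower map RSD),
  emulating the as-received vs regenerated contrast.

All generators are bit-reproducible given (spec, seed).

## Problem sizes and degenerate inputs

Full-size cube analyses (851,968 voxels, the reference scan geometry)
run in well under a second each, so the test suite and the
reproduction script use that size directly; brute-force oracle
comparisons use ≤ 8×8×4 cubes where exhaustive enumeration is cheap.
Degenerate inputs are defined rather than erroneous wherever a
convention exists: an empty suprathreshold set yields zero domains; a
single-cycle profile gets the midpoint depth D/2; an all-background
profile raises (no implant to calibrate); a zero-intensity cube has no
contribution CDF.

## Known limitations

* The RSF is treated as a single matrix-wide constant; per-substrate
  differences (Si vs HDPE vs pressed fiber) are not modelled.
* Quantification assumes all measured Cl derives from the analyte.
* The uniform-sputter-rate depth scale cannot capture rate changes
  within rough or curved fiber surfaces.
* imzML import sums each spectrum's intensity into one voxel; it does
  not do peak picking (assumed done upstream).
* Wash-series conditions are restricted to the controlled vocabulary
  (initial/washed/incubated 4 d/incubated 10 d and the
  pressing/sputtering states).
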