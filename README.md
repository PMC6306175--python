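# fibersims

Quantitative analysis of ToF-SIMS measurements of insecticide in
long-lasting insecticidal net (LLIN) fibers.

Incorporated LLINs (e.g. permethrin in HDPE monofilament) act as
monolithic sustained-release devices: insecticide dissolved in the
polymer blooms to the fiber surface, where it is bioavailable, and is
replenished from the interior after washing.  Time-of-flight secondary
ion mass spectrometry (ToF-SIMS) images the characteristic Cl⁻ ion of
permethrin at sub-micrometre resolution, laterally and in depth.  This
package turns such measurements — per-cycle depth profiles, per-location
spot intensities, and 3-D ion-image cubes — into quantitative results:

* **RSF calibration & LOD** (`fibersims.calibration`).  An
  ion-implanted standard of known areal dose φ (atoms/cm²) calibrates
  the relative sensitivity factor
  `RSF = φ / (Δz · Σᵢ max(Iᵢ − B, 0))` (atoms/cm³ per count), with the
  background level B estimated from trailing cycles and the per-cycle
  depth Δz from the profilometer-measured crater depth under a uniform
  sputter rate.  The detection limit is `RSF·(B + 3·σ_B)`.
* **Concentration profiles & unit conversion** (`fibersims.quantify`).
  Counts convert to Cl atomic density via the RSF, and to insecticide
  weight percent via the stoichiometry
  `wt% = 100·(C_Cl/n_Cl)·M/(N_A·ρ)` (defaults: permethrin C₂₁H₂₀Cl₂O₃,
  M = 391.29 g/mol, n_Cl = 2; HDPE ρ = 0.95 g/cm³), so a detection
  limit of 1.5×10¹⁸ Cl atoms/cm³ corresponds to 0.051 wt% permethrin.
* **Surface statistics** (`fibersims.surface`).  Per-location
  ³⁵Cl⁻/C₄H₃⁻ intensity ratios summarised per sample and condition
  (median, mean, sample SD, RSD, z-based 95% CI) and percent change of
  condition means versus the initial state for wash/regeneration
  experiments.
* **3-D distribution analysis** (`fibersims.voxel3d`).  For an
  intensity cube with levels x = 0…125 and counts N_x, the total Cl is
  ∝ Σ N_x·x; the normalised cumulative contribution (the share of Cl
  at intensity ≤ x) is fitted by the three-parameter log-logistic
  `y = a/(1 + (x/x₀)^(−b))`, whose quantiles solve in closed form as
  `x_q = x₀·(1/q − 1)^(−1/b)`.  High-intensity domains (x ≥ 50) are
  segmented as 26-connected components with per-domain volume and
  intensity fractions, centroid, principal-axis extents and
  orientation in physical micrometres, plus surface-connectivity
  flags.
* **Synthetic data** (`fibersims.synthetic`).  Generators for every
  input kind — Gaussian implant profiles of stated dose, cubes with
  discretised-lognormal backgrounds (median 12, mean 15.04) and planted
  oriented ellipsoidal domains, first-order blooming wash series, and
  patchy surface maps — so the whole pipeline is testable without
  instrument data and every analysis is validated by parameter
  recovery.

## Worked example

Generate a synthetic implant standard (dose 5×10¹⁵ atoms/cm², true RSF
2.2×10¹⁶, Poisson counting noise on a 30-count background) and
calibrate:

```sh
$ fibersims simulate implant --background 30 --poisson --seed 7 --out implant.csv
$ fibersims calibrate --profile implant.csv --crater-nm 800 --background-cycles 70:80
{
  "background_mean_counts": 31.3,
  "background_sd_counts": 9.092732140439297,
  "dose_atoms_cm2": 5000000000000000.0,
  "lod_atoms_cm3": 1.2889762603952576e+18,
  "lod_k": 3.0,
  "lod_wtpct": 0.044079754240090495,
  "rsf_atoms_cm3_per_count": 2.2004369187545876e+16,
  "species": "35Cl-"
}
```

The recovered RSF (2.200×10¹⁶ atoms/cm³ per count) matches the
generating value to 0.02%, and the 3σ detection limit of 1.29×10¹⁸
atoms/cm³ corresponds to 0.044 wt% permethrin.  Then generate and
analyse a fiber-like ion cube (256×256×13 voxels over
50 µm × 50 µm × 1.89 µm, 2% planted domain volume):

```sh
$ fibersims simulate cube --seed 1 --out cube.npz
$ fibersims cube-analyze --cube cube.npz --threshold 50 --min-voxels 8 --out cube_report
{
  ...
  "domain_volume_fraction": 0.020613450270432692,
  "logistic_r2": 0.9968583023494101,
  "logistic_x0": 20.654421687402643,
  "mean": 16.462854238656853,
  "median": 12,
  "n_domains": 13,
  ...
}
```

Segmentation recovers the planted 2% domain volume fraction (2.06%),
and the contribution CDF is well described by the log-logistic
(R² = 0.997 with domains present; ≥ 0.9998 for a pure lognormal
background).  `fibersims convert --cl-density 1.5e18` prints
`0.0512962 wt%`.  `fibersims run --config run.yaml` chains all stages
and writes CSV/JSON reports with a checksum manifest; see
`fibersims run --help`.

## File formats

Depth profiles and spot tables are comma- or tab-delimited text with a
mandatory header (decimal point only).  Ion cubes use a single-file
NumPy `.npz` container with three entries: `intensities` (integer
rows × cols × levels raster), `level_depths_um` (per-level depths,
strictly increasing) and `meta` (JSON block with `format_version`,
`pixel_size_um`, `species_label`).  `fibersims.io.read_imzml_cube`
imports 3-D imzML exports.

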