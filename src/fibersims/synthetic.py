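"""Synthetic instrument-data generators.

Every analysis stage in this package can be exercised without access to
a ToF-SIMS instrument by generating inputs with the statistical
structure the analysis assumes:

* :func:`gen_implant_profile` — a Gaussian implant depth profile of
  known dose on a constant count background, optionally with Poisson
  counting noise.  With zero noise, RSF calibration on the output
  recovers the generating RSF up to discretisation.
* :func:`gen_cube` — a 3-D ion-image cube whose background intensities
  follow a discretised lognormal (parameterised by the median and mean
  of the continuous law) with a small volume fraction of oriented
  high-intensity ellipsoidal domains planted in it.
* :func:`gen_wash_series` — per-location spot tables for a
  wash/regeneration experiment under single-compartment first-order
  blooming kinetics: washing removes a fraction of the surface deposit,
  then insecticide migrates back from the subsurface reservoir towards
  a plateau, essentially completing within a few days.
* :func:`gen_surface_map` — a single-level patchy surface deposit map
  (thresholded smoothed random field).

All generators are bit-reproducible given their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtri

from .io import DepthProfile, IonCube, SpotTable

__all__ = [
    "CubeSpec",
    "BloomSpec",
    "PlantedDomain",
    "gen_implant_profile",
    "gen_cube",
    "gen_wash_series",
    "gen_surface_map",
    "lognormal_params_from_median_mean",
]

NM_PER_CM = 1e7


def lognormal_params_from_median_mean(median: float, mean: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given median and mean.

    ``mu = ln(median)``, ``sigma^2 = 2 ln(mean/median)``; requires
    ``mean > median > 0``.
    """
    if not (median > 0 and mean > median):
        raise ValueError("need mean > median > 0 for a lognormal")
    mu = math.log(median)
    sigma = math.sqrt(2.0 * math.log(mean / median))
    return mu, sigma


# ---------------------------------------------------------------------------
# implant profiles


def gen_implant_profile(
    dose: float = 5e15,
    peak_depth_nm: float = 200.0,
    sigma_nm: float = 50.0,
    n_cycles: int = 80,
    crater_nm: float = 800.0,
    background: float = 0.0,
    rsf_true: float = 2.2e16,
    poisson_noise: bool = False,
    seed: int | None = None,
    species_label: str = "35Cl-",
) -> DepthProfile:
    """Synthesise a Gaussian implant depth profile of known dose.

    The expected count at cycle depth ``z`` is the implant concentration
    ``dose * N(z; peak, sigma)`` (atoms/cm^3, with the Gaussian density
    per cm) divided by ``rsf_true``, plus the constant background.  With
    ``poisson_noise`` each cycle's count is a Poisson draw around its
    expectation.

    The peak must lie well inside the crater (``peak + 3 sigma`` and
    ``peak - 3 sigma`` within ``(0, crater)``) so the dose is contained
    in the profiled range.
    """
    if peak_depth_nm + 3.0 * sigma_nm >= crater_nm or peak_depth_nm - 3.0 * sigma_nm <= 0:
        raise ValueError("implant peak +/- 3 sigma must lie inside the crater")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    z = (np.arange(n_cycles) + 0.5) / n_cycles * crater_nm
    # Gaussian areal-density profile; density per cm so conc is atoms/cm^3
    pdf_per_cm = (
        np.exp(-0.5 * ((z - peak_depth_nm) / sigma_nm) ** 2)
        / (sigma_nm / NM_PER_CM * math.sqrt(2.0 * math.pi))
    )
    conc = dose * pdf_per_cm
    expected = conc / rsf_true + background
    if poisson_noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DepthProfile(
        species_label=species_label,
        counts=counts,
        crater_depth_nm=crater_nm,
        sputter_params=f"synthetic implant, dose {dose:g} atoms/cm^2",
    )


# ---------------------------------------------------------------------------
# ion cubes


@dataclass(frozen=True)
class PlantedDomain:
    """Ground truth for one planted ellipsoidal domain."""

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    orientation: tuple[float, float, float]
    voxel_count: int


@dataclass(frozen=True)
class CubeSpec:
    """Parameters of a synthetic ion-image cube.

    Defaults emulate a 256 x 256 scan over 50 um x 50 um at 13 sputter
    levels to 1.89 um depth, background intensities from the discretised
    lognormal with continuous median 12 and mean 15.04 clipped to
    [0, 125], and oriented high-intensity ellipsoidal domains occupying
    2% of the voxels.  Domain semi-axes are drawn uniformly from
    ``domain_semi_axis_ranges_um`` (long in-plane axis up to 10 um, i.e.
    full extents up to ~3 um x 20 um) with a random in-plane
    orientation, and domain voxels are assigned integer intensities
    uniform on ``domain_intensity_range``.
    """

    shape: tuple[int, int, int] = (256, 256, 13)
    pixel_size_um: float = 50.0 / 256.0
    level_spacing_um: float = 1.89 / 12.0
    background_median: float = 12.0
    background_mean: float = 15.04
    x_max: int = 125
    target_domain_volume_fraction: float = 0.02
    domain_semi_axis_ranges_um: tuple[tuple[float, float], ...] = (
        (2.0, 10.0),
        (0.4, 1.5),
        (0.15, 0.45),
    )
    domain_intensity_range: tuple[int, int] = (50, 125)
    max_placement_failures: int = 500

    def __post_init__(self) -> None:
        if min(self.shape) < 1:
            raise ValueError("shape must be positive")
        if not 0.0 <= self.target_domain_volume_fraction <= 0.5:
            raise ValueError("domain volume fraction must be in [0, 0.5]")
        if self.pixel_size_um <= 0 or self.level_spacing_um <= 0:
            raise ValueError("voxel dimensions must be positive")
        for lo, hi in self.domain_semi_axis_ranges_um:
            if not 0 < lo <= hi:
                raise ValueError("semi-axis ranges must be positive")

    @property
    def level_depths_um(self) -> np.ndarray:
        return np.arange(self.shape[2]) * self.level_spacing_um


def _rasterize_ellipsoid(
    spec: CubeSpec,
    center: np.ndarray,
    semi_axes: np.ndarray,
    theta: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices inside an in-plane-rotated ellipsoid (physical units)."""
    rows, cols, levels = spec.shape
    pix = spec.pixel_size_um
    depths = spec.level_depths_um
    # principal directions: long axis in-plane at angle theta, short in-plane, axial
    u = np.array([math.cos(theta), math.sin(theta), 0.0])
    v = np.array([-math.sin(theta), math.cos(theta), 0.0])
    w = np.array([0.0, 0.0, 1.0])
    reach = math.hypot(semi_axes[0], semi_axes[1])
    c0 = max(int((center[0] - reach) / pix) - 1, 0)
    c1 = min(int((center[0] + reach) / pix) + 2, cols)
    r0 = max(int((center[1] - reach) / pix) - 1, 0)
    r1 = min(int((center[1] + reach) / pix) + 2, rows)
    k_mask = np.abs(depths - center[2]) <= semi_axes[2]
    ks = np.flatnonzero(k_mask)
    if c0 >= c1 or r0 >= r1 or ks.size == 0:
        return (np.array([], int),) * 3
    rr, cc, kk = np.meshgrid(
        np.arange(r0, r1), np.arange(c0, c1), ks, indexing="ij"
    )
    x = (cc + 0.5) * pix - center[0]
    y = (rr + 0.5) * pix - center[1]
    z = depths[kk] - center[2]
    d = np.stack([x, y, z], axis=-1)
    q = (
        (d @ u) ** 2 / semi_axes[0] ** 2
        + (d @ v) ** 2 / semi_axes[1] ** 2
        + (d @ w) ** 2 / semi_axes[2] ** 2
    )
    inside = q <= 1.0
    return rr[inside], cc[inside], kk[inside]


def gen_cube(
    spec: CubeSpec = CubeSpec(),
    seed: int | None = None,
    return_truth: bool = False,
):
    """Generate a synthetic ion cube (optionally with planted-domain truth).

    Background voxels are drawn from the lognormal whose *continuous*
    law has the spec's median and mean, rounded to integers and clipped
    to ``[0, x_max]``.  Ellipsoidal domains with random sizes and
    in-plane orientations are then planted without overlap until the
    target volume fraction is reached (the last ellipsoid is rescaled to
    land close to the target); their voxels are assigned intensities
    uniform on ``domain_intensity_range``.  Raises if the requested
    fraction cannot be placed without overlap within the retry budget.
    """
    rng = np.random.default_rng(seed)
    rows, cols, levels = spec.shape
    mu, sigma = lognormal_params_from_median_mean(
        spec.background_median, spec.background_mean
    )
    values = rng.lognormal(mean=mu, sigma=sigma, size=spec.shape)
    arr = np.clip(np.rint(values), 0, spec.x_max).astype(np.int64)

    truth: list[PlantedDomain] = []
    total = arr.size
    target_vox = int(round(spec.target_domain_volume_fraction * total))
    if target_vox > 0:
        planted = np.zeros(spec.shape, dtype=bool)
        planted_count = 0
        failures = 0
        vox_vol = spec.pixel_size_um**2 * spec.level_spacing_um
        depth_span = spec.level_depths_um[-1] if levels > 1 else spec.level_spacing_um
        # stop once the remainder is smaller than a resolvable ellipsoid
        min_remainder = max(int(0.002 * target_vox), 8)
        while target_vox - planted_count >= min_remainder:
            semi = np.array(
                [rng.uniform(lo, hi) for lo, hi in spec.domain_semi_axis_ranges_um]
            )
            est_vox = 4.0 / 3.0 * math.pi * semi.prod() / vox_vol
            remaining = target_vox - planted_count
            if est_vox > remaining:
                semi = semi * (remaining / est_vox) ** (1.0 / 3.0)
            theta = rng.uniform(0.0, math.pi)
            reach = math.hypot(semi[0], semi[1])
            margin_xy = min(reach, 0.45 * cols * spec.pixel_size_um)
            cx = rng.uniform(margin_xy, cols * spec.pixel_size_um - margin_xy)
            cy = rng.uniform(margin_xy, rows * spec.pixel_size_um - margin_xy)
            z_lo = min(semi[2], 0.45 * depth_span)
            cz = rng.uniform(z_lo, depth_span - z_lo)
            rr, cc, kk = _rasterize_ellipsoid(spec, np.array([cx, cy, cz]), semi, theta)
            if rr.size == 0 or planted[rr, cc, kk].any():
                failures += 1
                if failures > spec.max_placement_failures:
                    raise ValueError(
                        "could not place requested domain volume fraction "
                        f"{spec.target_domain_volume_fraction} without overlap"
                    )
                continue
            planted[rr, cc, kk] = True
            planted_count += rr.size
            orient = (math.cos(theta), math.sin(theta), 0.0)
            truth.append(
                PlantedDomain(
                    center_um=(cx, cy, cz),
                    semi_axes_um=tuple(float(s) for s in semi),
                    orientation=orient,
                    voxel_count=int(rr.size),
                )
            )
        lo, hi = spec.domain_intensity_range
        arr[planted] = rng.integers(lo, hi + 1, size=planted_count)

    cube = IonCube(
        intensities=arr,
        pixel_size_um=spec.pixel_size_um,
        level_depths_um=spec.level_depths_um,
    )
    if return_truth:
        return cube, tuple(truth)
    return cube


# ---------------------------------------------------------------------------
# wash / regeneration series


@dataclass(frozen=True)
class BloomSpec:
    """Parameters of the first-order blooming (regeneration) simulator.

    Washing reduces the initial surface level by ``wash_efficiency``;
    during incubation the surface level relaxes towards a plateau
    (``plateau_fraction_of_initial`` of the initial level, capped by the
    subsurface reservoir) with rate ``transfer_rate_per_day``.  The
    default rate of 1/day puts the surface within 2% of its plateau by
    day 4, matching the observation that regeneration is essentially
    complete within 4 days.  Per-location ratios scatter lognormally at
    ``noise_rsd_pct`` around the condition mean, emulating the patchy
    deposits behind the 18-55% relative SDs seen on real fibers.
    """

    initial_surface_amount: float = 5.0
    subsurface_reservoir: float = 40.0
    transfer_rate_per_day: float = 1.0
    plateau_fraction_of_initial: float = 0.72
    wash_efficiency: float = 0.8
    noise_rsd_pct: float = 35.0
    n_locations: int = 20
    incubation_days: tuple[float, ...] = (4.0, 10.0)
    reference_level: float = 100.0
    reference_rsd_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.transfer_rate_per_day < 0 or self.initial_surface_amount < 0:
            raise ValueError("rates and amounts must be non-negative")
        for frac in (self.plateau_fraction_of_initial, self.wash_efficiency):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")

    def condition_means(self) -> dict[str, float]:
        """Closed-form condition means of the recovery model."""
        initial = self.initial_surface_amount
        washed = initial * (1.0 - self.wash_efficiency)
        plateau = min(
            self.plateau_fraction_of_initial * initial, self.subsurface_reservoir
        )
        means = {"initial": initial, "washed": washed}
        for t in self.incubation_days:
            level = washed + (plateau - washed) * (
                1.0 - math.exp(-self.transfer_rate_per_day * t)
            )
            means[f"incubated_{t:g}d"] = level
        return means


def _lognormal_noise(rng: np.random.Generator, rsd_pct: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given relative SD (%)."""
    cv = rsd_pct / 100.0
    if cv <= 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


def gen_wash_series(
    spec: BloomSpec = BloomSpec(),
    sample_ids: tuple[str, ...] = ("A",),
    seed: int | None = None,
) -> SpotTable:
    """Generate a spot table for a wash/regeneration experiment.

    One block of ``n_locations`` records per (sample, condition); the
    analyte intensity is the condition mean times the reference
    intensity times unit-mean lognormal noise, so the per-location
    ratios are the condition mean perturbed at ``noise_rsd_pct``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in sample_ids:
        for condition, mean_level in spec.condition_means().items():
            n = spec.n_locations
            ref = spec.reference_level * _lognormal_noise(rng, spec.reference_rsd_pct, n)
            ratio = mean_level * _lognormal_noise(rng, spec.noise_rsd_pct, n)
            for loc in range(n):
                rows.append(
                    {
                        "sample_id": sample,
                        "condition": condition,
                        "location_id": loc + 1,
                        "analyte_intensity": ratio[loc] * ref[loc],
                        "reference_intensity": ref[loc],
                    }
                )
    return SpotTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# surface maps


def gen_surface_map(
    shape: tuple[int, int] = (256, 256),
    patch_density: float = 0.1,
    patch_scale: float = 4.0,
    seed: int | None = None,
    pixel_size_um: float = 50.0 / 256.0,
    base_intensity: int = 5,
    gain: float = 400.0,
) -> IonCube:
    """Generate a single-level patchy surface-deposit map.

    A white-noise field is smoothed with a Gaussian kernel of width
    ``patch_scale`` (pixels) and thresholded at the quantile leaving an
    expected area fraction ``patch_density`` above threshold; the excess
    above threshold is scaled by ``gain`` and added to a uniform base.
    Because smoothing is not renormalised, larger ``patch_scale`` gives
    weaker, smoother patches and hence a lower map RSD at equal density.
    """
    if patch_density < 0 or patch_density >= 1 or patch_scale <= 0:
        raise ValueError("need 0 <= patch_density < 1 and patch_scale > 0")
    rng = np.random.default_rng(seed)
    arr = np.full(shape, base_intensity, dtype=float)
    if patch_density > 0:
        field = ndimage.gaussian_filter(rng.standard_normal(shape), patch_scale)
        z = ndtri(1.0 - patch_density) * field.std()
        arr += gain * np.clip(field - z, 0.0, None)
    intensities = np.clip(np.rint(arr), 0, 125).astype(np.int64)[:, :, None]
    return IonCube(
        intensities=intensities,
        pixel_size_um=pixel_size_um,
        level_depths_um=np.array([0.0]),
        species_label="35Cl-",
    )
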