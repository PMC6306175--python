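"""3-D chlorine-distribution analysis of ion-image cubes.

A depth-resolved ion image (rows x cols x sputter levels of integer
35Cl- intensities) is summarised in three stages:

1. **Histogram / distribution statistics** — level counts ``N_x`` for
   every intensity ``x``, plus mode, median and mean.  The total Cl
   content of the imaged volume is proportional to the total intensity
   ``I_total = sum_x N_x * x``.
2. **Contribution analysis** — the product ``N_x * x`` is the share of
   total signal carried by voxels at intensity ``x`` (a size-biased
   weighting of the intensity distribution).  Its normalised cumulative
   sum, the contribution CDF, is well described by a three-parameter
   log-logistic curve ``y = a / (1 + (x/x0)^(-b))``, from which
   intensity quantiles of the Cl load can be solved in closed form.
   Threshold fractions ("what share of the Cl sits at intensity >= t")
   are always computed from the empirical histogram; the fitted curve
   is a separate, smooth summary.
3. **Domain segmentation** — connected components (26-connectivity by
   default) of voxels at or above an intensity threshold, interpreted
   as insecticide-rich domains.  Per-domain size, volume and intensity
   fractions, physical centroid, principal-axis extents and orientation
   are computed in micrometres using the anisotropic voxel geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .io import IonCube

__all__ = [
    "IntensityHistogram",
    "DistributionStats",
    "ContributionCDF",
    "LogisticFit",
    "DomainRecord",
    "DomainSegmentation",
    "SurfaceConnectivity",
    "histogram",
    "distribution_stats",
    "contribution_cdf",
    "fit_logistic",
    "solve_quantile",
    "fraction_above",
    "segment_domains",
    "surface_connectivity",
]


@dataclass(frozen=True)
class IntensityHistogram:
    """Exact voxel counts ``N_x`` per integer intensity level ``x``.

    ``counts[x]`` covers every level from 0 to ``x_max`` inclusive;
    ``total_intensity = sum_x counts[x] * x`` is proportional to the
    total Cl content of the imaged volume.
    """

    counts: np.ndarray
    total_voxels: int
    total_intensity: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1 or counts.min() < 0:
            raise ValueError("counts must be a 1-D non-negative array")
        if int(counts.sum()) != self.total_voxels:
            raise ValueError("sum of counts must equal total_voxels")
        if int(np.sum(counts * np.arange(counts.size))) != self.total_intensity:
            raise ValueError("total_intensity inconsistent with counts")
        counts.flags.writeable = False
        object.__setattr__(self, "counts", counts)

    @property
    def x_max(self) -> int:
        return int(self.counts.size - 1)

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.counts.size)


@dataclass(frozen=True)
class DistributionStats:
    mode: int
    median: int
    mean: float


@dataclass(frozen=True)
class ContributionCDF:
    """Normalised cumulative contribution ``sum_{x'<=x} N_x' x' / I_total``."""

    x: np.ndarray
    cumulative_fraction: np.ndarray


@dataclass(frozen=True)
class LogisticFit:
    """Three-parameter log-logistic fit ``y = a / (1 + (x/x0)^(-b))``."""

    a: float
    x0: float
    b: float
    r2: float

    def __post_init__(self) -> None:
        if not (self.x0 > 0 and self.b > 0):
            raise ValueError("x0 and b must be positive")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must be in [0, 1]")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.a / (1.0 + (x / self.x0) ** (-self.b))


def histogram(cube: IonCube) -> IntensityHistogram:
    """Exact intensity histogram of a cube."""
    flat = cube.intensities.ravel()
    counts = np.bincount(flat)
    return IntensityHistogram(
        counts=counts,
        total_voxels=int(flat.size),
        total_intensity=int(flat.sum()),
    )


def distribution_stats(h: IntensityHistogram) -> DistributionStats:
    """Mode, median and mean intensity (smallest level wins ties).

    The median is the smallest level whose cumulative voxel count
    reaches half the total.
    """
    if h.total_voxels < 1:
        raise ValueError("histogram is empty")
    mode = int(np.argmax(h.counts))
    cum = np.cumsum(h.counts)
    median = int(np.searchsorted(cum, h.total_voxels / 2.0))
    mean = h.total_intensity / h.total_voxels
    return DistributionStats(mode=mode, median=median, mean=mean)


def contribution_cdf(h: IntensityHistogram) -> ContributionCDF:
    """Cumulative fraction of total intensity carried by levels <= x.

    Non-decreasing, and exactly 1 at ``x_max``.
    """
    if h.total_intensity <= 0:
        raise ValueError("total intensity is zero; contribution CDF undefined")
    contrib = h.counts * h.levels
    cum = np.cumsum(contrib, dtype=np.int64)
    return ContributionCDF(
        x=h.levels.copy(),
        cumulative_fraction=cum / h.total_intensity,
    )


def _logistic(x, a, x0, b):
    return a / (1.0 + (x / x0) ** (-b))


def fit_logistic(cdf: ContributionCDF, maxfev: int = 20000) -> LogisticFit:
    """Least-squares three-parameter log-logistic fit of a contribution CDF.

    Only points with ``x >= 1`` enter the fit (zero-intensity voxels
    carry no signal and the model is singular at x = 0).  Initialisation
    is deterministic: ``a = 1``, ``x0`` = the empirical contribution
    median, ``b = 2``; the fit is unweighted.  ``r2`` is computed on the
    fitted points.
    """
    mask = cdf.x >= 1
    x = np.asarray(cdf.x, dtype=float)[mask]
    y = np.asarray(cdf.cumulative_fraction, dtype=float)[mask]
    if x.size < 4:
        raise ValueError("need at least 4 points with x >= 1 to fit")
    x0_init = float(x[np.searchsorted(y, 0.5)]) if y[-1] >= 0.5 else float(x[-1])
    x0_init = max(x0_init, 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _logistic,
            x,
            y,
            p0=(1.0, x0_init, 2.0),
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=maxfev,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"logistic fit did not converge: {exc}") from exc
    resid = y - _logistic(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return LogisticFit(a=float(popt[0]), x0=float(popt[1]), b=float(popt[2]), r2=min(max(r2, 0.0), 1.0))


def solve_quantile(fit: LogisticFit, q: float, normalized: bool = True) -> float:
    """Intensity below which a fraction ``q`` of the Cl load resides.

    Solves the fitted curve in closed form.  With ``normalized=True``
    (default) the curve is first normalised by its asymptote ``a`` so
    ``q`` is a true fraction of the fitted total:
    ``x = x0 * (1/q - 1)^(-1/b)``.  With ``normalized=False`` the raw
    curve ``y(x) = q`` is solved instead:
    ``x = x0 * (a/q - 1)^(-1/b)`` (requires ``q < a``).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if normalized:
        ratio = 1.0 / q - 1.0
    else:
        if q >= fit.a:
            raise ValueError(f"q={q} is not below the fitted asymptote a={fit.a}")
        ratio = fit.a / q - 1.0
    return fit.x0 * ratio ** (-1.0 / fit.b)


def fraction_above(h: IntensityHistogram, threshold: float) -> float:
    """Empirical fraction of total intensity at levels >= ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if h.total_intensity <= 0:
        raise ValueError("total intensity is zero")
    mask = h.levels >= threshold
    return float(np.sum(h.counts[mask] * h.levels[mask]) / h.total_intensity)


# ---------------------------------------------------------------------------
# domain segmentation


@dataclass(frozen=True)
class DomainRecord:
    """Metrics of one connected high-intensity domain (physical units)."""

    label: int
    voxel_count: int
    volume_fraction: float
    intensity_fraction: float
    centroid_um: tuple[float, float, float]
    axis_lengths_um: tuple[float, float, float]
    orientation: tuple[float, float, float]
    min_depth_um: float


@dataclass(frozen=True)
class DomainSegmentation:
    """Connected components of voxels at or above an intensity threshold."""

    label_volume: np.ndarray
    threshold: float
    connectivity: int
    min_voxels: int
    domains: tuple[DomainRecord, ...]
    total_voxels: int
    pixel_size_um: float
    level_depths_um: np.ndarray

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def total_volume_fraction(self) -> float:
        return float(sum(d.volume_fraction for d in self.domains))

    @property
    def total_intensity_fraction(self) -> float:
        return float(sum(d.intensity_fraction for d in self.domains))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.domains:
            rows.append(
                {
                    "label": d.label,
                    "voxel_count": d.voxel_count,
                    "volume_fraction": d.volume_fraction,
                    "intensity_fraction": d.intensity_fraction,
                    "centroid_x_um": d.centroid_um[0],
                    "centroid_y_um": d.centroid_um[1],
                    "centroid_z_um": d.centroid_um[2],
                    "axis1_um": d.axis_lengths_um[0],
                    "axis2_um": d.axis_lengths_um[1],
                    "axis3_um": d.axis_lengths_um[2],
                    "orient_x": d.orientation[0],
                    "orient_y": d.orientation[1],
                    "orient_z": d.orientation[2],
                    "min_depth_um": d.min_depth_um,
                }
            )
        return pd.DataFrame(rows)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def segment_domains(
    cube: IonCube,
    threshold: float,
    connectivity: int = 26,
    min_voxels: int = 1,
) -> DomainSegmentation:
    """Segment connected high-intensity domains of a cube.

    Voxels with intensity >= ``threshold`` are grouped into connected
    components (index-space 26- or 6-connectivity).  Components smaller
    than ``min_voxels`` are discarded as speckle — isolated
    suprathreshold voxels expected from the upper tail of the background
    intensity distribution rather than from extended insecticide-rich
    domains; the default ``min_voxels=1`` keeps every component, so the
    summed domain voxel count equals the suprathreshold voxel count.

    All physical metrics use the anisotropic voxel geometry: lateral
    coordinates are voxel centres at ``pixel_size_um`` pitch, axial
    coordinates are the per-level depths.  Orientation is the principal
    axis (largest-variance direction) of each domain's physical voxel
    coordinates; axis lengths are the full extents of the voxel centres
    projected on the three principal axes.
    """
    mask = cube.intensities >= threshold
    labels, n_raw = ndimage.label(mask, structure=_structure(connectivity))
    total_voxels = cube.n_voxels
    total_intensity = float(cube.intensities.sum())

    if n_raw == 0:
        return DomainSegmentation(
            label_volume=labels,
            threshold=threshold,
            connectivity=connectivity,
            min_voxels=min_voxels,
            domains=(),
            total_voxels=total_voxels,
            pixel_size_um=cube.pixel_size_um,
            level_depths_um=cube.level_depths_um,
        )

    sizes = np.bincount(labels.ravel(), minlength=n_raw + 1)
    keep = np.flatnonzero(sizes >= max(min_voxels, 1))
    keep = keep[keep != 0]
    # relabel kept components as 1..K in original label order
    remap = np.zeros(n_raw + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[labels]

    # group flat voxel indices by label without a per-label full scan
    flat_labels = labels.ravel()
    nz = np.flatnonzero(flat_labels)
    order = nz[np.argsort(flat_labels[nz], kind="stable")]
    group_sizes = np.bincount(flat_labels[nz], minlength=keep.size + 1)[1:]
    boundaries = np.concatenate([[0], np.cumsum(group_sizes)])

    rows, cols, levels = np.unravel_index(order, cube.shape)
    xs = (cols + 0.5) * cube.pixel_size_um
    ys = (rows + 0.5) * cube.pixel_size_um
    zs = cube.level_depths_um[levels]
    values = cube.intensities.ravel()[order].astype(float)

    records = []
    for k in range(keep.size):
        lo, hi = boundaries[k], boundaries[k + 1]
        coords = np.column_stack([xs[lo:hi], ys[lo:hi], zs[lo:hi]])
        count = hi - lo
        centroid = coords.mean(axis=0)
        if count > 1:
            cov = np.cov(coords.T)
            eigval, eigvec = np.linalg.eigh(cov)
            orderax = np.argsort(eigval)[::-1]
            axes = eigvec[:, orderax]
        else:
            axes = np.eye(3)
        proj = (coords - centroid) @ axes
        extents = proj.max(axis=0) - proj.min(axis=0)
        orient = axes[:, 0]
        pivot = int(np.argmax(np.abs(orient)))
        if orient[pivot] < 0:
            orient = -orient
        records.append(
            DomainRecord(
                label=k + 1,
                voxel_count=int(count),
                volume_fraction=count / total_voxels,
                intensity_fraction=float(values[lo:hi].sum() / total_intensity)
                if total_intensity > 0
                else 0.0,
                centroid_um=tuple(float(v) for v in centroid),
                axis_lengths_um=tuple(float(v) for v in extents),
                orientation=tuple(float(v) for v in orient),
                min_depth_um=float(zs[lo:hi].min()),
            )
        )

    return DomainSegmentation(
        label_volume=labels,
        threshold=threshold,
        connectivity=connectivity,
        min_voxels=min_voxels,
        domains=tuple(records),
        total_voxels=total_voxels,
        pixel_size_um=cube.pixel_size_um,
        level_depths_um=cube.level_depths_um,
    )


@dataclass(frozen=True)
class SurfaceConnectivity:
    """Which domains reach within ``depth_limit_um`` of the surface."""

    depth_limit_um: float
    surface_touching: dict[int, bool]
    n_surface_touching: int


def surface_connectivity(seg: DomainSegmentation, depth_limit_um: float) -> SurfaceConnectivity:
    """Flag domains with any voxel shallower than ``depth_limit_um``.

    The flags depend only on voxel membership, not on domain labels.
    """
    flags = {d.label: bool(d.min_depth_um < depth_limit_um) for d in seg.domains}
    return SurfaceConnectivity(
        depth_limit_um=depth_limit_um,
        surface_touching=flags,
        n_surface_touching=int(sum(flags.values())),
    )
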