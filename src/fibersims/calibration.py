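"""Implant-standard RSF calibration and depth-profile quantification.

Quantification of secondary-ion counts follows the ion-implantation
calibration scheme standard in SIMS: a sample of the same matrix is
implanted with a known areal dose ``phi`` (atoms/cm^2) of the analyte
ion, the implant is depth-profiled, and the relative sensitivity factor

    RSF = phi / (dz_cm * sum_i max(I_i - B, 0))        [atoms/cm^3 per count]

converts counts to atomic density, where ``I_i`` are the per-cycle
counts, ``B`` the background count level estimated from trailing cycles
past the implant peak, and ``dz_cm`` the per-cycle depth increment in
cm.  By construction the calibrated implant profile integrates back to
exactly the stated dose.

The depth axis assumes a uniform sputter rate: only the final crater
depth is measured (profilometry), so cycle ``i`` of ``n`` is assigned
the midpoint depth ``(i + 0.5)/n * crater_depth``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DepthProfile

__all__ = [
    "RSFCalibration",
    "ConcentrationProfile",
    "depth_scale",
    "compute_rsf",
    "quantify_profile",
]

logger = logging.getLogger(__name__)

NM_PER_CM = 1e7


@dataclass(frozen=True)
class RSFCalibration:
    """Result of an implant-standard calibration for one species/matrix.

    ``rsf`` is in atoms/cm^3 per count; ``lod_density`` is the smallest
    atomic density distinguishable from background, computed as
    ``rsf * (background_mean + lod_k * background_sd)``.
    """

    dose: float
    rsf: float
    background_mean: float
    background_sd: float
    lod_density: float
    species_label: str = "35Cl-"
    matrix_label: str = "HDPE"

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError("dose must be positive")
        if not self.rsf > 0:
            raise ValueError("rsf must be positive")
        if self.lod_density < 0:
            raise ValueError("lod_density must be non-negative")
        if self.background_mean > 0 and self.lod_density < self.rsf * self.background_mean:
            raise ValueError("lod_density below rsf * background_mean")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration versus depth for one species.

    ``depths_nm`` are cycle-midpoint depths (strictly increasing);
    ``concentrations`` are atomic densities in atoms/cm^3.
    """

    depths_nm: np.ndarray
    concentrations: np.ndarray
    species_label: str

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths_nm, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if depths.shape != conc.shape or depths.ndim != 1:
            raise ValueError("depths and concentrations must be matching 1-D arrays")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if depths.size > 1 and not np.all(np.diff(depths) > 0):
            raise ValueError("depths must be strictly increasing")
        object.__setattr__(self, "depths_nm", depths)
        object.__setattr__(self, "concentrations", conc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth_nm": self.depths_nm, "concentration_atoms_cm3": self.concentrations}
        )


def depth_scale(profile: DepthProfile) -> np.ndarray:
    """Midpoint depth (nm) of each sputter cycle under a uniform rate.

    Cycle ``i`` (0-based) of ``n`` is assigned ``(i + 0.5)/n * D`` where
    ``D`` is the measured crater depth; increments are the constant
    ``D/n`` and the cycle intervals exactly tile ``(0, D)``.
    """
    n = profile.n_cycles
    return (np.arange(n) + 0.5) / n * profile.crater_depth_nm


def _background_slice(background_cycles: tuple[int, int] | slice | str) -> slice:
    if isinstance(background_cycles, slice):
        return background_cycles
    if isinstance(background_cycles, str):
        a, _, b = background_cycles.partition(":")
        return slice(int(a) if a else None, int(b) if b else None)
    a, b = background_cycles
    return slice(a, b)


def compute_rsf(
    implant_profile: DepthProfile,
    dose: float,
    background_cycles: tuple[int, int] | slice | str,
    lod_k: float = 3.0,
    matrix_label: str = "HDPE",
) -> RSFCalibration:
    """Calibrate the RSF and detection limit from an implant profile.

    Parameters
    ----------
    implant_profile :
        Depth profile of the implanted standard; the implant peak must be
        fully contained in the profiled depth range.
    dose :
        Implanted areal density in atoms/cm^2.
    background_cycles :
        Index range (``(a, b)`` tuple, slice, or ``"a:b"`` string) of
        trailing cycles past the peak used to estimate the count
        background.
    lod_k :
        Multiple of the background standard deviation added to the
        background mean for the detection limit (3 by default; 0 gives
        the mean-only convention).
    """
    if not dose > 0:
        raise ValueError("dose must be positive")
    counts = implant_profile.counts
    sel = counts[_background_slice(background_cycles)]
    if sel.size < 1:
        raise ValueError("background_cycles selects no cycles")
    background_mean = float(np.mean(sel))
    background_sd = float(np.std(sel, ddof=1)) if sel.size > 1 else 0.0

    peak_idx = int(np.argmax(counts))
    bg_indices = np.arange(counts.size)[_background_slice(background_cycles)]
    if peak_idx in bg_indices:
        logger.warning(
            "background cycle range %s contains the profile maximum (cycle %d); "
            "background estimate may be biased high",
            background_cycles,
            peak_idx,
        )

    dz_cm = implant_profile.crater_depth_nm / implant_profile.n_cycles / NM_PER_CM
    net = np.clip(counts - background_mean, 0.0, None)
    integral = dz_cm * float(net.sum())
    if integral <= 0:
        raise ValueError(
            "net count integral is non-positive; profile does not contain an implant"
        )
    rsf = dose / integral
    lod_density = rsf * (background_mean + lod_k * background_sd)
    return RSFCalibration(
        dose=dose,
        rsf=rsf,
        background_mean=background_mean,
        background_sd=background_sd,
        lod_density=lod_density,
        species_label=implant_profile.species_label,
        matrix_label=matrix_label,
    )


def quantify_profile(profile: DepthProfile, cal: RSFCalibration) -> ConcentrationProfile:
    """Convert a raw depth profile to concentration versus depth.

    Each cycle's background-subtracted count (truncated at zero) is
    multiplied by the RSF; depths come from :func:`depth_scale`.
    """
    if profile.species_label != cal.species_label:
        raise ValueError(
            f"species mismatch: profile {profile.species_label!r} vs "
            f"calibration {cal.species_label!r}"
        )
    net = np.clip(profile.counts - cal.background_mean, 0.0, None)
    return ConcentrationProfile(
        depths_nm=depth_scale(profile),
        concentrations=cal.rsf * net,
        species_label=profile.species_label,
    )
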