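"""Unit conversion between Cl atomic density and insecticide weight percent.

Permethrin (C21H20Cl2O3) carries two chlorine atoms per molecule, so a
measured Cl atomic density ``C_Cl`` (atoms/cm^3) in an HDPE matrix maps
to a mass fraction under the dilute approximation (sample density equal
to the matrix density):

    wt% = 100 * (C_Cl / n_Cl) * M / N_A / rho

with ``n_Cl`` Cl atoms per molecule, ``M`` the analyte molar mass
(g/mol), ``N_A`` Avogadro's number and ``rho`` the matrix density
(g/cm^3).  The default constants (permethrin, 391.29 g/mol, 2 Cl; HDPE,
0.95 g/cm^3) are overridable for other analytes or matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ConcentrationProfile

__all__ = [
    "AVOGADRO",
    "MatrixModel",
    "DEFAULT_MATRIX",
    "cl_density_to_wtpct",
    "wtpct_to_cl_density",
    "profile_to_wtpct",
]

AVOGADRO = 6.02214076e23  # 1/mol (exact, SI 2019)


@dataclass(frozen=True)
class MatrixModel:
    """Stoichiometric constants tying Cl density to analyte mass fraction."""

    matrix_density: float = 0.95  # g/cm^3, HDPE
    analyte_molar_mass: float = 391.29  # g/mol, permethrin C21H20Cl2O3
    cl_atoms_per_molecule: int = 2
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if min(self.matrix_density, self.analyte_molar_mass, self.avogadro) <= 0:
            raise ValueError("matrix constants must be positive")
        if self.cl_atoms_per_molecule < 1:
            raise ValueError("cl_atoms_per_molecule must be >= 1")


DEFAULT_MATRIX = MatrixModel()


def cl_density_to_wtpct(c_cl, m: MatrixModel = DEFAULT_MATRIX):
    """Weight percent of analyte for a Cl atomic density (atoms/cm^3).

    Accepts scalars or arrays; linear in the input.
    """
    c = np.asarray(c_cl, dtype=float)
    if np.any(c < 0):
        raise ValueError("Cl density must be non-negative")
    w = 100.0 * (c / m.cl_atoms_per_molecule) * m.analyte_molar_mass / m.avogadro / m.matrix_density
    return float(w) if np.isscalar(c_cl) else w


def wtpct_to_cl_density(w, m: MatrixModel = DEFAULT_MATRIX):
    """Cl atomic density (atoms/cm^3) for an analyte weight percent.

    Exact inverse of :func:`cl_density_to_wtpct`.
    """
    warr = np.asarray(w, dtype=float)
    if np.any(warr < 0):
        raise ValueError("weight percent must be non-negative")
    c = warr / 100.0 * m.avogadro * m.matrix_density / m.analyte_molar_mass * m.cl_atoms_per_molecule
    return float(c) if np.isscalar(w) else c


def profile_to_wtpct(profile: ConcentrationProfile, m: MatrixModel = DEFAULT_MATRIX):
    """Depth (nm) and analyte wt% arrays for a concentration profile."""
    return profile.depths_nm, cl_density_to_wtpct(profile.concentrations, m)
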