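"""File formats and validated in-memory containers.

Three kinds of inputs are handled:

* **Depth profiles** — per-sputter-cycle secondary-ion counts for one or
  more species, as delimited text (CSV or TSV) with a header row naming
  the species columns, one row per cycle.  The total crater depth (from
  profilometry) is supplied separately, since it is measured after the
  profile is acquired.
* **Spot tables** — per-location analyte and reference intensities with
  sample and condition labels, as delimited text.
* **Ion cubes** — 3-D integer intensity rasters (rows x cols x sputter
  levels) with physical voxel metadata, stored in a single ``.npz``
  container holding the raster, the per-level depths, and a JSON
  metadata block (see README for the layout).  An optional imzML import
  adapter is provided for instrument exports.

All readers validate into the domain types below and never silently drop
rows; all reader/writer pairs round-trip losslessly on valid input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "IonCube",
    "SpotTable",
    "CONDITIONS",
    "read_depth_profile",
    "write_depth_profile",
    "read_spot_table",
    "write_spot_table",
    "read_ion_cube",
    "write_ion_cube",
    "read_imzml_cube",
]

#: Controlled vocabulary for experimental conditions in spot tables.
CONDITIONS = frozenset(
    {
        "initial",
        "washed",
        "incubated_4d",
        "incubated_10d",
        "unpressed",
        "unpressed_sputtered",
        "pressed",
        "pressed_sputtered",
        "other",
    }
)

_CONDITION_ALIASES = {
    "4d_incubated": "incubated_4d",
    "10d_incubated": "incubated_10d",
    "4d": "incubated_4d",
    "10d": "incubated_10d",
    "as_received": "unpressed",
}

_SPOT_COLUMNS = [
    "sample_id",
    "condition",
    "location_id",
    "analyte_intensity",
    "reference_intensity",
]


@dataclass(frozen=True)
class DepthProfile:
    """Per-cycle ion counts for one species, plus crater geometry.

    Parameters
    ----------
    species_label :
        Ion species, e.g. ``"35Cl-"``.
    counts :
        Non-negative counts, one entry per sputter cycle, in acquisition
        order.
    crater_depth_nm :
        Total sputter-crater depth in nm, measured by profilometry after
        the acquisition.
    analysis_area_um :
        Lateral (width, height) of the analysed area in micrometres.
    sputter_params :
        Free-text acquisition metadata, e.g. ``"3 keV Cs+, 20 nA"``.
    """

    species_label: str
    counts: np.ndarray
    crater_depth_nm: float
    analysis_area_um: tuple[float, float] = (50.0, 50.0)
    sputter_params: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(counts)):
            bad = int(np.flatnonzero(~np.isfinite(counts))[0]) + 1
            raise ValueError(f"non-finite count at cycle {bad}")
        if np.any(counts < 0):
            bad = int(np.flatnonzero(counts < 0)[0]) + 1
            raise ValueError(f"negative count at cycle {bad}")
        if not self.crater_depth_nm > 0:
            raise ValueError("crater_depth_nm must be positive")
        counts.flags.writeable = False
        object.__setattr__(self, "counts", counts)

    @property
    def n_cycles(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class IonCube:
    """3-D secondary-ion intensity raster with physical voxel metadata.

    ``intensities`` is indexed ``[row, col, level]``; rows and columns are
    lateral with pitch ``pixel_size_um``, levels are successive sputter
    depths ``level_depths_um`` (strictly increasing, micrometres).
    """

    intensities: np.ndarray
    pixel_size_um: float
    level_depths_um: np.ndarray
    species_label: str = "35Cl-"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError("intensities must be a non-empty 3-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("intensities must be integer-valued")
            arr = np.round(arr).astype(np.int64)
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        depths = np.asarray(self.level_depths_um, dtype=float)
        if depths.ndim != 1 or depths.size != arr.shape[2]:
            raise ValueError(
                f"level_depths_um has {depths.size} entries for "
                f"{arr.shape[2]} levels"
            )
        if not np.all(np.diff(depths) > 0):
            raise ValueError("level_depths_um must be strictly increasing")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        arr = np.ascontiguousarray(arr)
        arr.flags.writeable = False
        depths.flags.writeable = False
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "level_depths_um", depths)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_voxels(self) -> int:
        return int(self.intensities.size)


@dataclass
class SpotTable:
    """Per-location analyte/reference intensity records.

    The wrapped DataFrame has columns ``sample_id``, ``condition``,
    ``location_id``, ``analyte_intensity``, ``reference_intensity``.
    Conditions are restricted to :data:`CONDITIONS`; ``location_id`` is
    unique within each (sample, condition) group and reference
    intensities are strictly positive so ratios are always defined.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _SPOT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        df = df[_SPOT_COLUMNS].copy()
        df["condition"] = df["condition"].map(normalize_condition)
        df["location_id"] = df["location_id"].astype(int)
        for col in ("analyte_intensity", "reference_intensity"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        if df["analyte_intensity"].isna().any() or df["reference_intensity"].isna().any():
            raise ValueError("spot table contains missing intensities")
        nonpos = df["reference_intensity"] <= 0
        if nonpos.any():
            row = df.index[nonpos][0]
            raise ValueError(
                f"non-positive reference_intensity at row {row} "
                f"(location {df.loc[row, 'location_id']})"
            )
        dup = df.duplicated(subset=["sample_id", "condition", "location_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate location_id "
                f"{row['location_id']} within ({row['sample_id']}, "
                f"{row['condition']})"
            )
        self.df = df.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.df)


def normalize_condition(label: str) -> str:
    """Map a free-form condition label onto the controlled vocabulary."""
    key = str(label).strip().lower().replace(" ", "_").replace("-", "_")
    key = _CONDITION_ALIASES.get(key, key)
    if key not in CONDITIONS:
        raise ValueError(
            f"unknown condition {label!r}; allowed: {sorted(CONDITIONS)}"
        )
    return key


# ---------------------------------------------------------------------------
# delimited tables


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a mandatory header row."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


# ---------------------------------------------------------------------------
# depth profiles


def read_depth_profile(
    path: str | Path,
    crater_depth_nm: float,
    analysis_area_um: tuple[float, float] = (50.0, 50.0),
    sputter_params: str = "",
) -> dict[str, DepthProfile]:
    """Read a delimited per-cycle counts table into DepthProfiles.

    The file must have a header row naming one column per species and one
    data row per sputter cycle, in acquisition order.  Returns a mapping
    from species label to profile; all profiles share ``crater_depth_nm``.
    """
    df = _read_delimited(path)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: no profile data found")
    profiles: dict[str, DepthProfile] = {}
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            row = int(np.flatnonzero(~np.isfinite(values))[0]) + 1
            raise ValueError(f"{path}: missing or non-numeric count at row {row}, column {col!r}")
        if np.any(values < 0):
            row = int(np.flatnonzero(values < 0)[0]) + 1
            raise ValueError(f"{path}: negative count at row {row}, column {col!r}")
        profiles[str(col)] = DepthProfile(
            species_label=str(col),
            counts=values,
            crater_depth_nm=crater_depth_nm,
            analysis_area_um=analysis_area_um,
            sputter_params=sputter_params,
        )
    return profiles


def write_depth_profile(profiles: Mapping[str, DepthProfile] | DepthProfile, path: str | Path) -> None:
    """Write one or more depth profiles (same cycle count) as CSV."""
    if isinstance(profiles, DepthProfile):
        profiles = {profiles.species_label: profiles}
    lengths = {p.n_cycles for p in profiles.values()}
    if len(lengths) != 1:
        raise ValueError("all profiles in one file must share n_cycles")
    df = pd.DataFrame({label: p.counts for label, p in profiles.items()})
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# spot tables


def read_spot_table(path: str | Path) -> SpotTable:
    """Read a delimited spot-measurement table."""
    return SpotTable(_read_delimited(path))


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# ion cubes

_CUBE_FORMAT_VERSION = 1


def write_ion_cube(cube: IonCube, path: str | Path) -> None:
    """Write an ion cube to the single-file ``.npz`` container.

    The container stores the integer raster under ``intensities``, the
    level depths under ``level_depths_um`` and a JSON metadata block
    under ``meta`` (pixel size, species label, format version).
    """
    meta = {
        "format_version": _CUBE_FORMAT_VERSION,
        "pixel_size_um": float(cube.pixel_size_um),
        "species_label": cube.species_label,
    }
    np.savez(
        path,
        intensities=cube.intensities,
        level_depths_um=cube.level_depths_um,
        meta=np.bytes_(json.dumps(meta).encode()),
    )


def read_ion_cube(path: str | Path) -> IonCube:
    """Read an ion cube written by :func:`write_ion_cube`."""
    with np.load(path) as npz:
        if "meta" not in npz or "intensities" not in npz or "level_depths_um" not in npz:
            raise ValueError(f"{path}: not an ion-cube container (missing entries)")
        meta = json.loads(bytes(npz["meta"].item()).decode())
        pixel_size = float(meta.get("pixel_size_um", 0.0))
        if pixel_size <= 0:
            raise ValueError(f"{path}: invalid pixel_size_um in metadata")
        return IonCube(
            intensities=npz["intensities"],
            pixel_size_um=pixel_size,
            level_depths_um=npz["level_depths_um"],
            species_label=str(meta.get("species_label", "")),
        )


def read_imzml_cube(
    path: str | Path,
    pixel_size_um: float,
    level_depths_um: np.ndarray | None = None,
    species_label: str = "35Cl-",
) -> IonCube:
    """Import a 3-D cube from an imzML file (optional adapter).

    Each spectrum's total intensity is summed into the voxel addressed by
    its (x, y, z) coordinates; z indexes the sputter level.  Physical
    voxel metadata is not reliably stored in imzML exports, so it is
    supplied by the caller (``level_depths_um`` defaults to 1-µm-spaced
    levels).
    """
    from pyimzml.ImzMLParser import ImzMLParser  # deferred optional import

    parser = ImzMLParser(str(path))
    coords = np.asarray(parser.coordinates, dtype=int)
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.ones(len(coords), dtype=int)])
    nx, ny, nz = coords.max(axis=0)
    arr = np.zeros((int(ny), int(nx), int(nz)), dtype=np.int64)
    for i, (x, y, z) in enumerate(coords):
        _, intens = parser.getspectrum(i)
        arr[y - 1, x - 1, z - 1] += int(round(float(np.sum(intens))))
    if level_depths_um is None:
        level_depths_um = np.arange(arr.shape[2], dtype=float)
    return IonCube(
        intensities=arr,
        pixel_size_um=pixel_size_um,
        level_depths_um=level_depths_um,
        species_label=species_label,
    )
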