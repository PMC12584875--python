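"""Volumetric and tabular I/O plus the package-wide coordinate conventions.

Conventions used by every other module
--------------------------------------
* Volume arrays are indexed ``[z, y, x]`` with x the fastest (storage) axis,
  matching the standard MRC2014 interpretation; z is the tomogram beam axis
  and therefore the missing-wedge axis.
* Voxel indices are 0-based and refer to voxel centers; the physical position
  of index ``(i, j, k)`` (z, y, x) is ``index * voxel_size + origin`` in
  Angstrom, component-wise.
* Point coordinates are stored as ``(x, y, z)`` triples in Angstrom.
* Thickness values are reported in nm (1 nm = 10 A).

MRC2014 reading/writing is delegated to :mod:`gemmi`; STAR-style particle
tables are parsed with ``gemmi.cif`` (STAR is the parent syntax of CIF).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .exceptions import DataError, SchemaError, VolumeParseError

logger = logging.getLogger(__name__)

A_PER_NM = 10.0

#: fixed column order of the measurements CSV
MEASUREMENT_COLUMNS = [
    "instance_label",
    "p1_x", "p1_y", "p1_z",
    "p2_x", "p2_y", "p2_z",
    "n1_x", "n1_y", "n1_z",
    "n2_x", "n2_y", "n2_z",
    "thickness_nm",
    "theta_deg",
    "valid",
    "rejection_reason",
]


@dataclass
class DensityVolume:
    """A 3D scalar grid with physical voxel size.

    Parameters
    ----------
    values
        Scalar grid indexed ``[z, y, x]``.
    voxel_size
        A per voxel as an ``(x, y, z)`` triple (isotropic input broadcast).
    origin
        Physical offset of voxel ``(0, 0, 0)`` in A, ``(x, y, z)``.
    mode
        MRC mode of the file this volume was read from, if any.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mode: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise DataError("volume grid must be 3D with dimensions >= 1")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise DataError(f"voxel size must be positive, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def index_to_xyz(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Physical (x, y, z) positions in A of fractional ``[z, y, x]`` indices."""
        idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
        return idx[:, ::-1] * self.voxel_size + self.origin

    def xyz_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional ``[z, y, x]`` indices of physical (x, y, z) positions in A."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return ((xyz - self.origin) / self.voxel_size)[:, ::-1]


@dataclass
class LabelVolume(DensityVolume):
    """Instance segmentation on the same grid conventions as DensityVolume.

    0 is background; each positive integer is one membrane instance.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if np.max(np.abs(self.values - rounded)) > 1e-6:
                raise DataError("label volume contains non-integral values")
            self.values = rounded.astype(np.int32)
        if self.values.min() < 0:
            raise DataError("label volume contains negative labels")

    @property
    def labels(self) -> np.ndarray:
        return self.values

    @property
    def instances(self) -> np.ndarray:
        """Sorted positive instance labels present in the volume."""
        u = np.unique(self.values)
        return u[u > 0]


@dataclass
class ParticleTable:
    """Particle positions in physical A coordinates, order-preserving."""

    table: pd.DataFrame  # columns x, y, z (A) plus any extras

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def check_bounds(self, volume: DensityVolume, margin: float = 0.0) -> np.ndarray:
        """Warn about particles outside the volume; returns an in-bounds mask."""
        lo = volume.origin - margin
        hi = volume.origin + (np.array(volume.shape)[::-1] - 1) * volume.voxel_size + margin
        pos = self.positions
        ok = np.all((pos >= lo) & (pos <= hi), axis=1)
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} of {len(ok)} particles fall outside the volume bounds",
                stacklevel=2,
            )
        return ok


def _grid_to_array(grid) -> np.ndarray:
    # gemmi grids expose axes as (x, y, z); our convention is [z, y, x]
    return np.array(grid, copy=True).transpose(2, 1, 0)


def _array_to_grid(values_zyx: np.ndarray, voxel_size: np.ndarray, grid_cls):
    arr = np.ascontiguousarray(values_zyx.transpose(2, 1, 0))
    grid = grid_cls(arr)
    nx, ny, nz = arr.shape
    grid.set_unit_cell(
        gemmi.UnitCell(
            nx * voxel_size[0], ny * voxel_size[1], nz * voxel_size[2], 90, 90, 90
        )
    )
    return grid


def read_volume(path: str | Path, kind: str = "density") -> DensityVolume | LabelVolume:
    """Read an MRC2014 volume.

    Parameters
    ----------
    path
        MRC file path.
    kind
        ``"density"`` or ``"label"``. Label volumes must hold integral values
        (rounding tolerance 1e-6).
    """
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        size = path.stat().st_size if path.exists() else 0
        raise VolumeParseError(
            f"cannot parse {path} as MRC2014 (file size {size} bytes): {exc}"
        ) from exc
    mode = ccp4.header_i32(4)
    values = _grid_to_array(ccp4.grid)
    spacing = np.array(ccp4.grid.spacing, dtype=float)  # (x, y, z)
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        logger.warning(
            "anisotropic voxel size %s A in %s; per-axis sizes retained", spacing, path
        )
    if kind == "label":
        return LabelVolume(values, spacing, origin, mode=mode)
    if kind == "density":
        return DensityVolume(values.astype(np.float32), spacing, origin, mode=mode)
    raise ValueError(f"kind must be 'density' or 'label', got {kind!r}")


def write_volume(vol: DensityVolume, path: str | Path) -> None:
    """Write a volume as MRC2014.

    Density volumes are written as float32 (mode 2). Label volumes with all
    labels <= 127 are written as int8 (mode 0); larger label sets fall back to
    float32 with integral values.
    """
    if not np.all(np.isfinite(vol.values)):
        raise DataError("volume contains non-finite values; refusing to write")
    path = Path(path)
    if isinstance(vol, LabelVolume) and vol.values.max(initial=0) <= 127:
        grid = _array_to_grid(vol.values.astype(np.int8), vol.voxel_size, gemmi.Int8Grid)
        ccp4 = gemmi.Ccp4Mask()
    else:
        grid = _array_to_grid(
            vol.values.astype(np.float32), vol.voxel_size, gemmi.FloatGrid
        )
        ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), vol.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(path))


_STAR_XYZ = ["_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ"]
_CSV_XYZ = ["x", "y", "z"]


def _read_star_table(path: Path) -> pd.DataFrame:
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()
    found = block.find(_STAR_XYZ)
    if len(found) == 0:
        # maybe tags present but empty table, or tags missing
        present = [t for t in _STAR_XYZ if block.find_loop(t) or block.find_value(t)]
        if len(present) < 3:
            raise SchemaError(
                f"{path}: STAR table must provide columns {_STAR_XYZ}"
            )
    rows = [[float(row[i]) for i in range(3)] for row in found]
    return pd.DataFrame(rows, columns=_CSV_XYZ)


def read_particles(
    path: str | Path,
    units: str = "angstrom",
    voxel_size: float | np.ndarray | None = None,
) -> ParticleTable:
    """Read particle coordinates from a STAR-style table or CSV.

    Parameters
    ----------
    units
        ``"voxel"`` or ``"angstrom"``; voxel coordinates are converted to A
        using ``voxel_size``.
    """
    path = Path(path)
    if path.suffix.lower() == ".star":
        df = _read_star_table(path)
    else:
        raw = pd.read_csv(path)
        cols = {c.lower(): c for c in raw.columns}
        if all(c in cols for c in _CSV_XYZ):
            df = raw.rename(columns={cols[c]: c for c in _CSV_XYZ})
        elif all(c.lower() in cols for c in _STAR_XYZ):
            df = raw.rename(
                columns={cols[t.lower()]: c for t, c in zip(_STAR_XYZ, _CSV_XYZ)}
            )
        else:
            raise SchemaError(
                f"{path}: expected position columns {_CSV_XYZ} or {_STAR_XYZ}, "
                f"got {list(raw.columns)}"
            )
    df = df.copy()
    if units == "voxel":
        if voxel_size is None:
            raise ValueError("voxel units require voxel_size")
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        df[_CSV_XYZ] = df[_CSV_XYZ].to_numpy(dtype=float) * vs
    elif units != "angstrom":
        raise ValueError(f"units must be 'voxel' or 'angstrom', got {units!r}")
    return ParticleTable(df)


def measurements_frame(pairs) -> pd.DataFrame:
    """Assemble the measurements table (fixed column order) from a pair set.

    ``pairs`` is a :class:`tomothick.pairing.PointPairs`.
    """
    n = len(pairs.thickness_nm)
    data = {
        "instance_label": np.full(n, pairs.instance_label, dtype=int),
        "p1_x": pairs.p1[:, 0], "p1_y": pairs.p1[:, 1], "p1_z": pairs.p1[:, 2],
        "p2_x": pairs.p2[:, 0], "p2_y": pairs.p2[:, 1], "p2_z": pairs.p2[:, 2],
        "n1_x": pairs.n1[:, 0], "n1_y": pairs.n1[:, 1], "n1_z": pairs.n1[:, 2],
        "n2_x": pairs.n2[:, 0], "n2_y": pairs.n2[:, 1], "n2_z": pairs.n2[:, 2],
        "thickness_nm": pairs.thickness_nm,
        "theta_deg": pairs.theta_deg,
        "valid": pairs.valid,
        "rejection_reason": pairs.rejection_reason,
    }
    return pd.DataFrame(data, columns=MEASUREMENT_COLUMNS)


def write_measurements(pairs, path: str | Path) -> None:
    """Write one CSV row per point pair (valid and rejected alike).

    Numeric precision: positions/normals and nm values 3 decimals, angles 2.
    """
    df = measurements_frame(pairs) if not isinstance(pairs, pd.DataFrame) else pairs
    df = df.copy()
    for col in df.columns:
        if col.startswith(("p1_", "p2_", "n1_", "n2_")) or col == "thickness_nm":
            df[col] = df[col].map(lambda v: f"{v:.3f}" if np.isfinite(v) else "")
        elif col == "theta_deg":
            df[col] = df[col].map(lambda v: f"{v:.2f}" if np.isfinite(v) else "")
    df.to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Re-read a measurements CSV written by :func:`write_measurements`."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing measurement columns {missing}")
    return df
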