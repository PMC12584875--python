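"""Resolution-limited EM density maps from atomistic membrane-protein systems.

Each atom is splatted as a normalized 3D Gaussian blob whose width sets the
target resolution (sigma = FWHM / 2.35). In amplitude mode an atom
contributes its elastic scattering amplitude A(element); in weak-phase mode
it contributes the imaginary part of A exp(i * phase_strength * phi), the
weak phase object approximation with phi a per-element electrostatic
potential proxy. The discrete blob is renormalized so each atom's map
integral equals its amplitude exactly, making the total integral an exact
sum over atoms.

The per-element amplitude table is proportional to Z^(4/3), normalized to
carbon (a Mott-like scaling of elastic cross sections); phi is proportional
to the atomic number Z. Both tables are configurable -- every downstream
thickness and asymmetry readout depends only on relative contrast, so the
absolute scale is immaterial.

Simulated maps use physical density (dense = high values); the shared
feature detector is therefore run with inverted contrast when treating
headgroup layers as profile minima, matching the cryo-ET convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError

from .exceptions import ConfigError, DataError, DegenerateGeometryError
from .profiles import IntensityProfile, ProfileParams, detect_features
from .volume_io import A_PER_NM, DensityVolume

#: atomic numbers of supported elements
ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}

#: relative elastic scattering amplitudes, Z^(4/3) normalized to carbon
SCATTERING_AMPLITUDES = {
    el: (z / 6.0) ** (4.0 / 3.0) for el, z in ATOMIC_NUMBERS.items()
}

#: electrostatic potential proxy (relative), proportional to Z
POTENTIALS = {el: z / 6.0 for el, z in ATOMIC_NUMBERS.items()}


@dataclass
class SimParams:
    mode: str = "amplitude"  # or "weak_phase"
    fwhm: float = 1.6  # target resolution, A
    phase_strength: float = 0.2
    voxel_size: float = 0.8  # A; finer than tomograms, resolves the blobs
    truncation_sigmas: float = 4.0
    amplitudes: dict = field(default_factory=lambda: dict(SCATTERING_AMPLITUDES))
    potentials: dict = field(default_factory=lambda: dict(POTENTIALS))

    def __post_init__(self) -> None:
        if self.mode not in ("amplitude", "weak_phase"):
            raise ConfigError("mode must be 'amplitude' or 'weak_phase'")
        if self.fwhm <= 0 or self.voxel_size <= 0:
            raise ConfigError("fwhm and voxel_size must be positive")

    @property
    def sigma(self) -> float:
        """Gaussian width in A: FWHM / 2.35."""
        return self.fwhm / 2.35


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise DataError(f"cannot guess element from atom name {name!r}")


@dataclass
class AtomSet:
    """Atomistic coordinates with element symbols and selection flags."""

    elements: np.ndarray  # (N,) str
    positions: np.ndarray  # (N, 3) A
    is_protein: np.ndarray  # (N,) bool
    box: np.ndarray  # (3,) A

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        self.is_protein = np.asarray(self.is_protein, dtype=bool)
        self.box = np.asarray(self.box, dtype=float)
        out = (self.positions < 0) | (self.positions >= self.box)
        if out.any():
            warnings.warn(
                f"{int(out.any(axis=1).sum())} atoms outside the box; "
                "blobs are wrapped periodically",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def is_phosphorus(self) -> np.ndarray:
        return self.elements == "P"

    def select(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(
            self.elements[mask], self.positions[mask],
            self.is_protein[mask], self.box,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "AtomSet":
        """Read PDB or GRO coordinates via MDAnalysis.

        Protein atoms are identified by MDAnalysis's standard protein
        residue selection; elements come from the topology when present,
        else from the first letter of the atom name.
        """
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        try:
            elements = np.array([e.upper() for e in u.atoms.elements], dtype=object)
        except (AttributeError, mda.exceptions.NoDataError):
            elements = np.array(
                [_guess_element(n) for n in u.atoms.names], dtype=object
            )
        protein = np.zeros(len(u.atoms), dtype=bool)
        protein[u.select_atoms("protein").ix] = True
        if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
            lo = u.atoms.positions.min(axis=0)
            box = u.atoms.positions.max(axis=0) - lo + 2.0
            pos = u.atoms.positions - lo + 1.0
        else:
            box = u.dimensions[:3].astype(float)
            pos = u.atoms.positions.astype(float)
        return cls(elements, pos, protein, box)


def atoms_to_density(atoms: AtomSet, params: SimParams | None = None) -> DensityVolume:
    """Accumulate per-atom Gaussian blobs into a density map.

    Amplitude mode: value weight A(element). Weak-phase mode: weight
    A sin(phase_strength * phi(element)), the imaginary component of the
    complex transmission A exp(i phase_strength phi). Blobs are truncated at
    ``truncation_sigmas`` and wrapped periodically (MD boxes are periodic);
    each atom's discrete integral is renormalized to its weight exactly.
    """
    params = params or SimParams()
    sigma = params.sigma
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    unknown = sorted({e for e in atoms.elements if e not in params.amplitudes})
    if unknown:
        raise ConfigError(
            f"no scattering amplitude for element(s) {unknown}; "
            f"table covers {sorted(params.amplitudes)}"
        )
    v = params.voxel_size
    dims_xyz = np.maximum(np.ceil(atoms.box / v).astype(int), 1)
    nx, ny, nz = dims_xyz
    values = np.zeros(nx * ny * nz)  # flat, index = (ix * ny + iy) * nz + iz
    radius = int(np.ceil(params.truncation_sigmas * sigma / v))
    k = 2 * radius + 1
    offsets = np.arange(-radius, radius + 1)
    voxel_volume = v**3

    for element in np.unique(atoms.elements):
        amp = params.amplitudes[element]
        if params.mode == "weak_phase":
            weight = amp * np.sin(params.phase_strength * params.potentials[element])
        else:
            weight = amp
        pos = atoms.positions[atoms.elements == element]
        for start in range(0, len(pos), 2048):
            p = pos[start : start + 2048]
            base = np.rint(p / v).astype(int)  # (M, 3)
            # per-axis Gaussian factors at voxel centers (M, k) per axis
            centers = (base[:, :, None] + offsets[None, None, :]) * v
            g = np.exp(-((centers - p[:, :, None]) ** 2) / (2 * sigma**2))
            blob = np.einsum("mi,mj,mk->mijk", g[:, 0], g[:, 1], g[:, 2])
            blob *= (weight / voxel_volume) / blob.sum(axis=(1, 2, 3), keepdims=True)
            idx = np.mod(base[:, :, None] + offsets[None, None, :], dims_xyz[None, :, None])
            flat = (
                (idx[:, 0, :, None, None] * ny + idx[:, 1, None, :, None]) * nz
                + idx[:, 2, None, None, :]
            )
            np.add.at(values, flat.ravel(), blob.ravel())

    grid = values.reshape(nx, ny, nz).transpose(2, 1, 0)  # to [z, y, x]
    return DensityVolume(grid, v)


@dataclass
class Footprint:
    """Protein footprint in the membrane (XY) plane."""

    com_xy: np.ndarray  # (2,) A
    hull_xy: np.ndarray | None  # (M, 2) hull vertices in order, A; None = point
    area: float  # A^2
    equivalent_radius: float  # A, radius of the equal-area circle

    @classmethod
    def point(cls, center_xy) -> "Footprint":
        """Degenerate footprint for protein-free controls: a point reference."""
        return cls(np.asarray(center_xy, dtype=float), None, 0.0, 0.0)


def protein_footprint(atoms: AtomSet) -> Footprint:
    """Center of mass, convex hull and equivalent radius of the protein in XY."""
    xy = atoms.positions[atoms.is_protein][:, :2]
    if len(xy) == 0:
        raise DataError("no protein atoms in selection")
    if len(xy) < 3:
        raise DegenerateGeometryError("need >= 3 protein atoms for a footprint hull")
    com = xy.mean(axis=0)
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"protein atoms are (nearly) collinear in XY: {exc}"
        ) from exc
    area = float(hull.volume)  # 2D: "volume" is the area
    return Footprint(
        com_xy=com,
        hull_xy=xy[hull.vertices],
        area=area,
        equivalent_radius=float(np.sqrt(area / np.pi)),
    )


def _footprint_distance(
    xy: np.ndarray, footprint: Footprint, from_com: bool = False
) -> np.ndarray:
    """Signed distance in A: 0 at the footprint edge, negative inside."""
    if from_com or footprint.hull_xy is None:
        return np.linalg.norm(xy - footprint.com_xy, axis=1)
    poly = shapely.Polygon(footprint.hull_xy)
    pts = shapely.points(xy)
    d = shapely.distance(pts, poly.exterior)
    inside = shapely.contains(poly, pts)
    return np.where(inside, -d, d)


@dataclass
class AnnularProfile:
    """Distance-binned z density profile around the protein footprint."""

    r_in: float  # nm
    r_out: float  # nm
    z_nm: np.ndarray
    density: np.ndarray | None
    gradient: np.ndarray | None
    n_positions: int
    empty: bool = False


def annular_profiles(
    vol: DensityVolume,
    footprint: Footprint,
    bin_edges_nm,
    from_com: bool = False,
) -> list[AnnularProfile]:
    """Mean z-profiles over concentric annuli of footprint distance.

    ``bin_edges_nm`` are ascending edges, e.g. [0, 1, 2, 3]; distances are
    measured from the convex-hull boundary (``from_com=True`` measures from
    the center of mass instead). XY positions inside the hull carry negative
    distance and belong to no bin with a non-negative lower edge.
    """
    edges = np.asarray(bin_edges_nm, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigError("bin edges must be ascending with >= 2 entries")
    nz, ny, nx = vol.shape
    vx, vy, vz = vol.voxel_size
    xs = np.arange(nx) * vx + vol.origin[0]
    ys = np.arange(ny) * vy + vol.origin[1]
    xy = np.stack(np.meshgrid(xs, ys, indexing="xy"), axis=-1).reshape(-1, 2)
    d_nm = _footprint_distance(xy, footprint, from_com) / A_PER_NM
    d_nm = d_nm.reshape(ny, nx)
    z_nm = (np.arange(nz) * vz + vol.origin[2]) / A_PER_NM
    out = []
    for r_in, r_out in zip(edges[:-1], edges[1:]):
        mask = (d_nm >= r_in) & (d_nm < r_out)
        n_pos = int(mask.sum())
        if n_pos == 0:
            out.append(AnnularProfile(r_in, r_out, z_nm, None, None, 0, empty=True))
            continue
        prof = vol.values[:, mask].mean(axis=1)
        out.append(
            AnnularProfile(
                r_in, r_out, z_nm, prof, np.gradient(prof), n_pos
            )
        )
    return out


def protein_only_profile(
    atoms: AtomSet, params: SimParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(z_nm, density) of the isolated protein, for the comparison panel."""
    sub = atoms.select(atoms.is_protein)
    if len(sub) == 0:
        raise DataError("no protein atoms in selection")
    vol = atoms_to_density(sub, params)
    z_nm = np.arange(vol.shape[0]) * vol.voxel_size[2] / A_PER_NM
    return z_nm, vol.values.mean(axis=(1, 2))


def _gradient_extrema(g: np.ndarray) -> np.ndarray:
    """Indices of strict local extrema of a 1D array."""
    dg = np.diff(g)
    sign = np.sign(dg)
    # ignore flat steps by propagating the previous sign
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    return np.flatnonzero(sign[1:] * sign[:-1] < 0) + 1


def profile_thickness(
    ap: AnnularProfile, params: ProfileParams | None = None
) -> tuple[float, float]:
    """(minima-to-minima, inflection-to-inflection) thickness in nm.

    Feature detection runs on the z-profile with inverted contrast (dense
    headgroup layers as minima). Inflection points are the first strict
    extrema of the density gradient found outward from each headgroup
    minimum.
    """
    if ap.empty or ap.density is None:
        raise DataError("annular bin is empty; no profile to measure")
    params = params or ProfileParams(invert_contrast=True)
    step = float(ap.z_nm[1] - ap.z_nm[0])
    profile = IntensityProfile(ap.density, step, 0, len(ap.density) - 1)
    res = detect_features(profile, params)
    if not res.accepted:
        raise DataError(f"bilayer features not detectable: {res.reason}")
    m1, m2 = res.m1_idx, res.m2_idx
    thickness_minima = (m2 - m1) * step
    y = -ap.density if params.invert_contrast else ap.density
    g = np.gradient(y)
    ext = _gradient_extrema(g)
    left = ext[ext < m1]
    right = ext[ext > m2]
    if len(left) == 0 or len(right) == 0:
        raise DataError("no gradient extremum outward of a headgroup minimum")
    i1, i2 = int(left[-1]), int(right[0])
    thickness_inflection = (i2 - i1) * step
    return float(thickness_minima), float(thickness_inflection)


@dataclass
class PhosphateBin:
    r_in: float
    r_out: float
    z_values_nm: np.ndarray
    hist: np.ndarray
    hist_edges_nm: np.ndarray
    leaflet_mean_z_nm: tuple[float, float] | None
    leaflet_median_z_nm: tuple[float, float] | None


def project_phosphates(
    atoms: AtomSet,
    footprint: Footprint,
    bin_edges_nm,
    z_step_nm: float,
    from_com: bool = False,
) -> list[PhosphateBin]:
    """Per-annulus phosphorus z-coordinates, histogrammed at the profile step.

    Leaflet statistics split the atoms at the mean phosphorus z; bins without
    atoms yield empty histograms (no error).
    """
    pmask = atoms.is_phosphorus
    if not pmask.any():
        raise DataError("no phosphorus atoms in selection")
    pos = atoms.positions[pmask]
    d_nm = _footprint_distance(pos[:, :2], footprint, from_com) / A_PER_NM
    z_nm = pos[:, 2] / A_PER_NM
    mid = float(z_nm.mean())
    edges = np.asarray(bin_edges_nm, dtype=float)
    out = []
    for r_in, r_out in zip(edges[:-1], edges[1:]):
        sel = (d_nm >= r_in) & (d_nm < r_out)
        z = np.sort(z_nm[sel])
        if len(z):
            lo = np.floor(z.min() / z_step_nm) * z_step_nm
            hedges = np.arange(lo, z.max() + z_step_nm, z_step_nm)
            if len(hedges) < 2:
                hedges = np.array([lo, lo + z_step_nm])
            hist, hedges = np.histogram(z, bins=hedges)
            lower, upper = z[z < mid], z[z >= mid]
            mean_z = (
                (float(lower.mean()), float(upper.mean()))
                if len(lower) and len(upper) else None
            )
            med_z = (
                (float(np.median(lower)), float(np.median(upper)))
                if len(lower) and len(upper) else None
            )
        else:
            hist, hedges = np.zeros(0, dtype=int), np.zeros(0)
            mean_z = med_z = None
        out.append(PhosphateBin(r_in, r_out, z, hist, hedges, mean_z, med_z))
    return out
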