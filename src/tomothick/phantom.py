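"""Synthetic phantoms: matched (tomogram, segmentation, ground truth) triplets.

The intensity model mirrors a cryo-ET membrane in cross section: on the
signed distance s to the mid-surface (nm),

    I(s) = baseline - d1 G(s + dm; sigma_t) - d2 G(s - dm; sigma_t)
           + core G(s; sigma_c)

with G a unit-amplitude Gaussian, two headgroup troughs of depths d1, d2
(asymmetry ratio rho = d1/d2) centered at +-dm and a central hydrophobic
ridge. The segmentation label covers |s| <= thickness/2 where the nominal
boundary-to-boundary thickness is measured at the troughs' outward
inflection surfaces: dm = thickness/2 - sigma_t, so the label edge sits at
the steepest intensity change, where membrane-segmentation networks place
their boundaries. Optional seeded Gaussian white noise and a hard Fourier
missing-wedge mask emulate tomographic acquisition conditions.

The default slab is tilted 12 degrees about y: an exactly axis-aligned plane
is a degenerate orientation in which the binary label locks to a single
voxel-quantization phase and the boundary readout inherits a bias of up to
half a voxel, which generic (real-world) orientations average away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DataError
from .profiles import IntensityProfile
from .volume_io import A_PER_NM, DensityVolume, LabelVolume

GEOMETRIES = ("slab", "sphere", "tube", "sine")


@dataclass
class PhantomSpec:
    """Generation parameters; the defaults are the package's study conditions."""

    geometry: str = "slab"
    shape: tuple[int, int, int] = (64, 96, 96)  # (nz, ny, nx) voxels
    voxel_size: float = 7.84  # A, bin4 working resolution
    thickness_nm: float = 5.0  # boundary-to-boundary at the inflection surfaces
    trough_depth1: float = 1.0
    trough_depth2: float = 1.0
    trough_sigma_nm: float = 0.5
    core_height: float = 0.3
    core_sigma_nm: float = 0.8
    baseline: float = 0.0
    noise_sigma: float = 0.0
    wedge_half_angle: float | None = None  # degrees; 30 matches a +-60 tilt range
    seed: int = 0
    slab_tilt_deg: float = 12.0
    sphere_radius_nm: float = 40.0
    tube_radius_nm: float = 20.0
    sine_amplitude_nm: float = 3.0
    sine_period_nm: float = 50.0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ConfigError(f"geometry must be one of {GEOMETRIES}")
        if self.thickness_nm <= 2 * self.trough_sigma_nm:
            raise ConfigError(
                "thickness_nm must exceed 2 x trough_sigma_nm "
                "(troughs must fit inside the membrane)"
            )
        if self.voxel_size <= 0:
            raise ConfigError("voxel_size must be positive")

    @property
    def trough_offset_nm(self) -> float:
        """Distance of each trough center from the mid-surface."""
        return self.thickness_nm / 2 - self.trough_sigma_nm


def _center_nm(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.shape
    v = spec.voxel_size / A_PER_NM
    return (np.array([nx, ny, nz], dtype=float) - 1) / 2 * v  # (x, y, z) nm


def _slab_normal(spec: PhantomSpec) -> np.ndarray:
    t = np.deg2rad(spec.slab_tilt_deg)
    return np.array([np.sin(t), 0.0, np.cos(t)])


def signed_distance(spec: PhantomSpec, xyz_nm: np.ndarray) -> np.ndarray:
    """Signed distance (nm) from points (x, y, z in nm) to the mid-surface."""
    p = np.atleast_2d(np.asarray(xyz_nm, dtype=float)) - _center_nm(spec)
    if spec.geometry == "slab":
        return p @ _slab_normal(spec)
    if spec.geometry == "sphere":
        return np.linalg.norm(p, axis=-1) - spec.sphere_radius_nm
    if spec.geometry == "tube":
        return np.hypot(p[:, 0], p[:, 2]) - spec.tube_radius_nm
    # sine sheet: vertical offset from z = A sin(k x), scaled by the local
    # slope cosine -- first-order perpendicular distance, accurate while the
    # surface curvature radius stays large against the membrane thickness
    k = 2 * np.pi / spec.sine_period_nm
    dz = p[:, 2] - spec.sine_amplitude_nm * np.sin(k * p[:, 0])
    slope = spec.sine_amplitude_nm * k * np.cos(k * p[:, 0])
    return dz / np.sqrt(1.0 + slope**2)


def analytic_normal(spec: PhantomSpec, xyz_nm: np.ndarray) -> np.ndarray:
    """Unit normals of the mid-surface (pointing toward s > 0)."""
    p = np.atleast_2d(np.asarray(xyz_nm, dtype=float)) - _center_nm(spec)
    if spec.geometry == "slab":
        return np.broadcast_to(_slab_normal(spec), p.shape).copy()
    if spec.geometry == "sphere":
        return p / np.maximum(np.linalg.norm(p, axis=-1, keepdims=True), 1e-12)
    if spec.geometry == "tube":
        n = np.zeros_like(p)
        r = np.maximum(np.hypot(p[:, 0], p[:, 2]), 1e-12)
        n[:, 0] = p[:, 0] / r
        n[:, 2] = p[:, 2] / r
        return n
    k = 2 * np.pi / spec.sine_period_nm
    n = np.zeros_like(p)
    n[:, 0] = -spec.sine_amplitude_nm * k * np.cos(k * p[:, 0])
    n[:, 2] = 1.0
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


@dataclass
class PhantomTruth:
    """Analytic ground truth of a generated phantom."""

    spec: PhantomSpec

    @property
    def thickness_nm(self) -> float:
        return self.spec.thickness_nm

    @property
    def trough_centers_nm(self) -> tuple[float, float]:
        dm = self.spec.trough_offset_nm
        return (-dm, dm)

    def signed_distance(self, xyz_a: np.ndarray) -> np.ndarray:
        return signed_distance(self.spec, np.asarray(xyz_a) / A_PER_NM)

    def normal_at(self, xyz_a: np.ndarray) -> np.ndarray:
        return analytic_normal(self.spec, np.asarray(xyz_a) / A_PER_NM)

    def side_of(self, xyz_a: np.ndarray) -> np.ndarray:
        """1 where the point lies at s > 0 (outer/upper face), else 2."""
        return np.where(self.signed_distance(xyz_a) >= 0, 1, 2)


def _grid_signed_distance(spec: PhantomSpec) -> np.ndarray:
    """Signed distance evaluated at every voxel center, by broadcasting."""
    nz, ny, nx = spec.shape
    v = spec.voxel_size / A_PER_NM
    cx, cy, cz = _center_nm(spec)
    x = np.arange(nx) * v - cx
    y = np.arange(ny) * v - cy
    z = np.arange(nz) * v - cz
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]
    if spec.geometry == "slab":
        n = _slab_normal(spec)
        return n[0] * xx + n[2] * zz + 0.0 * yy
    if spec.geometry == "sphere":
        return np.sqrt(xx**2 + yy**2 + zz**2) - spec.sphere_radius_nm
    if spec.geometry == "tube":
        return np.sqrt(xx**2 + zz**2) + 0.0 * yy - spec.tube_radius_nm
    k = 2 * np.pi / spec.sine_period_nm
    dz = zz - spec.sine_amplitude_nm * np.sin(k * xx) + 0.0 * yy
    slope = spec.sine_amplitude_nm * k * np.cos(k * xx)
    return dz / np.sqrt(1.0 + slope**2)


def _check_fit(spec: PhantomSpec) -> None:
    nz, ny, nx = spec.shape
    v = spec.voxel_size / A_PER_NM
    margin = 2 * v
    half = spec.thickness_nm / 2
    if spec.geometry == "sphere":
        need = spec.sphere_radius_nm + half + margin
        half_extent = min(nx, ny, nz) * v / 2
        if need > half_extent:
            raise DataError(
                f"sphere of outer radius {need:.1f} nm does not fit the "
                f"{spec.shape} grid (half extent {half_extent:.1f} nm)"
            )
    elif spec.geometry == "tube":
        need = spec.tube_radius_nm + half + margin
        half_extent = min(nx, nz) * v / 2
        if need > half_extent:
            raise DataError("tube does not fit the grid with a 2-voxel margin")
    elif spec.geometry == "sine":
        need = spec.sine_amplitude_nm + half + margin
        if need > nz * v / 2:
            raise DataError("sine sheet does not fit the grid with a 2-voxel margin")
    # a slab always fits


def apply_missing_wedge(values: np.ndarray, half_angle_deg: float) -> np.ndarray:
    """Zero Fourier components within ``half_angle_deg`` of the z axis.

    The wedge models a single-tilt acquisition about the y axis: a component
    is lost when its direction in the x-z plane lies closer than the half
    angle to z. The mask is symmetric under k -> -k, so the output stays
    real. The line kx = kz = 0 (sampled at every tilt) is preserved.
    """
    nz, ny, nx = values.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    ang = np.degrees(np.arctan2(np.abs(kx), np.abs(kz)))
    mask = (ang >= half_angle_deg) | ((kx == 0) & (kz == 0))
    mask = np.broadcast_to(mask, (nz, ny, nx))
    return np.real(np.fft.ifftn(np.fft.fftn(values) * mask))


def generate(spec: PhantomSpec) -> tuple[DensityVolume, LabelVolume, PhantomTruth]:
    """Generate the (tomogram, segmentation, truth) triplet for ``spec``.

    Deterministic for a fixed seed, including the noise realization.
    """
    _check_fit(spec)
    s = _grid_signed_distance(spec)
    dm = spec.trough_offset_nm
    st, sc = spec.trough_sigma_nm, spec.core_sigma_nm
    intensity = (
        spec.baseline
        - spec.trough_depth1 * np.exp(-((s + dm) ** 2) / (2 * st**2))
        - spec.trough_depth2 * np.exp(-((s - dm) ** 2) / (2 * st**2))
        + spec.core_height * np.exp(-(s**2) / (2 * sc**2))
    )
    labels = (np.abs(s) <= spec.thickness_nm / 2).astype(np.int32)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, size=intensity.shape)
    if spec.wedge_half_angle is not None:
        intensity = apply_missing_wedge(intensity, spec.wedge_half_angle)
    vol = DensityVolume(intensity.astype(np.float32), spec.voxel_size)
    lab = LabelVolume(labels, spec.voxel_size)
    return vol, lab, PhantomTruth(spec)


PROFILE_KINDS = (
    "clean", "one_minimum", "no_central_max", "minima_outside", "low_prominence",
)


def profile_fixture(
    kind: str = "clean",
    rho: float = 1.0,
    depth: float = 1.0,
    trough_sep_nm: float = 3.8,
    trough_sigma_nm: float = 0.5,
    core_height: float = 0.3,
    core_sigma_nm: float = 0.8,
    spacing_nm: float = 0.261,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> IntensityProfile:
    """Standalone 1D profile with a prescribed feature structure.

    ``kind="clean"`` yields a bilayer profile with minima ``trough_sep_nm``
    apart whose leaflet depth differences relative to the central maximum
    are in ratio ``rho`` = dI1/dI2 exactly (dI2 = ``depth``): the two trough
    amplitudes are solved from a linear system that accounts for the central
    ridge and trough-tail cross-contributions, so the asymmetry score of the
    noise-free profile equals ``rho``. The defect kinds each violate exactly
    one filtering criterion:

    * ``one_minimum`` -- a single trough;
    * ``no_central_max`` -- two equally deep minima whose saddle rises by
      only ~4% of the range (below the 5% default threshold; built
      noise-free by symmetric construction);
    * ``minima_outside`` -- a clean bilayer whose P1/P2 markers span only a
      narrow central window far from the troughs;
    * ``low_prominence`` -- a second trough of 2% relative depth.
    """
    if kind not in PROFILE_KINDS:
        raise ConfigError(f"kind must be one of {PROFILE_KINDS}")
    a = trough_sep_nm / 2
    p_half = a + trough_sigma_nm  # inflection (= P1/P2) position
    half_extent = 1.45 * p_half
    n_half = int(np.ceil(half_extent / spacing_nm))
    x = (np.arange(-n_half, n_half + 1)) * spacing_nm
    n = len(x)

    def trough(center, d, sigma=trough_sigma_nm):
        return -d * np.exp(-((x - center) ** 2) / (2 * sigma**2))

    ridge = core_height * depth * np.exp(-(x**2) / (2 * core_sigma_nm**2))
    if kind == "one_minimum":
        y = trough(0.0, depth)
    elif kind == "no_central_max":
        # two equal troughs 2.3 sigma apart: bimodal, but the saddle rises
        # less than 5% of the range above the (exactly equal) minima
        b = 1.15 * trough_sigma_nm
        y = trough(-b, depth) + trough(b, depth)
    elif kind == "low_prominence":
        y = trough(-a, depth) + trough(a, 0.02 * depth)
    else:  # clean, minima_outside
        # solve trough amplitudes so that the depth differences relative to
        # the central maximum come out as dI1 = rho * depth, dI2 = depth:
        #   dI_i = d_i (1 - t_a) + d_j (t_2a - t_a) + core_height*depth*(1 - r_a)
        t_a = np.exp(-(a**2) / (2 * trough_sigma_nm**2))
        t_2a = np.exp(-((2 * a) ** 2) / (2 * trough_sigma_nm**2))
        r_a = np.exp(-(a**2) / (2 * core_sigma_nm**2))
        kk = core_height * depth * (1 - r_a)
        mat = np.array([[1 - t_a, t_2a - t_a], [t_2a - t_a, 1 - t_a]])
        d1, d2 = np.linalg.solve(mat, [rho * depth - kk, depth - kk])
        if d1 <= 0 or d2 <= 0:
            raise ConfigError(
                f"rho={rho} is unreachable with core_height={core_height}"
            )
        y = trough(-a, d1) + trough(a, d2) + ridge
    if noise_sigma > 0 and kind in ("clean", "minima_outside"):
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=n)

    if kind == "minima_outside":
        w = 0.3 * a
        i1 = int(np.argmin(np.abs(x + w)))
        i2 = int(np.argmin(np.abs(x - w)))
    else:
        i1 = int(np.argmin(np.abs(x + p_half)))
        i2 = int(np.argmin(np.abs(x - p_half)))
    return IntensityProfile(y, spacing_nm, i1, i2)
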