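"""Oriented surface-point reconstruction from one labeled membrane instance.

A voxel instance segmentation is turned into two opposing, oriented boundary
point clouds: marching cubes on the binarized instance provides sub-voxel
boundary vertices, a 26-connectivity boundary test drops vertices that sit on
label-label interfaces rather than true membrane/background boundaries,
normals are smoothed by Gaussian-weighted neighbor averaging, and the two
membrane surfaces are separated by a principal component analysis of the
normal directions (with a distance-transform fallback for closed surfaces,
whose normals span all directions and defeat the PCA rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .exceptions import ConfigError, DataError, DegenerateGeometryError
from .volume_io import LabelVolume

logger = logging.getLogger(__name__)

DEDUP_TOL = 1e-3  # A; marching-cubes vertices on shared edges duplicate exactly


@dataclass
class OrientedPoints:
    """Boundary points with (provisional or refined) unit normals.

    ``positions`` are (N, 3) physical (x, y, z) in A; ``normals`` are unit
    (x, y, z) vectors pointing from the membrane interior toward background.
    """

    positions: np.ndarray
    normals: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SurfacePointSet:
    """Oriented boundary points of one instance with side assignments."""

    positions: np.ndarray
    normals: np.ndarray
    sides: np.ndarray  # (N,) int, 1 or 2
    instance_label: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)

    def side(self, which: int) -> OrientedPoints:
        m = self.sides == which
        return OrientedPoints(self.positions[m], self.normals[m])


def _dedup(positions: np.ndarray, normals: np.ndarray, tol: float = DEDUP_TOL):
    key = np.round(positions / tol).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    idx.sort()
    return positions[idx], normals[idx]


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n[n == 0] = 1.0
    return v / n


def extract_boundary_points(
    labels: LabelVolume,
    instance_label: int,
    position_smoothing: float = 1.0,
    normal_smoothing: float = 2.0,
) -> OrientedPoints:
    """Extract boundary vertices of one instance with outward provisional normals.

    The instance mask is isosurfaced at level 0.5 after a light Gaussian
    anti-aliasing smooth (``position_smoothing`` voxels): for a flat boundary
    the 0.5-level of the smoothed step stays exactly at the segmentation
    boundary mid-plane, while the voxel staircase amplitude drops by an
    order of magnitude. Provisional normals come from the gradient of a more
    heavily smoothed field (``normal_smoothing`` voxels): the staircase of a
    tilted plane has a lateral period of ``1/tan(tilt)`` voxels, which a
    1-voxel kernel cannot average away, so normals need the larger support.
    Normals are oriented from membrane interior toward background (the mask
    decreases outward, so the negated gradient already points that way).

    A vertex is retained only if its nearest voxel either is an instance
    voxel with a background voxel among its 26 neighbors, or is itself
    background -- this removes vertices generated at contacts with *other*
    instances.
    """
    mask = labels.labels == instance_label
    if not mask.any():
        raise KeyError(f"instance label {instance_label} not present in volume")
    span = [int(np.ptp(np.nonzero(mask)[ax])) + 1 for ax in range(3)]
    if min(span) < 2:
        raise DegenerateGeometryError(
            f"instance {instance_label} spans {span} voxels; "
            "needs >= 2 along every axis"
        )
    fmask = mask.astype(np.float32)
    smooth_pos = ndimage.gaussian_filter(fmask, sigma=position_smoothing)
    verts, _faces, _mc_norms, _vals = marching_cubes(smooth_pos, level=0.5)

    smooth_nrm = ndimage.gaussian_filter(fmask, sigma=normal_smoothing)
    grads = np.gradient(smooth_nrm)
    norms = -np.stack(
        [ndimage.map_coordinates(g, verts.T, order=1, mode="nearest") for g in grads],
        axis=1,
    )
    bad = np.linalg.norm(norms, axis=1) < 1e-9
    if bad.any():
        # flat-gradient vertices (rare, e.g. thin protrusions): keep the
        # marching-cubes normal, oriented toward decreasing mask values
        mc = _mc_norms[bad]
        ahead = ndimage.map_coordinates(
            fmask, (verts[bad] + 0.75 * mc).T, order=1, mode="nearest"
        )
        behind = ndimage.map_coordinates(
            fmask, (verts[bad] - 0.75 * mc).T, order=1, mode="nearest"
        )
        norms[bad] = np.where((ahead > behind)[:, None], -mc, mc)
    norms /= np.maximum(np.linalg.norm(norms, axis=1, keepdims=True), 1e-12)

    # retain only vertices at true membrane/background boundaries (26-conn)
    background = labels.labels == 0
    touches_bg = ndimage.binary_dilation(background, structure=np.ones((3, 3, 3)))
    boundary_voxel = mask & touches_bg
    nearest = np.clip(
        np.rint(verts).astype(int), 0, np.array(mask.shape) - 1
    )
    nz, ny, nx = nearest[:, 0], nearest[:, 1], nearest[:, 2]
    keep = boundary_voxel[nz, ny, nx] | background[nz, ny, nx]
    verts, norms = verts[keep], norms[keep]
    if len(verts) == 0:
        raise DegenerateGeometryError(
            f"instance {instance_label} has no membrane/background boundary"
        )

    positions = verts[:, ::-1] * labels.voxel_size + labels.origin
    normals = _normalize(norms[:, ::-1])
    positions, normals = _dedup(positions, normals)
    return OrientedPoints(positions, normals)


def _median_spacing(positions: np.ndarray, tree: cKDTree | None = None) -> float:
    tree = tree or cKDTree(positions)
    d, _ = tree.query(positions, k=2)
    return float(np.median(d[:, 1]))


def interpolate_points(points: OrientedPoints, factor: int) -> OrientedPoints:
    """Densify the point cloud by midpoint insertion along local neighbor edges.

    ``factor`` k inserts midpoints until the median point spacing drops to at
    most 1/k of the original; new points inherit interpolated, re-normalized
    normals. ``factor=1`` is the identity.
    """
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ConfigError(f"interpolation factor must be an integer >= 1, got {factor}")
    positions = points.positions.copy()
    normals = points.normals.copy()
    if factor == 1 or len(positions) < 2:
        return OrientedPoints(positions, normals)
    target = _median_spacing(positions) / factor
    for _ in range(int(np.ceil(np.log2(factor))) + 2):
        tree = cKDTree(positions)
        spacing = _median_spacing(positions, tree)
        if spacing <= target * (1 + 1e-9):
            break
        pairs = tree.query_pairs(r=1.3 * spacing, output_type="ndarray")
        if len(pairs) == 0:
            logger.warning("no neighbor edges found during interpolation; stopping")
            break
        mids = 0.5 * (positions[pairs[:, 0]] + positions[pairs[:, 1]])
        mid_normals = _normalize(normals[pairs[:, 0]] + normals[pairs[:, 1]])
        degenerate = np.linalg.norm(
            normals[pairs[:, 0]] + normals[pairs[:, 1]], axis=1
        ) < 1e-9
        mid_normals[degenerate] = normals[pairs[degenerate, 0]]
        positions = np.vstack([positions, mids])
        normals = np.vstack([normals, mid_normals])
        positions, normals = _dedup(positions, normals)
    return OrientedPoints(positions, normals)


def refine_normals(
    points: OrientedPoints,
    radius: float,
    weighting: str = "gaussian",
    sides: np.ndarray | None = None,
) -> OrientedPoints:
    """Smooth normals by weighted averaging over same-side neighbors.

    Weight is ``exp(-d^2 / (2 sigma^2))`` with ``sigma = radius/2`` (self
    included with weight 1). When explicit ``sides`` are not yet available,
    "same side" is approximated by requiring a positive dot product with the
    query normal, which keeps the two bilayer surfaces from canceling each
    other near rims and on thin instances. The sign of each input normal is
    preserved; isolated points keep their original normal.
    """
    if radius <= 0:
        raise ConfigError(f"smoothing radius must be positive, got {radius}")
    if weighting not in ("gaussian",):
        raise ConfigError(f"unknown weighting {weighting!r}")
    positions, normals = points.positions, points.normals
    n = len(positions)
    sigma = radius / 2.0
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    acc = normals.copy()  # self weight = 1
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        if sides is not None:
            same = sides[i] == sides[j]
        else:
            same = np.einsum("ij,ij->i", normals[i], normals[j]) > 0
        i, j = i[same], j[same]
        d2 = np.sum((positions[i] - positions[j]) ** 2, axis=1)
        w = np.exp(-d2 / (2 * sigma**2))
        np.add.at(acc, i, w[:, None] * normals[j])
        np.add.at(acc, j, w[:, None] * normals[i])
    norms = np.linalg.norm(acc, axis=1)
    degenerate = norms < 1e-12
    if degenerate.any():
        logger.info("%d points kept their original normal (degenerate average)",
                    int(degenerate.sum()))
        acc[degenerate] = normals[degenerate]
    flip = np.einsum("ij,ij->i", acc, normals) < 0
    acc[flip] *= -1.0
    return OrientedPoints(positions, _normalize(acc))


def _distance_transform_sides(
    points: OrientedPoints, labels: LabelVolume, instance_label: int
) -> np.ndarray:
    """Side assignment for closed surfaces via the filled-instance EDT gradient."""
    mask = labels.labels == instance_label
    filled = ndimage.binary_fill_holes(mask)
    dist = ndimage.distance_transform_edt(filled)
    grads = np.gradient(dist)  # (z, y, x) components
    idx = labels.xyz_to_index(points.positions).T  # (3, N) as (z, y, x)
    g = np.stack(
        [ndimage.map_coordinates(c, idx, order=1, mode="nearest") for c in grads],
        axis=1,
    )
    outward = -g[:, ::-1]  # to (x, y, z); EDT grows inward, so outward = -grad
    dot = np.einsum("ij,ij->i", points.normals, outward)
    return np.where(dot >= 0, 1, 2).astype(np.int8)


def separate_surfaces(
    points: OrientedPoints,
    labels: LabelVolume | None = None,
    instance_label: int | None = None,
    eig_ratio_threshold: float = 2.0,
    provenance: dict | None = None,
) -> SurfacePointSet:
    """Assign each point to surface 1 or 2.

    Sheet-like instances: PCA of the normal vectors; side = sign of the
    projection on the first principal axis (projection exactly 0 -> side 1).
    Closed surfaces are auto-detected (normal covariance nearly isotropic,
    lambda1/lambda3 < ``eig_ratio_threshold``) and routed to the
    distance-transform fallback, which requires ``labels``.
    """
    if len(points) < 10:
        raise DegenerateGeometryError(
            f"need >= 10 points to separate surfaces, got {len(points)}"
        )
    normals = points.normals
    cov = normals.T @ normals / len(normals)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    ratio = eigvals[0] / max(eigvals[2], 1e-12)
    use_fallback = ratio < eig_ratio_threshold
    if use_fallback:
        if labels is None or instance_label is None:
            raise DegenerateGeometryError(
                "normal distribution is nearly isotropic (closed surface); "
                "side separation needs the label volume for the "
                "distance-transform fallback"
            )
        sides = _distance_transform_sides(points, labels, instance_label)
        method = "distance_transform"
    else:
        proj = normals @ eigvecs[:, 0]
        n_zero = int(np.sum(proj == 0))
        if n_zero:
            logger.info("%d normals project to exactly 0; assigned to side 1", n_zero)
        sides = np.where(proj >= 0, 1, 2).astype(np.int8)
        method = "pca"
    if (sides == 1).sum() == 0 or (sides == 2).sum() == 0:
        if method == "pca" and labels is not None and instance_label is not None:
            sides = _distance_transform_sides(points, labels, instance_label)
            method = "distance_transform"
        if (sides == 1).sum() == 0 or (sides == 2).sum() == 0:
            raise DegenerateGeometryError(
                "one surface side is empty (all normals alike); "
                "instance is not a measurable membrane"
            )
    prov = dict(provenance or {})
    prov["separation_method"] = method
    return SurfacePointSet(
        points.positions, points.normals, sides,
        instance_label=int(instance_label or 0), provenance=prov,
    )


def reconstruct_surface(
    labels: LabelVolume,
    instance_label: int,
    interpolation_factor: int = 1,
    smoothing_radius: float | None = None,
) -> SurfacePointSet:
    """Convenience wrapper: extract -> interpolate -> refine -> separate.

    ``smoothing_radius`` defaults to 3 voxel widths.
    """
    if smoothing_radius is None:
        smoothing_radius = 3.0 * float(np.mean(labels.voxel_size))
    pts = extract_boundary_points(labels, instance_label)
    pts = interpolate_points(pts, interpolation_factor)
    pts = refine_normals(pts, radius=smoothing_radius)
    return separate_surfaces(
        pts, labels, instance_label,
        provenance={
            "iso_level": 0.5,
            "interpolation_factor": interpolation_factor,
            "smoothing_radius": smoothing_radius,
        },
    )


def surface_frame(sps: SurfacePointSet):
    """Per-instance surface table: point id, side, position (A), normal."""
    import pandas as pd

    return pd.DataFrame(
        {
            "point_id": np.arange(len(sps)),
            "side": sps.sides,
            "x": sps.positions[:, 0],
            "y": sps.positions[:, 1],
            "z": sps.positions[:, 2],
            "nx": sps.normals[:, 0],
            "ny": sps.normals[:, 1],
            "nz": sps.normals[:, 2],
        }
    )


def write_surface_csv(sps: SurfacePointSet, path) -> None:
    surface_frame(sps).to_csv(path, index=False, float_format="%.4f")
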