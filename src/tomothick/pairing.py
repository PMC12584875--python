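"""Normal-guided cone search and greedy one-to-one point pairing.

Each query point on surface 1 projects a ray along its (refined) normal; a
cone search collects opposite-surface candidates that lie within the cone
half-angle of that ray and closer than the distance cutoff. All candidate
triples are pooled globally, sorted by distance with a total (distance,
query id, target id) tie-break, and traversed once greedily, so the result
is independent of input ordering and of how queries were chunked across
workers. Thickness is the Euclidean distance between the paired points, in
nm; the orientation angle theta = arccos(|n . z|) measures each measurement
against the missing-wedge (beam) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .exceptions import ConfigError, UndefinedStatisticError
from .surface import OrientedPoints, SurfacePointSet
from .volume_io import A_PER_NM

REASON_NO_CANDIDATE = "no_candidate"


@dataclass
class PairingParams:
    cone_half_angle: float = 1.0  # degrees
    max_distance: float = 8.0  # nm
    candidates_per_query: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.cone_half_angle < 90:
            raise ConfigError(
                f"cone_half_angle must be in (0, 90) degrees, got {self.cone_half_angle}"
            )
        if self.max_distance <= 0:
            raise ConfigError(f"max_distance must be positive, got {self.max_distance}")
        if self.candidates_per_query < 1:
            raise ConfigError("candidates_per_query must be >= 1")


@dataclass
class PointPairs:
    """One row per query point; unmatched queries carry a rejection reason."""

    q_index: np.ndarray  # indices into the side-1 point list
    t_index: np.ndarray  # indices into the side-2 point list; -1 if unmatched
    p1: np.ndarray  # (N, 3) A
    p2: np.ndarray  # (N, 3) A; NaN rows for unmatched
    n1: np.ndarray
    n2: np.ndarray
    thickness_nm: np.ndarray
    theta_deg: np.ndarray
    valid: np.ndarray
    rejection_reason: np.ndarray  # object dtype, "" when none
    instance_label: int = 0
    sides: tuple[int, int] = (1, 2)
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.q_index)

    @property
    def matched(self) -> np.ndarray:
        return self.t_index >= 0

    def midpoints(self) -> np.ndarray:
        """Pair midpoints in A (NaN for unmatched queries)."""
        return 0.5 * (self.p1 + self.p2)


def _candidate_triples(
    qpos: np.ndarray,
    qnorm: np.ndarray,
    tree: cKDTree,
    opp_pos: np.ndarray,
    params: PairingParams,
):
    """Vectorized cone search; returns (query_idx, target_idx, distance_A)."""
    if len(qpos) == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    r = params.max_distance * A_PER_NM
    cos_thr = np.cos(np.deg2rad(params.cone_half_angle))
    lists = tree.query_ball_point(qpos, r=r)
    counts = np.fromiter((len(l) for l in lists), dtype=int, count=len(lists))
    if counts.sum() == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    qi = np.repeat(np.arange(len(qpos)), counts)
    ti = np.concatenate([l for l in lists if l]).astype(int)
    delta = opp_pos[ti] - qpos[qi]
    d = np.linalg.norm(delta, axis=1)
    ok = d > 1e-9
    # cone about the normal *line*: surface normals are oriented toward the
    # background, so the opposite surface lies along -n; |cos| accepts both.
    cosang = np.abs(np.einsum("ij,ij->i", qnorm[qi], delta))
    cosang = np.divide(cosang, d, out=np.zeros_like(d), where=ok)
    ok &= cosang >= cos_thr - 1e-12
    qi, ti, d = qi[ok], ti[ok], d[ok]
    # per-query top-k by distance, deterministic index tie-break
    order = np.lexsort((ti, d, qi))
    qi, ti, d = qi[order], ti[order], d[order]
    if len(qi):
        group_start = np.r_[0, np.flatnonzero(np.diff(qi)) + 1]
        rank = np.arange(len(qi)) - np.repeat(group_start, np.diff(np.r_[group_start, len(qi)]))
        keep = rank < params.candidates_per_query
        qi, ti, d = qi[keep], ti[keep], d[keep]
    return qi, ti, d


def find_candidates(
    query_position: np.ndarray,
    query_normal: np.ndarray,
    opposite_positions: np.ndarray,
    params: PairingParams,
) -> list[tuple[int, float]]:
    """Ranked candidates for one query point.

    Returns up to ``candidates_per_query`` (opposite index, distance in nm)
    tuples satisfying both the cone and distance constraints, sorted
    ascending by distance (ties broken by index). An empty list is allowed.
    """
    opp = np.atleast_2d(np.asarray(opposite_positions, dtype=float))
    if len(opp) == 0:
        raise ConfigError("opposite point set is empty")
    tree = cKDTree(opp)
    qi, ti, d = _candidate_triples(
        np.atleast_2d(np.asarray(query_position, dtype=float)),
        np.atleast_2d(np.asarray(query_normal, dtype=float)),
        tree, opp, params,
    )
    return [(int(t), float(dist) / A_PER_NM) for t, dist in zip(ti, d)]


def compute_theta(normals: np.ndarray) -> np.ndarray:
    """Orientation angle vs the missing-wedge (z) axis, in [0, 90] degrees.

    theta = arccos(|n . z|) with n the unit membrane normal; the absolute
    value makes the angle independent of the normal's sign.
    """
    n = np.atleast_2d(np.asarray(normals, dtype=float))
    nz = np.abs(n[:, 2]) / np.linalg.norm(n, axis=1)
    return np.degrees(np.arccos(np.clip(nz, -1.0, 1.0)))


def greedy_pair(
    queries: OrientedPoints,
    opposite: OrientedPoints,
    params: PairingParams | None = None,
    n_chunks: int = 1,
    instance_label: int = 0,
) -> PointPairs:
    """Pool candidates globally, sort by distance, and pair greedily one-to-one.

    Once paired, both endpoints are excluded from further consideration.
    The global sort uses the total order (distance, query id, target id), so
    the output is identical for any ``n_chunks`` decomposition.
    """
    params = params or PairingParams()
    if len(queries) == 0 or len(opposite) == 0:
        raise ConfigError("both sides must be non-empty for pairing")
    tree = cKDTree(opposite.positions)
    chunks = np.array_split(np.arange(len(queries)), max(1, n_chunks))
    qis, tis, ds = [], [], []
    for chunk in chunks:
        if len(chunk) == 0:
            continue
        qi, ti, d = _candidate_triples(
            queries.positions[chunk], queries.normals[chunk], tree,
            opposite.positions, params,
        )
        qis.append(qi + chunk[0])
        tis.append(ti)
        ds.append(d)
    qi = np.concatenate(qis) if qis else np.empty(0, int)
    ti = np.concatenate(tis) if tis else np.empty(0, int)
    d = np.concatenate(ds) if ds else np.empty(0)

    order = np.lexsort((ti, qi, d))
    used_q = np.zeros(len(queries), dtype=bool)
    used_t = np.zeros(len(opposite), dtype=bool)
    match = np.full(len(queries), -1, dtype=int)
    for k in order:
        a, b = qi[k], ti[k]
        if not used_q[a] and not used_t[b]:
            used_q[a] = used_t[b] = True
            match[a] = b

    n = len(queries)
    matched = match >= 0
    p1 = queries.positions.copy()
    n1 = queries.normals.copy()
    p2 = np.full((n, 3), np.nan)
    n2 = np.full((n, 3), np.nan)
    p2[matched] = opposite.positions[match[matched]]
    n2[matched] = opposite.normals[match[matched]]
    thickness = np.full(n, np.nan)
    thickness[matched] = (
        np.linalg.norm(p2[matched] - p1[matched], axis=1) / A_PER_NM
    )
    reasons = np.array(
        [("" if m else REASON_NO_CANDIDATE) for m in matched], dtype=object
    )
    return PointPairs(
        q_index=np.arange(n),
        t_index=match,
        p1=p1, p2=p2, n1=n1, n2=n2,
        thickness_nm=thickness,
        theta_deg=compute_theta(n1),
        valid=matched.copy(),
        rejection_reason=reasons,
        instance_label=instance_label,
    )


def pair_surfaces(
    sps: SurfacePointSet,
    params: PairingParams | None = None,
    n_chunks: int = 1,
    symmetric: bool = False,
) -> PointPairs:
    """Pair side-1 queries against side-2 targets for one instance.

    ``symmetric=True`` additionally runs the reverse direction and appends
    reverse-only valid pairs (deduplicated on unordered endpoint identity).
    """
    side1, side2 = sps.side(1), sps.side(2)
    fwd = greedy_pair(side1, side2, params, n_chunks, sps.instance_label)
    if not symmetric:
        return fwd
    rev = greedy_pair(side2, side1, params, n_chunks, sps.instance_label)
    seen = {
        (int(q), int(t))
        for q, t in zip(fwd.q_index[fwd.matched], fwd.t_index[fwd.matched])
    }
    keep = [
        i for i in np.flatnonzero(rev.matched)
        if (int(rev.t_index[i]), int(rev.q_index[i])) not in seen
    ]
    if not keep:
        return fwd
    keep = np.asarray(keep)
    return PointPairs(
        q_index=np.r_[fwd.q_index, rev.t_index[keep]],
        t_index=np.r_[fwd.t_index, rev.q_index[keep]],
        p1=np.vstack([fwd.p1, rev.p2[keep]]),
        p2=np.vstack([fwd.p2, rev.p1[keep]]),
        n1=np.vstack([fwd.n1, rev.n2[keep]]),
        n2=np.vstack([fwd.n2, rev.n1[keep]]),
        thickness_nm=np.r_[fwd.thickness_nm, rev.thickness_nm[keep]],
        theta_deg=np.r_[fwd.theta_deg, compute_theta(rev.n2[keep])],
        valid=np.r_[fwd.valid, rev.valid[keep]],
        rejection_reason=np.r_[fwd.rejection_reason, rev.rejection_reason[keep]],
        instance_label=sps.instance_label,
    )


def orientation_bias(pairs: PointPairs) -> float:
    """Pearson correlation between theta and thickness over valid pairs.

    Near-zero values indicate the absence of missing-wedge orientation bias.
    """
    m = pairs.valid & np.isfinite(pairs.thickness_nm)
    theta, thick = pairs.theta_deg[m], pairs.thickness_nm[m]
    if len(theta) < 3:
        raise UndefinedStatisticError("need >= 3 valid pairs for a correlation")
    if np.ptp(theta) == 0 or np.ptp(thick) == 0:
        raise UndefinedStatisticError(
            "correlation undefined: zero variance in theta or thickness"
        )
    r, _p = stats.pearsonr(theta, thick)
    return float(r)
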