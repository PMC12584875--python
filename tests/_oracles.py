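"""Independent reference implementations used as test oracles."""

import numpy as np

from tomothick.surface import OrientedPoints
from tomothick.volume_io import A_PER_NM


def brute_force_pairs(queries, opposite, params):
    """Single-threaded O(N^2) reference: cone+distance scan, global greedy."""
    triples = []
    cos_thr = np.cos(np.deg2rad(params.cone_half_angle))
    for qi in range(len(queries)):
        cands = []
        for ti in range(len(opposite)):
            delta = opposite.positions[ti] - queries.positions[qi]
            d = np.linalg.norm(delta)
            if d <= 1e-9 or d > params.max_distance * A_PER_NM:
                continue
            if abs(np.dot(queries.normals[qi], delta)) / d < cos_thr - 1e-12:
                continue
            cands.append((d, ti))
        cands.sort()
        triples.extend((d, qi, ti) for d, ti in cands[: params.candidates_per_query])
    triples.sort()
    used_q, used_t = set(), set()
    match = np.full(len(queries), -1, dtype=int)
    for d, qi, ti in triples:
        if qi not in used_q and ti not in used_t:
            used_q.add(qi)
            used_t.add(ti)
            match[qi] = ti
    return match


def random_cloud(seed, n=200, spread=60.0):
    """Two roughly parallel random point layers with near-axial normals."""
    rng = np.random.default_rng(seed)
    q_pos = rng.uniform(0, spread, size=(n, 3))
    q_pos[:, 2] = rng.uniform(0, 5, size=n)
    t_pos = rng.uniform(0, spread, size=(n, 3))
    t_pos[:, 2] = rng.uniform(30, 55, size=n)
    nrm = rng.normal(size=(n, 3)) * np.array([0.2, 0.2, 1.0])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return OrientedPoints(q_pos, nrm), OrientedPoints(t_pos, nrm.copy())
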