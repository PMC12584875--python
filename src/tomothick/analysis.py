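"""Pipeline orchestration, per-instance summaries, group statistics and
colocalization.

`run_pipeline` executes surface reconstruction -> pairing -> profile
filtering -> summaries for every instance in a segmentation and writes the
standard output artifacts (surface CSVs, measurements CSV, profile tables,
summaries CSV, thickness map) into one directory, together with an echo of
the configuration. Outputs are deterministic for a fixed configuration at
any parallel chunking degree.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.spatial import cKDTree

from . import profiles as prof
from . import surface as surf
from .exceptions import ConfigError, DataError, UndefinedStatisticError
from .pairing import PairingParams, PointPairs, orientation_bias, pair_surfaces
from .volume_io import (
    A_PER_NM,
    DensityVolume,
    LabelVolume,
    ParticleTable,
    measurements_frame,
    write_measurements,
)

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "instance_label", "n_pairs_total", "n_pairs_valid",
    "mean_nm", "median_nm", "sd_nm", "iqr_nm",
    "mean_theta_deg", "pearson_r_theta_thickness",
]


@dataclass
class RunConfig:
    """All pipeline parameters; serialized verbatim into the output directory."""

    tomogram: str = ""
    labels: str = ""
    out_dir: str = "tomothick_out"
    instances: list[int] | None = None  # None = all positive labels
    interpolation_factor: int = 1
    smoothing_radius: float | None = None  # A; default 3 voxel widths
    pairing: PairingParams = field(default_factory=PairingParams)
    profile: prof.ProfileParams = field(default_factory=prof.ProfileParams)
    n_chunks: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "pairing" in d and isinstance(d["pairing"], dict):
            d["pairing"] = PairingParams(**d["pairing"])
        if "profile" in d and isinstance(d["profile"], dict):
            d["profile"] = prof.ProfileParams(**d["profile"])
        return cls(**d)


def summarize_instance(pairs: PointPairs) -> dict:
    """Per-instance statistics over valid pairs only."""
    m = pairs.valid & np.isfinite(pairs.thickness_nm)
    t = pairs.thickness_nm[m]
    theta = pairs.theta_deg[m]
    try:
        r = orientation_bias(pairs)
    except UndefinedStatisticError:
        r = np.nan
    q75, q25 = (np.percentile(t, [75, 25]) if len(t) else (np.nan, np.nan))
    return {
        "instance_label": pairs.instance_label,
        "n_pairs_total": int(len(pairs)),
        "n_pairs_valid": int(m.sum()),
        "mean_nm": float(t.mean()) if len(t) else np.nan,
        "median_nm": float(np.median(t)) if len(t) else np.nan,
        "sd_nm": float(t.std(ddof=1)) if len(t) > 1 else np.nan,
        "iqr_nm": float(q75 - q25),
        "mean_theta_deg": float(theta.mean()) if len(theta) else np.nan,
        "pearson_r_theta_thickness": r,
    }


def profiles_frame(result: prof.FilterResult) -> pd.DataFrame:
    """Long-format table of all extracted profiles, keyed by pair id."""
    rows = []
    for i, p in result.profiles.items():
        rows.append(
            pd.DataFrame(
                {
                    "pair_id": i,
                    "sample_idx": np.arange(len(p)),
                    "value": p.samples,
                    "spacing_nm": p.spacing,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["pair_id", "sample_idx", "value", "spacing_nm"])
    return pd.concat(rows, ignore_index=True)


def features_frame(result: prof.FilterResult) -> pd.DataFrame:
    cols = [
        "pair_id", "m1_idx", "m2_idx", "m1_value", "m2_value",
        "c_idx", "c_value", "prominence1", "prominence2", "dI1", "dI2",
    ]
    rows = [
        {
            "pair_id": i, "m1_idx": f.m1_idx, "m2_idx": f.m2_idx,
            "m1_value": f.m1_value, "m2_value": f.m2_value,
            "c_idx": f.c_idx, "c_value": f.c_value,
            "prominence1": f.prominence1, "prominence2": f.prominence2,
            "dI1": f.dI1, "dI2": f.dI2,
        }
        for i, f in result.features.items()
    ]
    return pd.DataFrame(rows, columns=cols)


def thickness_map(pairs_list: list[PointPairs]) -> pd.DataFrame:
    """Per-point local thickness field: pair midpoints (A) with thickness (nm)."""
    rows = []
    for pairs in pairs_list:
        m = pairs.valid & np.isfinite(pairs.thickness_nm)
        if not m.any():
            continue
        mid = pairs.midpoints()[m]
        rows.append(
            pd.DataFrame(
                {
                    "instance_label": pairs.instance_label,
                    "x": mid[:, 0], "y": mid[:, 1], "z": mid[:, 2],
                    "thickness_nm": pairs.thickness_nm[m],
                }
            )
        )
    if not rows:
        logger.warning("no valid pairs; thickness map is empty")
        return pd.DataFrame(columns=["instance_label", "x", "y", "z", "thickness_nm"])
    return pd.concat(rows, ignore_index=True)


def thickness_label_volume(
    map_df: pd.DataFrame, labels: LabelVolume, radius_voxels: float = 2.0
) -> DensityVolume:
    """Re-paint boundary voxels with the mean thickness of nearby pairs.

    For external renderers: every labeled voxel within ``radius_voxels`` of a
    pair midpoint carries the mean thickness (nm) of those midpoints; other
    voxels are 0.
    """
    out = np.zeros(labels.shape, dtype=np.float32)
    if len(map_df) == 0:
        logger.warning("empty thickness map; label repaint is all zero")
        return DensityVolume(out, labels.voxel_size, labels.origin)
    mids = map_df[["x", "y", "z"]].to_numpy(dtype=float)
    thick = map_df["thickness_nm"].to_numpy(dtype=float)
    vox = np.argwhere(labels.labels > 0)  # (M, 3) z, y, x
    pos = labels.index_to_xyz(vox)
    tree = cKDTree(mids)
    r = radius_voxels * float(np.mean(labels.voxel_size))
    lists = tree.query_ball_point(pos, r=r)
    for (z, y, x), hits in zip(vox, lists):
        if hits:
            out[z, y, x] = thick[hits].mean()
    return DensityVolume(out, labels.voxel_size, labels.origin)


def colocalize(
    pairs_list: list[PointPairs] | pd.DataFrame,
    particles: ParticleTable,
    radius_nm: float,
) -> pd.DataFrame:
    """Nearest-measurement association for each particle.

    Returns one row per particle with the nearest pair midpoint within
    ``radius_nm`` (Euclidean, in physical coordinates), its local thickness
    and the distance; unmatched particles are flagged.
    """
    map_df = (
        pairs_list if isinstance(pairs_list, pd.DataFrame)
        else thickness_map(pairs_list)
    )
    n = len(particles)
    out = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "matched": np.zeros(n, dtype=bool),
            "distance_nm": np.full(n, np.nan),
            "thickness_nm": np.full(n, np.nan),
            "pair_x": np.full(n, np.nan),
            "pair_y": np.full(n, np.nan),
            "pair_z": np.full(n, np.nan),
        }
    )
    if len(map_df) == 0 or n == 0:
        return out
    mids = map_df[["x", "y", "z"]].to_numpy(dtype=float)
    tree = cKDTree(mids)
    d, idx = tree.query(particles.positions)
    d_nm = d / A_PER_NM
    hit = d_nm <= radius_nm
    out.loc[hit, "matched"] = True
    out.loc[hit, "distance_nm"] = d_nm[hit]
    out.loc[hit, "thickness_nm"] = map_df["thickness_nm"].to_numpy()[idx[hit]]
    out.loc[hit, ["pair_x", "pair_y", "pair_z"]] = mids[idx[hit]]
    return out


def significance_stars(p: float) -> str:
    """ns: P > 0.05; *: P < 0.05; **: P < 0.01; ***: P < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    means_a: np.ndarray, means_b: np.ndarray, paired: bool = False
) -> dict:
    """Two-sided t test on instance-level mean thicknesses.

    Paired tests require aligned instances of equal count. Zero-variance
    paired differences are handled explicitly: all-zero differences give
    t = 0, p = 1; constant nonzero shifts give p = 0 and are flagged
    degenerate.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("need >= 2 instances per group for a t test")
    degenerate = False
    if paired:
        if len(a) != len(b):
            raise DataError("paired test requires equal, aligned group sizes")
        diff = a - b
        if np.ptp(diff) == 0:
            degenerate = True
            if diff[0] == 0:
                t, p = 0.0, 1.0
            else:
                t, p = np.sign(diff[0]) * np.inf, 0.0
            logger.warning("paired differences have zero variance; degenerate t test")
        else:
            t, p = stats.ttest_rel(a, b)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t, p, degenerate = 0.0, 1.0, True
        else:
            t, p = stats.ttest_ind(a, b)
    return {
        "t": float(t), "p": float(p),
        "stars": significance_stars(float(p)),
        "paired": paired, "n_a": len(a), "n_b": len(b),
        "degenerate": degenerate,
    }


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; raw values are the default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def pairs_from_measurements(df: pd.DataFrame, instance_label: int) -> PointPairs:
    """Reconstruct a pair set from a measurements table (one instance)."""
    sub = df[df["instance_label"] == instance_label].reset_index(drop=True)
    n = len(sub)
    get3 = lambda pre: sub[[f"{pre}_x", f"{pre}_y", f"{pre}_z"]].to_numpy(dtype=float)
    reasons = np.array(
        ["" if (isinstance(r, float) and np.isnan(r)) or r == "" else str(r)
         for r in sub["rejection_reason"].fillna("")],
        dtype=object,
    )
    t_index = np.where(np.isfinite(sub["thickness_nm"].to_numpy(dtype=float)),
                       np.arange(n), -1)
    return PointPairs(
        q_index=np.arange(n),
        t_index=t_index,
        p1=get3("p1"), p2=get3("p2"), n1=get3("n1"), n2=get3("n2"),
        thickness_nm=sub["thickness_nm"].to_numpy(dtype=float),
        theta_deg=sub["theta_deg"].to_numpy(dtype=float),
        valid=sub["valid"].to_numpy(dtype=bool),
        rejection_reason=reasons,
        instance_label=instance_label,
    )


def run_pipeline(
    config: RunConfig,
    tomogram: DensityVolume | None = None,
    labels: LabelVolume | None = None,
) -> Path:
    """Run surface -> pairing -> filtering -> summaries for every instance.

    Volumes may be passed in-memory (phantoms) or read from the configured
    paths. Writes all artifacts into ``config.out_dir`` and returns it.
    """
    from .volume_io import read_volume

    if tomogram is None:
        tomogram = read_volume(config.tomogram, kind="density")
    if labels is None:
        labels = read_volume(config.labels, kind="label")
    if tomogram.shape != labels.shape:
        raise ConfigError(
            f"tomogram grid {tomogram.shape} != label grid {labels.shape}"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(config.to_yaml())

    instance_list = config.instances or list(labels.instances)
    all_measurements = []
    all_profiles = []
    all_features = []
    summaries = []
    pairs_list = []
    for label in instance_list:
        try:
            sps = surf.reconstruct_surface(
                labels, int(label),
                interpolation_factor=config.interpolation_factor,
                smoothing_radius=config.smoothing_radius,
            )
        except (KeyError, DataError) as exc:
            logger.info("skipping instance %s: %s", label, exc)
            continue
        surf.write_surface_csv(sps, out_dir / f"surface_{label}.csv")
        logger.info(
            "instance %s: %d surface points (side1 %d / side2 %d)",
            label, len(sps), int((sps.sides == 1).sum()), int((sps.sides == 2).sum()),
        )
        pairs = pair_surfaces(sps, config.pairing, n_chunks=config.n_chunks)
        logger.info(
            "instance %s: %d/%d queries paired", label,
            int(pairs.matched.sum()), len(pairs),
        )
        result = prof.filter_pairs(pairs, tomogram, config.profile)
        logger.info(
            "instance %s: %d pairs retained after filtering", label,
            int(pairs.valid.sum()),
        )
        mdf = measurements_frame(pairs)
        mdf.insert(0, "pair_id", np.arange(len(mdf)))
        all_measurements.append(mdf)
        pdf = profiles_frame(result)
        pdf.insert(0, "instance_label", label)
        all_profiles.append(pdf)
        fdf = features_frame(result)
        fdf.insert(0, "instance_label", label)
        all_features.append(fdf)
        summaries.append(summarize_instance(pairs))
        pairs_list.append(pairs)

    if all_measurements:
        meas = pd.concat(all_measurements, ignore_index=True)
    else:
        meas = pd.DataFrame()
    write_measurements_all(meas, out_dir / "measurements.csv")
    pd.concat(all_profiles, ignore_index=True).to_csv(
        out_dir / "profiles.csv", index=False
    ) if all_profiles else None
    pd.concat(all_features, ignore_index=True).to_csv(
        out_dir / "features.csv", index=False
    ) if all_features else None
    pd.DataFrame(summaries, columns=SUMMARY_COLUMNS).to_csv(
        out_dir / "summaries.csv", index=False, float_format="%.4f"
    )
    tmap = thickness_map(pairs_list)
    tmap.to_csv(out_dir / "thickness_map.csv", index=False, float_format="%.3f")
    return out_dir


def write_measurements_all(df: pd.DataFrame, path: Path) -> None:
    if len(df) == 0:
        pd.DataFrame(columns=["pair_id"] + list(df.columns)).to_csv(path, index=False)
        return
    write_measurements(df, path)
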