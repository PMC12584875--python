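"""Per-pair intensity profiles, bilayer feature detection and quality filtering.

For each point pair the tomogram is sampled by trilinear interpolation along
the P1->P2 axis, extended outward by a fraction of the pair separation. A
trans-membrane profile of a resolvable bilayer shows two minima (the
electron-dense phosphate headgroup layers, dark in cryo-ET contrast)
separated by a central maximum (the hydrophobic core). Measurements whose
profile lacks this signature are rejected with an enumerated reason:

``one_minimum``
    fewer than two local minima exist at all;
``low_prominence``
    fewer than two minima rise above the prominence threshold (a fraction of
    the profile's dynamic range);
``no_central_max``
    the saddle between the two chosen minima does not rise above the higher
    minimum by the same threshold;
``minima_outside``
    a minimum falls outside the window [P1 - ext, P2 + ext];
``edge``
    the extended sampling segment leaves the tomogram.

The checks are applied in that order, so each rejection names the first
violated criterion. The same feature detector drives the leaflet-asymmetry
score a = max(dI1, dI2) / min(dI1, dI2) >= 1 computed on thickness-binned
mean profiles, reported as percent asymmetry (a - 1) * 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences, savgol_filter

from .exceptions import ConfigError, DataError, TomothickError, UndefinedStatisticError
from .pairing import PointPairs
from .volume_io import A_PER_NM, DensityVolume

logger = logging.getLogger(__name__)

REASON_ONE_MINIMUM = "one_minimum"
REASON_LOW_PROMINENCE = "low_prominence"
REASON_NO_CENTRAL_MAX = "no_central_max"
REASON_MINIMA_OUTSIDE = "minima_outside"
REASON_EDGE = "edge"


class ProfileEdgeError(DataError):
    """The extended sampling segment exits the tomogram."""


@dataclass
class ProfileParams:
    extension_fraction: float = 0.30  # outward extension as fraction of |P2 - P1|
    samples_per_voxel: int = 3
    prominence_min: float = 0.05  # fraction of the profile's dynamic range
    invert_contrast: bool = False  # True when dense structures are bright

    def __post_init__(self) -> None:
        if self.extension_fraction < 0:
            raise ConfigError("extension_fraction must be >= 0")
        if self.samples_per_voxel < 1:
            raise ConfigError("samples_per_voxel must be >= 1")
        if not 0 < self.prominence_min < 1:
            raise ConfigError("prominence_min must be in (0, 1)")


@dataclass
class IntensityProfile:
    """1D samples along a pair's axis; idx_P1/idx_P2 mark the endpoints."""

    samples: np.ndarray
    spacing: float  # nm per sample
    idx_P1: int
    idx_P2: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.idx_P1 < self.idx_P2:
            raise DataError("idx_P1 must be < idx_P2")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ProfileFeatures:
    """Detected bilayer features, in the headgroups-as-minima representation."""

    m1_idx: int
    m2_idx: int
    m1_value: float
    m2_value: float
    c_idx: int
    c_value: float
    prominence1: float
    prominence2: float
    ambiguous_third: bool = False  # a 3rd minimum within 80% of the 2nd's prominence

    accepted = True

    @property
    def dI1(self) -> float:
        return abs(self.c_value - self.m1_value)

    @property
    def dI2(self) -> float:
        return abs(self.c_value - self.m2_value)


@dataclass
class Rejection:
    reason: str
    accepted = False


def extract_profile(
    tomogram: DensityVolume,
    p1: np.ndarray,
    p2: np.ndarray,
    params: ProfileParams | None = None,
) -> IntensityProfile:
    """Sample the tomogram along P1->P2, extended outward on both ends.

    Sample spacing is ``voxel_size / samples_per_voxel``; interpolation is
    trilinear. Raises :class:`ProfileEdgeError` when the extended segment
    leaves the volume.
    """
    params = params or ProfileParams()
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    sep = p2 - p1
    length = float(np.linalg.norm(sep))
    if length <= 0:
        raise DataError("pair endpoints coincide")
    u = sep / length
    ext = params.extension_fraction * length
    spacing_a = float(np.mean(tomogram.voxel_size)) / params.samples_per_voxel
    n = int(np.floor((length + 2 * ext) / spacing_a)) + 1
    start = p1 - ext * u
    xyz = start + np.arange(n)[:, None] * spacing_a * u
    idx = tomogram.xyz_to_index(xyz)  # (n, 3) as (z, y, x)
    dims = np.array(tomogram.shape, dtype=float)
    if np.any(idx < 0) or np.any(idx > dims - 1):
        raise ProfileEdgeError("extended profile segment exits the tomogram")
    from scipy.ndimage import map_coordinates

    samples = map_coordinates(tomogram.values.astype(float), idx.T, order=1)
    idx_p1 = int(round(ext / spacing_a))
    idx_p2 = min(int(round((ext + length) / spacing_a)), n - 1)
    return IntensityProfile(samples, spacing_a / A_PER_NM, idx_p1, idx_p2)


def detect_features(
    profile: IntensityProfile, params: ProfileParams | None = None
) -> ProfileFeatures | Rejection:
    """Detect the two headgroup minima and the central maximum, or reject.

    See the module docstring for the rejection taxonomy and check order.
    """
    params = params or ProfileParams()
    y = np.asarray(profile.samples, dtype=float)
    if len(y) < 7:
        raise DataError(f"profile has {len(y)} samples; need >= 7")
    if params.invert_contrast:
        y = -y
    rng = float(np.ptp(y))
    inv = -y
    minima, _ = find_peaks(inv)
    if len(minima) < 2:
        return Rejection(REASON_ONE_MINIMUM)
    prom = peak_prominences(inv, minima)[0]
    thr = params.prominence_min * rng
    ok = prom >= thr
    if ok.sum() < 2:
        return Rejection(REASON_LOW_PROMINENCE)
    cand, cprom = minima[ok], prom[ok]
    order = np.lexsort((cand, -cprom))
    pick = np.sort(cand[order[:2]])
    m1, m2 = int(pick[0]), int(pick[1])
    ambiguous = len(cand) >= 3 and cprom[order[2]] >= 0.8 * cprom[order[1]]
    if ambiguous:
        logger.debug(
            "profile has a 3rd minimum within 80%% of the 2nd's prominence; "
            "keeping the two most prominent"
        )
    between = y[m1 + 1 : m2]
    if len(between) == 0:
        return Rejection(REASON_NO_CENTRAL_MAX)
    c = m1 + 1 + int(np.argmax(between))
    if y[c] - max(y[m1], y[m2]) < thr:
        return Rejection(REASON_NO_CENTRAL_MAX)
    ext_samples = int(round(params.extension_fraction * (profile.idx_P2 - profile.idx_P1)))
    lo = profile.idx_P1 - ext_samples
    hi = profile.idx_P2 + ext_samples
    if m1 < lo or m2 > hi:
        return Rejection(REASON_MINIMA_OUTSIDE)
    i1 = int(np.flatnonzero(cand == m1)[0])
    i2 = int(np.flatnonzero(cand == m2)[0])
    return ProfileFeatures(
        m1_idx=m1, m2_idx=m2,
        m1_value=float(y[m1]), m2_value=float(y[m2]),
        c_idx=c, c_value=float(y[c]),
        prominence1=float(cprom[i1]), prominence2=float(cprom[i2]),
        ambiguous_third=bool(ambiguous),
    )


def minima_distance(features: ProfileFeatures, profile: IntensityProfile) -> float:
    """Minima-to-minima distance in nm (the alternative thickness readout)."""
    if not getattr(features, "accepted", False):
        raise TomothickError("minima_distance requires accepted features")
    return (features.m2_idx - features.m1_idx) * profile.spacing


def _resample(profile: IntensityProfile, m: int) -> np.ndarray:
    x = np.linspace(0.0, 1.0, len(profile.samples))
    return np.interp(np.linspace(0.0, 1.0, m), x, profile.samples)


def mean_profile(profiles: list[IntensityProfile]) -> IntensityProfile:
    """Average profiles of (nearly) identical geometry on a common grid."""
    if not profiles:
        raise DataError("cannot average zero profiles")
    m = int(np.median([len(p) for p in profiles]))
    m = max(m, 7)
    stack = np.stack([_resample(p, m) for p in profiles])
    lengths = [(len(p) - 1) * p.spacing for p in profiles]
    spacing = float(np.mean(lengths)) / (m - 1)
    f1 = np.mean([p.idx_P1 / (len(p) - 1) for p in profiles])
    f2 = np.mean([p.idx_P2 / (len(p) - 1) for p in profiles])
    return IntensityProfile(
        stack.mean(axis=0), spacing,
        int(round(f1 * (m - 1))), int(round(f2 * (m - 1))),
    )


@dataclass
class FilterResult:
    """Outcome of profile-based filtering over one pair set."""

    pairs: PointPairs
    profiles: dict[int, IntensityProfile]
    features: dict[int, ProfileFeatures]
    bin_table: pd.DataFrame  # per-thickness-bin before/after counts
    mean_all: IntensityProfile | None = None
    mean_accepted: IntensityProfile | None = None
    sd_all: np.ndarray | None = None
    sd_accepted: np.ndarray | None = None


def filter_pairs(
    pairs: PointPairs,
    tomogram: DensityVolume,
    params: ProfileParams | None = None,
    bin_width_nm: float = 1.0,
) -> FilterResult:
    """Extract and screen one profile per matched pair; update validity flags.

    Thickness values are never altered, only the ``valid`` flags and
    rejection reasons. Returns per-bin before/after tallies and the mean
    (+/- sd) profiles of all vs accepted measurements.
    """
    params = params or ProfileParams()
    profiles: dict[int, IntensityProfile] = {}
    features: dict[int, ProfileFeatures] = {}
    for i in np.flatnonzero(pairs.matched):
        try:
            prof = extract_profile(tomogram, pairs.p1[i], pairs.p2[i], params)
        except ProfileEdgeError:
            pairs.valid[i] = False
            pairs.rejection_reason[i] = REASON_EDGE
            continue
        profiles[int(i)] = prof
        res = detect_features(prof, params)
        if res.accepted:
            pairs.valid[i] = True
            features[int(i)] = res
        else:
            pairs.valid[i] = False
            pairs.rejection_reason[i] = res.reason

    thick = pairs.thickness_nm
    matched = pairs.matched & np.isfinite(thick)
    rows = []
    if matched.any():
        lo = np.floor(thick[matched].min() / bin_width_nm) * bin_width_nm
        hi = thick[matched].max()
        edges = np.arange(lo, hi + bin_width_nm, bin_width_nm)
        for a in edges:
            b = a + bin_width_nm
            in_bin = matched & (thick >= a) & (thick < b)
            if in_bin.any():
                rows.append(
                    {
                        "bin_lo_nm": a,
                        "bin_hi_nm": b,
                        "n_before": int(in_bin.sum()),
                        "n_after": int((in_bin & pairs.valid).sum()),
                    }
                )
    bin_table = pd.DataFrame(rows, columns=["bin_lo_nm", "bin_hi_nm", "n_before", "n_after"])

    mean_all = mean_acc = None
    sd_all = sd_acc = None
    all_profiles = list(profiles.values())
    acc_profiles = [profiles[i] for i in features]
    if all_profiles:
        mean_all = mean_profile(all_profiles)
        stack = np.stack([_resample(p, len(mean_all)) for p in all_profiles])
        sd_all = stack.std(axis=0)
    if acc_profiles:
        mean_acc = mean_profile(acc_profiles)
        stack = np.stack([_resample(p, len(mean_acc)) for p in acc_profiles])
        sd_acc = stack.std(axis=0)
    return FilterResult(pairs, profiles, features, bin_table,
                        mean_all, mean_acc, sd_all, sd_acc)


def asymmetry_score(dI1: float, dI2: float) -> float:
    """Larger-over-smaller leaflet depth ratio; always >= 1."""
    lo, hi = sorted([abs(dI1), abs(dI2)])
    if lo == 0:
        raise UndefinedStatisticError("asymmetry undefined: one leaflet depth is 0")
    return hi / lo


def score_to_percent(score: float) -> float:
    """Percent asymmetry: (score - 1) * 100; 1.0 -> 0%, 1.05 -> 5%."""
    return (score - 1.0) * 100.0


def _parabolic_value(y: np.ndarray, i: int) -> float:
    """Extremum value refined by a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(y[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(y[i])
    return float(y[i] - (y[i + 1] - y[i - 1]) ** 2 / (8 * denom))


def profile_asymmetry(
    profile: IntensityProfile,
    params: ProfileParams | None = None,
    refine: bool = False,
) -> tuple[float, float]:
    """(score, percent asymmetry) of one (typically bin-averaged) profile.

    With ``refine=True`` the extremum values are read from local parabolic
    fits instead of the raw samples, which suppresses residual noise on
    averaged profiles.
    """
    res = detect_features(profile, params)
    if not res.accepted:
        raise DataError(f"profile rejected by feature detection: {res.reason}")
    if refine:
        yw = -profile.samples if (params and params.invert_contrast) else profile.samples
        c = _parabolic_value(yw, res.c_idx)
        v1 = _parabolic_value(yw, res.m1_idx)
        v2 = _parabolic_value(yw, res.m2_idx)
        a = asymmetry_score(abs(c - v1), abs(c - v2))
    else:
        a = asymmetry_score(res.dI1, res.dI2)
    return a, score_to_percent(a)


@dataclass
class AsymmetryBin:
    lo: float  # nm
    hi: float  # nm
    n_profiles: int
    mean: IntensityProfile
    score: float
    percent: float
    features: ProfileFeatures


def asymmetry_analysis(
    thicknesses_nm: np.ndarray,
    profiles: list[IntensityProfile],
    bin_width: float = 0.1,
    min_bin_count: int = 20,
    params: ProfileParams | None = None,
    smooth: bool = True,
) -> list[AsymmetryBin]:
    """Thickness-binned leaflet asymmetry from accepted profiles.

    Profiles are grouped into ``bin_width`` nm thickness bins; bins below
    ``min_bin_count`` are omitted. Features are computed on each bin's mean
    profile (after an optional light Savitzky-Golay smooth, with parabolic
    refinement of the extremum values) and the score is the larger/smaller
    depth-difference ratio. Bins whose smaller depth difference is exactly 0
    are flagged undefined and excluded with a warning.
    """
    thicknesses_nm = np.asarray(thicknesses_nm, dtype=float)
    if len(thicknesses_nm) != len(profiles):
        raise DataError("thicknesses and profiles must align")
    out: list[AsymmetryBin] = []
    if len(profiles) == 0:
        return out
    keys = np.floor(thicknesses_nm / bin_width).astype(int)
    for key in np.unique(keys):
        idx = np.flatnonzero(keys == key)
        if len(idx) < min_bin_count:
            continue
        mp = mean_profile([profiles[i] for i in idx])
        samples = mp.samples
        if smooth and len(samples) >= 7:
            samples = savgol_filter(samples, window_length=5, polyorder=2)
        smp = IntensityProfile(samples, mp.spacing, mp.idx_P1, mp.idx_P2)
        res = detect_features(smp, params)
        if not res.accepted:
            logger.warning(
                "asymmetry bin [%.2f, %.2f) nm rejected by feature detection (%s)",
                key * bin_width, (key + 1) * bin_width, res.reason,
            )
            continue
        yw = -samples if (params and params.invert_contrast) else samples
        c = _parabolic_value(yw, res.c_idx)
        v1 = _parabolic_value(yw, res.m1_idx)
        v2 = _parabolic_value(yw, res.m2_idx)
        d1, d2 = abs(c - v1), abs(c - v2)
        if min(d1, d2) == 0:
            logger.warning(
                "asymmetry bin [%.2f, %.2f) nm undefined (zero leaflet depth); excluded",
                key * bin_width, (key + 1) * bin_width,
            )
            continue
        a = asymmetry_score(d1, d2)
        out.append(
            AsymmetryBin(
                lo=key * bin_width, hi=(key + 1) * bin_width,
                n_profiles=len(idx), mean=smp,
                score=a, percent=score_to_percent(a), features=res,
            )
        )
    return out


def asymmetry_table(bins: list[AsymmetryBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bin_lo_nm": b.lo, "bin_hi_nm": b.hi, "n_profiles": b.n_profiles,
                "score": b.score, "percent": b.percent,
            }
            for b in bins
        ],
        columns=["bin_lo_nm", "bin_hi_nm", "n_profiles", "score", "percent"],
    )


def leaflet_context(
    pairs: PointPairs,
    pair_index: int,
    features: ProfileFeatures,
    profile: IntensityProfile,
    compartment_names: dict[int, str] | None = None,
) -> dict[str, str]:
    """Tag each headgroup minimum with the compartment it adjoins.

    The minimum whose profile position projects nearer to P1 adjoins the
    query surface (side 1 by default); the other adjoins side 2. User-chosen
    compartment names propagate through ``compartment_names``.
    """
    names = compartment_names or {1: "side1", 2: "side2"}
    s_query, s_target = pairs.sides
    m1_near_p1 = abs(features.m1_idx - profile.idx_P1) <= abs(
        features.m1_idx - profile.idx_P2
    )
    if m1_near_p1:
        return {"m1": names[s_query], "m2": names[s_target]}
    return {"m1": names[s_target], "m2": names[s_query]}
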