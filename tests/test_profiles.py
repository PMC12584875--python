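"""Profile extraction, feature detection, filtering and asymmetry scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomothick import phantom, profiles
from tomothick.exceptions import DataError, TomothickError
from tomothick.profiles import IntensityProfile, ProfileParams
from tomothick.volume_io import DensityVolume


def w_profile(values=(1.0, 0.2, -2.0, 0.0, -2.0, 0.2, 1.0), spacing=0.25,
              i1=1, i2=5):
    return IntensityProfile(np.asarray(values, float), spacing, i1, i2)


class TestExtractProfile:
    def test_uniform_volume_constant_samples(self):
        vol = DensityVolume(np.ones((20, 20, 20)), 7.84)
        p = profiles.extract_profile(vol, [40.0, 40, 40], [40.0, 40, 110])
        np.testing.assert_allclose(p.samples, 1.0)
        assert p.idx_P1 < p.idx_P2

    def test_analytic_bilayer_trough_positions(self, slab_phantom):
        vol, _lab, truth = slab_phantom
        spec = truth.spec
        # sample through the slab along the analytic normal at grid center
        center = (np.array(vol.shape[::-1]) - 1) / 2 * spec.voxel_size
        n = truth.normal_at(center[None, :])[0]
        half = spec.thickness_nm / 2 * 10
        p1 = center - half * n
        p2 = center + half * n
        prof = profiles.extract_profile(vol, p1, p2)
        res = profiles.detect_features(prof)
        assert res.accepted
        mid = (prof.idx_P1 + prof.idx_P2) / 2
        pos1 = (res.m1_idx - mid) * prof.spacing
        pos2 = (res.m2_idx - mid) * prof.spacing
        dm = spec.trough_offset_nm
        assert pos1 == pytest.approx(-dm, abs=prof.spacing)
        assert pos2 == pytest.approx(dm, abs=prof.spacing)

    def test_extension_crossing_face_rejected(self):
        vol = DensityVolume(np.ones((10, 10, 10)), 7.84)
        with pytest.raises(profiles.ProfileEdgeError):
            profiles.extract_profile(vol, [40.0, 40, 4.0], [40.0, 40, 60.0])


class TestDetectFeatures:
    def test_w_shape_accepted(self):
        res = profiles.detect_features(w_profile())
        assert res.accepted
        assert res.m1_idx == 2 and res.m2_idx == 4 and res.c_idx == 3

    def test_v_shape_rejected_one_minimum(self):
        p = IntensityProfile([1.0, 0.5, 0.0, -2.0, 0.0, 0.5, 1.0], 0.25, 1, 5)
        res = profiles.detect_features(p)
        assert not res.accepted
        assert res.reason == profiles.REASON_ONE_MINIMUM

    def test_prominence_threshold_controls_acceptance(self):
        # second trough depth 1% of range: rejected at 5%, accepted at 0.5%
        y = [0.0, 0.0, -2.0, 0.0, -0.02, 0.0, 0.0]
        p = IntensityProfile(y, 0.25, 1, 5)
        res = profiles.detect_features(p, ProfileParams(prominence_min=0.05))
        assert res.reason == profiles.REASON_LOW_PROMINENCE
        res = profiles.detect_features(p, ProfileParams(prominence_min=0.005))
        assert res.accepted

    def test_contrast_inversion_duality(self):
        p = w_profile()
        inverted = IntensityProfile(-p.samples, p.spacing, p.idx_P1, p.idx_P2)
        a = profiles.detect_features(p, ProfileParams(invert_contrast=False))
        b = profiles.detect_features(inverted, ProfileParams(invert_contrast=True))
        assert a.accepted and b.accepted
        assert (a.m1_idx, a.m2_idx, a.c_idx) == (b.m1_idx, b.m2_idx, b.c_idx)
        assert a.dI1 == pytest.approx(b.dI1)

    @pytest.mark.parametrize("kind", phantom.PROFILE_KINDS[1:])
    def test_each_defect_kind_gets_its_reason(self, kind):
        res = profiles.detect_features(phantom.profile_fixture(kind))
        assert not res.accepted
        assert res.reason == kind

    def test_short_profile_precondition(self):
        with pytest.raises(DataError):
            profiles.detect_features(IntensityProfile([0, 1, 0, 1, 0], 0.1, 1, 3))


class TestMinimaDistance:
    def test_arithmetic(self):
        prof = phantom.profile_fixture("clean")
        res = profiles.detect_features(prof)
        res.m1_idx, res.m2_idx = 6, 18
        assert profiles.minima_distance(res, IntensityProfile(
            np.zeros(25), 0.261, 2, 22)) == pytest.approx(12 * 0.261)

    def test_analytic_bilayer_separation(self):
        prof = phantom.profile_fixture("clean", trough_sep_nm=3.8)
        res = profiles.detect_features(prof)
        assert res.accepted
        d = profiles.minima_distance(res, prof)
        assert d == pytest.approx(3.8, abs=prof.spacing)

    def test_rejected_profile_contract_error(self):
        rej = profiles.detect_features(phantom.profile_fixture("one_minimum"))
        with pytest.raises(TomothickError):
            profiles.minima_distance(rej, phantom.profile_fixture("clean"))

    def test_at_most_boundary_to_boundary_for_interior_minima(self):
        prof = phantom.profile_fixture("clean")
        res = profiles.detect_features(prof)
        boundary = (prof.idx_P2 - prof.idx_P1) * prof.spacing
        assert profiles.minima_distance(res, prof) <= boundary


class TestFilterPairs:
    def _phantom_pairs(self, noise=0.0, seed=0):
        from tomothick import pairing, surface

        spec = phantom.PhantomSpec(
            geometry="slab", shape=(40, 48, 48), noise_sigma=noise, seed=seed
        )
        vol, lab, _ = phantom.generate(spec)
        sps = surface.reconstruct_surface(lab, 1)
        pairs = pairing.pair_surfaces(sps)
        return pairs, vol

    def test_clean_phantom_full_retention(self):
        pairs, vol = self._phantom_pairs()
        result = profiles.filter_pairs(pairs, vol)
        m = pairs.matched & (pairs.rejection_reason != profiles.REASON_EDGE)
        assert m.sum() > 100
        assert pairs.valid[m].all()
        assert result.bin_table["n_after"].sum() >= 100

    def test_filtering_preserves_thickness_values(self):
        pairs, vol = self._phantom_pairs(noise=0.3, seed=5)
        before = pairs.thickness_nm.copy()
        profiles.filter_pairs(pairs, vol)
        np.testing.assert_array_equal(pairs.thickness_nm, before)

    def test_empty_pair_list_empty_tallies(self):
        from tomothick.pairing import PointPairs

        empty = PointPairs(
            q_index=np.empty(0, int), t_index=np.empty(0, int),
            p1=np.empty((0, 3)), p2=np.empty((0, 3)),
            n1=np.empty((0, 3)), n2=np.empty((0, 3)),
            thickness_nm=np.empty(0), theta_deg=np.empty(0),
            valid=np.empty(0, bool), rejection_reason=np.empty(0, object),
        )
        vol = DensityVolume(np.ones((8, 8, 8)), 7.84)
        result = profiles.filter_pairs(empty, vol)
        assert len(result.bin_table) == 0
        assert result.profiles == {}


class TestAsymmetry:
    def test_equal_depths_score_one(self):
        p = w_profile((1.0, 0.2, -2.0, 0.0, -2.0, 0.2, 1.0))
        score, percent = profiles.profile_asymmetry(p)
        assert score == 1.0
        assert percent == 0.0

    def test_depths_21_20_score_105(self):
        p = w_profile((1.0, 0.2, -2.1, 0.0, -2.0, 0.2, 1.0))
        score, percent = profiles.profile_asymmetry(p)
        assert score == pytest.approx(1.05)
        assert percent == pytest.approx(5.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        gain=st.floats(0.1, 10.0),
        offset=st.floats(-5.0, 5.0),
        d1=st.floats(1.0, 3.0),
        d2=st.floats(1.0, 3.0),
    )
    def test_affine_invariance(self, gain, offset, d1, d2):
        base = np.array([1.0, 0.2, -d1, 0.0, -d2, 0.2, 1.0])
        p = IntensityProfile(base, 0.25, 1, 5)
        q = IntensityProfile(gain * base + offset, 0.25, 1, 5)
        try:
            s1, _ = profiles.profile_asymmetry(p)
        except DataError:
            return  # degenerate shape for these draws; nothing to compare
        s2, _ = profiles.profile_asymmetry(q)
        assert s1 >= 1.0
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_small_bins_omitted(self):
        profs = [phantom.profile_fixture("clean") for _ in range(19)]
        bins = profiles.asymmetry_analysis(
            np.full(19, 5.0), profs, min_bin_count=20
        )
        assert bins == []

    def test_binning_by_thickness(self):
        profs = [phantom.profile_fixture("clean") for _ in range(50)]
        th = np.r_[np.full(25, 5.02), np.full(25, 5.18)]
        bins = profiles.asymmetry_analysis(th, profs, bin_width=0.1, min_bin_count=20)
        np.testing.assert_allclose(
            [(b.lo, b.hi) for b in bins], [(5.0, 5.1), (5.1, 5.2)], atol=1e-9
        )
        assert all(b.n_profiles == 25 for b in bins)

    def test_recovers_construction_ratio_noise_free(self):
        for rho in (1.0, 1.05, 1.2):
            profs = [phantom.profile_fixture("clean", rho=rho)] * 25
            bins = profiles.asymmetry_analysis(np.full(25, 5.0), profs,
                                               min_bin_count=20)
            assert bins[0].score == pytest.approx(rho, rel=0.005)


class TestLeafletContext:
    def _pairs(self):
        from tomothick.pairing import PointPairs

        return PointPairs(
            q_index=np.array([0]), t_index=np.array([0]),
            p1=np.zeros((1, 3)), p2=np.zeros((1, 3)),
            n1=np.zeros((1, 3)), n2=np.zeros((1, 3)),
            thickness_nm=np.array([5.0]), theta_deg=np.array([0.0]),
            valid=np.array([True]),
            rejection_reason=np.array([""], dtype=object),
        )

    def test_m1_tagged_by_nearer_side(self):
        prof = phantom.profile_fixture("clean")
        feat = profiles.detect_features(prof)
        tags = profiles.leaflet_context(
            self._pairs(), 0, feat, prof, {1: "lumen", 2: "cytosol"}
        )
        assert tags == {"m1": "lumen", "m2": "cytosol"}

    def test_swapping_names_swaps_tags(self):
        prof = phantom.profile_fixture("clean")
        feat = profiles.detect_features(prof)
        a = profiles.leaflet_context(
            self._pairs(), 0, feat, prof, {1: "lumen", 2: "cytosol"}
        )
        b = profiles.leaflet_context(
            self._pairs(), 0, feat, prof, {1: "cytosol", 2: "lumen"}
        )
        assert a["m1"] == b["m2"] and a["m2"] == b["m1"]
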