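"""Pipeline orchestration, summaries, colocalization and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tomothick import analysis, phantom, volume_io
from tomothick.exceptions import ConfigError, DataError
from tomothick.volume_io import DensityVolume, LabelVolume, ParticleTable


def two_slab_volume(thick1=4.0, thick2=6.0, voxel=7.84, tilt_deg=10.0):
    """Two parallel tilted slabs (labels 1 and 2) of different thickness."""
    nz, ny, nx = 56, 40, 40
    v = voxel / 10
    th = np.deg2rad(tilt_deg)
    z = (np.arange(nz) * v)[:, None, None] * np.ones((1, ny, nx))
    x = (np.arange(nx) * v)[None, None, :] * np.ones((nz, ny, 1))
    u = z * np.cos(th) + x * np.sin(th)  # coordinate along the slab normal
    c1, c2 = 12 * v, 40 * v
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    labels[np.abs(u - c1) <= thick1 / 2] = 1
    labels[np.abs(u - c2) <= thick2 / 2] = 2
    dm1, dm2 = thick1 / 2 - 0.5, thick2 / 2 - 0.5
    intensity = (
        -np.exp(-((u - c1 - dm1) ** 2) / 0.5) - np.exp(-((u - c1 + dm1) ** 2) / 0.5)
        - np.exp(-((u - c2 - dm2) ** 2) / 0.5) - np.exp(-((u - c2 + dm2) ** 2) / 0.5)
        + 0.3 * np.exp(-((u - c1) ** 2) / 1.28) + 0.3 * np.exp(-((u - c2) ** 2) / 1.28)
    )
    return DensityVolume(intensity.astype(np.float32), voxel), LabelVolume(labels, voxel)


@pytest.fixture(scope="module")
def slab_run(tmp_path_factory, slab_phantom):
    vol, lab, truth = slab_phantom
    out = tmp_path_factory.mktemp("run")
    cfg = analysis.RunConfig(out_dir=str(out / "a"))
    analysis.run_pipeline(cfg, tomogram=vol, labels=lab)
    return out / "a", truth


class TestRunPipeline:
    def test_artifacts_exist_and_mean_matches_truth(self, slab_run):
        out, truth = slab_run
        for name in ("config.yaml", "surface_1.csv", "measurements.csv",
                     "profiles.csv", "features.csv", "summaries.csv",
                     "thickness_map.csv"):
            assert (out / name).exists()
        s = pd.read_csv(out / "summaries.csv")
        assert len(s) == 1
        assert s.loc[0, "mean_nm"] == pytest.approx(truth.thickness_nm, abs=0.392)

    def test_rerun_is_byte_identical(self, slab_run, slab_phantom, tmp_path):
        out, _ = slab_run
        vol, lab, _ = slab_phantom
        cfg = analysis.RunConfig(out_dir=str(tmp_path / "b"))
        analysis.run_pipeline(cfg, tomogram=vol, labels=lab)
        for name in ("measurements.csv", "summaries.csv", "thickness_map.csv"):
            assert (tmp_path / "b" / name).read_bytes() == (out / name).read_bytes()

    def test_chunked_run_identical(self, slab_run, slab_phantom, tmp_path):
        out, _ = slab_run
        vol, lab, _ = slab_phantom
        cfg = analysis.RunConfig(out_dir=str(tmp_path / "c"), n_chunks=4)
        analysis.run_pipeline(cfg, tomogram=vol, labels=lab)
        assert (tmp_path / "c" / "measurements.csv").read_bytes() == (
            out / "measurements.csv"
        ).read_bytes()

    def test_summary_mean_consistent_with_measurement_rows(self, slab_run):
        out, _ = slab_run
        meas = volume_io.read_measurements(out / "measurements.csv")
        s = pd.read_csv(out / "summaries.csv")
        valid = meas[meas["valid"]]
        assert s.loc[0, "mean_nm"] == pytest.approx(
            valid["thickness_nm"].mean(), abs=1e-3
        )

    def test_two_instances_two_summary_rows(self, tmp_path):
        vol, lab = two_slab_volume()
        cfg = analysis.RunConfig(out_dir=str(tmp_path / "two"))
        analysis.run_pipeline(cfg, tomogram=vol, labels=lab)
        s = pd.read_csv(tmp_path / "two" / "summaries.csv")
        assert s["instance_label"].tolist() == [1, 2]

    def test_grid_mismatch_config_error(self, tmp_path):
        vol = DensityVolume(np.zeros((8, 8, 8)), 7.84)
        lab = LabelVolume(np.zeros((8, 8, 9), dtype=int), 7.84)
        with pytest.raises(ConfigError, match="grid"):
            analysis.run_pipeline(
                analysis.RunConfig(out_dir=str(tmp_path / "x")), vol, lab
            )

    def test_config_yaml_round_trip(self):
        cfg = analysis.RunConfig(n_chunks=3)
        cfg.pairing.cone_half_angle = 2.5
        back = analysis.RunConfig.from_yaml(cfg.to_yaml())
        assert back.n_chunks == 3
        assert back.pairing.cone_half_angle == 2.5


class TestThicknessMap:
    def test_uniform_slab_map_is_uniform(self, slab_run):
        out, truth = slab_run
        tmap = pd.read_csv(out / "thickness_map.csv")
        assert len(tmap) > 100
        assert tmap["thickness_nm"].std() < 0.25
        assert tmap["thickness_nm"].mean() == pytest.approx(
            truth.thickness_nm, abs=0.392
        )

    def test_two_slab_map_is_bimodal_by_instance(self, tmp_path):
        vol, lab = two_slab_volume()
        cfg = analysis.RunConfig(out_dir=str(tmp_path / "two"))
        analysis.run_pipeline(cfg, tomogram=vol, labels=lab)
        tmap = pd.read_csv(tmp_path / "two" / "thickness_map.csv")
        m1 = tmap[tmap["instance_label"] == 1]["thickness_nm"].mean()
        m2 = tmap[tmap["instance_label"] == 2]["thickness_nm"].mean()
        assert m1 == pytest.approx(4.0, abs=0.5)
        assert m2 == pytest.approx(6.0, abs=0.5)

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = analysis.thickness_map([])
        assert len(out) == 0

    def test_label_repaint_carries_local_mean(self, slab_run, slab_phantom):
        out, truth = slab_run
        _vol, lab, _ = slab_phantom
        tmap = pd.read_csv(out / "thickness_map.csv")
        painted = analysis.thickness_label_volume(tmap, lab)
        vals = painted.values[painted.values > 0]
        assert len(vals) > 0
        assert vals.mean() == pytest.approx(truth.thickness_nm, abs=0.392)


class TestColocalize:
    def _map(self):
        rng = np.random.default_rng(0)
        mids = rng.uniform(0, 400, size=(200, 3))
        return pd.DataFrame(
            {"x": mids[:, 0], "y": mids[:, 1], "z": mids[:, 2],
             "thickness_nm": rng.uniform(4, 6, 200)}
        )

    def test_particle_at_midpoint_distance_zero(self):
        map_df = self._map()
        particles = ParticleTable(
            pd.DataFrame([map_df.iloc[0][["x", "y", "z"]].to_dict()])
        )
        out = analysis.colocalize(map_df, particles, radius_nm=5.0)
        assert out.loc[0, "matched"]
        assert out.loc[0, "distance_nm"] == 0.0
        assert out.loc[0, "thickness_nm"] == map_df.loc[0, "thickness_nm"]

    def test_particle_beyond_radius_unmatched(self):
        map_df = self._map()
        particles = ParticleTable(pd.DataFrame({"x": [9999.0], "y": [0], "z": [0]}))
        out = analysis.colocalize(map_df, particles, radius_nm=5.0)
        assert not out.loc[0, "matched"]

    def test_matches_brute_force_oracle(self):
        map_df = self._map()
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 400, size=(50, 3))
        particles = ParticleTable(pd.DataFrame(pts, columns=["x", "y", "z"]))
        out = analysis.colocalize(map_df, particles, radius_nm=10.0)
        mids = map_df[["x", "y", "z"]].to_numpy()
        for i in range(50):
            d = np.linalg.norm(mids - pts[i], axis=1) / 10.0
            j = int(np.argmin(d))
            if d[j] <= 10.0:
                assert out.loc[i, "matched"]
                assert out.loc[i, "distance_nm"] == pytest.approx(d[j])
                assert out.loc[i, "thickness_nm"] == map_df.loc[j, "thickness_nm"]
            else:
                assert not out.loc[i, "matched"]


class TestCompareGroups:
    def test_identical_groups_null(self):
        res = analysis.compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["stars"] == "ns"

    def test_paired_constant_shift_degenerate(self):
        res = analysis.compare_groups([5.0, 5.1, 5.2], [6.0, 6.1, 6.2], paired=True)
        assert res["degenerate"]
        assert res["p"] == 0.0

    def test_sample_size_guard(self):
        with pytest.raises(DataError):
            analysis.compare_groups([5.0], [5.0, 5.1])

    def test_rejection_rate_near_analytic_power(self):
        # unpaired t, n=10/group, N(5.0, 0.2) vs N(5.4, 0.2):
        # noncentral-t power oracle at alpha = 0.05
        n, delta, sd, alpha = 10, 0.4, 0.2, 0.05
        ncp = delta / (sd * np.sqrt(2 / n))
        df = 2 * n - 2
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        power = 1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        rng = np.random.default_rng(12)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            a = rng.normal(5.0, sd, n)
            b = rng.normal(5.4, sd, n)
            hits += analysis.compare_groups(a, b)["p"] < alpha
        assert hits / n_sim == pytest.approx(power, abs=0.04)

    def test_star_convention(self):
        assert analysis.significance_stars(0.2) == "ns"
        assert analysis.significance_stars(0.04) == "*"
        assert analysis.significance_stars(0.009) == "**"
        assert analysis.significance_stars(0.0009) == "***"

    def test_holm_correction_monotone_and_bounded(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        adj = analysis.holm_correction(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        # smallest raw p gets the largest multiplier
        assert adj[3] == pytest.approx(0.02)


class TestMeasurementsRoundTrip:
    def test_pairs_reconstructed_from_csv(self, slab_run):
        out, _ = slab_run
        df = volume_io.read_measurements(out / "measurements.csv")
        pairs = analysis.pairs_from_measurements(df, 1)
        assert len(pairs) == len(df)
        assert pairs.valid.sum() == df["valid"].sum()
        summary = analysis.summarize_instance(pairs)
        s = pd.read_csv(out / "summaries.csv")
        assert summary["mean_nm"] == pytest.approx(s.loc[0, "mean_nm"], abs=1e-3)
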