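"""Synthetic cohort generator: folding, planted microstructure, DWI
forward model, determinism and analytic calibration."""

import json

import numpy as np
import pytest

from fetalfold.cohort import (
    FoldMode,
    FoldSpec,
    GridSpec,
    base_fraction,
    calibrate_noise_sd,
    default_fold_spec,
    fold_surface,
    future_depth,
    make_cohort,
    matched_noise_sd,
    patch_depth_sd,
    plant_microstructure,
    plant_vertex_metrics,
    planted_rho,
    simulate_cohort,
    synth_dwi,
)
from fetalfold.decomposition import DEFAULT_SCHEME, FractionMaps, \
    default_fluid_response
from fetalfold.surface import MeshError, icosphere, sulcal_depth


def narrow_spec(amplitude=6.0, width=0.04):
    mesh = icosphere(5)
    center = tuple(mesh.vertices[123])
    return FoldSpec(modes=(FoldMode(center=center, width_rad=width,
                                    amplitude_mm=amplitude, onset_ga=29.0,
                                    rate=1.0),), radius_mm=30.0)


class TestFoldSurface:
    def test_young_brain_is_unfolded(self, ico4):
        spec = default_fold_spec()
        mesh = fold_surface(ico4, spec, ga=20.0)  # far below all onsets
        radii = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(radii - spec.radius_mm).max() < 0.05
        assert sulcal_depth(mesh).values.max() < 0.05

    def test_old_pit_depth_approaches_amplitude(self):
        template = icosphere(5)
        spec = narrow_spec(amplitude=6.0)
        mesh = fold_surface(template, spec, ga=60.0)  # growth saturated
        depth = sulcal_depth(mesh)
        assert abs(depth.values[123] - 6.0) < 0.10 * 6.0

    def test_disjoint_modes_superpose(self, ico4):
        m1 = FoldMode(center=(1.0, 0, 0), width_rad=0.15, amplitude_mm=5.0,
                      onset_ga=28.0)
        m2 = FoldMode(center=(-1.0, 0, 0), width_rad=0.15, amplitude_mm=4.0,
                      onset_ga=28.0)
        r = 30.0
        single1 = fold_surface(ico4, FoldSpec((m1,), r), 36.0)
        single2 = fold_surface(ico4, FoldSpec((m2,), r), 36.0)
        both = fold_surface(ico4, FoldSpec((m1, m2), r), 36.0)
        d1 = r - np.linalg.norm(single1.vertices, axis=1)
        d2 = r - np.linalg.norm(single2.vertices, axis=1)
        dboth = r - np.linalg.norm(both.vertices, axis=1)
        np.testing.assert_allclose(dboth, d1 + d2, atol=1e-9)

    def test_excessive_displacement_rejected(self, ico4):
        spec = FoldSpec((FoldMode(center=(0, 0, 1.0), width_rad=0.3,
                                  amplitude_mm=40.0, onset_ga=24.0),),
                        radius_mm=30.0)
        with pytest.raises(MeshError):
            fold_surface(ico4, spec, ga=60.0)


class TestPlantMicrostructure:
    def test_zero_beta_zero_noise_constant_shells(self, ico3):
        # without coupling or noise the volume holds exactly three levels:
        # SP base, CP base and the fluid-dominated exterior
        spec = FoldSpec(default_fold_spec().modes, radius_mm=20.0)
        ga = 30.0
        grid = GridSpec(voxel_size_mm=2.0)
        fm = plant_microstructure(ico3, spec, ga=ga, beta=0.0, noise_sd=0.0,
                                  grid=grid, seed=0)
        levels = np.unique(fm.tissue)
        np.testing.assert_allclose(
            levels, sorted([0.05, base_fraction(ga, "sp"),
                            base_fraction(ga, "cp")]), atol=1e-12)
        # both shells non-empty and distinct
        assert (fm.tissue == base_fraction(ga, "sp")).sum() > 100
        assert (fm.tissue == base_fraction(ga, "cp")).sum() > 100

    def test_coupling_offset_between_pit_and_crown(self):
        template = icosphere(4)
        spec = FoldSpec((FoldMode(center=(0, 0, 1.0), width_rad=0.3,
                                  amplitude_mm=10.0, onset_ga=26.0,
                                  rate=2.0),), radius_mm=20.0)
        beta = -0.02
        grid = GridSpec(voxel_size_mm=1.5)
        fm = plant_microstructure(template, spec, ga=36.0, beta=beta,
                                  noise_sd=0.0, grid=grid, seed=1)
        dfut = future_depth(template, spec)
        mesh = fold_surface(template, spec, 36.0)
        from fetalfold.surface import vertex_normals

        normals = vertex_normals(mesh)
        inv = np.linalg.inv(fm.affine)
        pit = int(np.argmax(dfut.values))
        crown = int(np.argmin(dfut.values))
        vals = {}
        for v in (pit, crown):
            p = mesh.vertices[v] + 1.0 * normals[v]
            ijk = np.round(inv[:3, :3] @ p + inv[:3, 3]).astype(int)
            vals[v] = fm.tissue[tuple(ijk)]
        expected = beta * (dfut.values[pit] - dfut.values[crown])
        # nearest-vertex painting quantises the depth lookup; allow slack
        assert abs((vals[pit] - vals[crown]) - expected) < 0.25 * abs(expected)

    def test_unit_sum_and_determinism(self, ico3):
        spec = FoldSpec(default_fold_spec().modes, radius_mm=20.0)
        grid = GridSpec(voxel_size_mm=2.0)
        fm1 = plant_microstructure(ico3, spec, 30.0, -0.02, 0.02, grid, seed=5)
        fm2 = plant_microstructure(ico3, spec, 30.0, -0.02, 0.02, grid, seed=5)
        np.testing.assert_array_equal(fm1.tissue, fm2.tissue)
        np.testing.assert_allclose(fm1.tissue + fm1.fluid, 1.0, atol=1e-12)


class TestSynthDwi:
    def test_volume_count_follows_scheme(self):
        fm = FractionMaps(np.full((2, 2, 2), 0.5), np.full((2, 2, 2), 0.5),
                          np.eye(4))
        dwi = synth_dwi(fm, snr=None)
        assert dwi.shape == (2, 2, 2, 141)

    def test_pure_fluid_decays_as_fluid_response(self):
        fm = FractionMaps(np.zeros((1, 1, 1)), np.ones((1, 1, 1)), np.eye(4))
        dwi = synth_dwi(fm, snr=None)[0, 0, 0]
        fluid = default_fluid_response(DEFAULT_SCHEME.shells)
        for i, b in enumerate(DEFAULT_SCHEME.bvals):
            shell = int(np.searchsorted(DEFAULT_SCHEME.shells, b))
            assert dwi[i] == pytest.approx(fluid.amplitudes[shell])

    def test_noise_free_roundtrip(self, rng):
        from fetalfold.decomposition import (
            default_tissue_response,
            fit_fractions,
            shell_means,
        )

        wt = rng.uniform(0, 1, size=(5, 4, 3))
        fm = FractionMaps(wt, 1 - wt, np.eye(4))
        dwi = synth_dwi(fm, snr=None)
        rec = fit_fractions(shell_means(dwi, DEFAULT_SCHEME),
                            default_tissue_response(),
                            default_fluid_response(DEFAULT_SCHEME.shells))
        np.testing.assert_allclose(rec.tissue, wt, atol=1e-6)

    def test_invalid_snr_rejected(self):
        fm = FractionMaps(np.ones((1, 1, 1)), np.zeros((1, 1, 1)), np.eye(4))
        with pytest.raises(ValueError):
            synth_dwi(fm, snr=-3.0)


class TestCalibration:
    def test_planted_rho_closed_form(self):
        rho = planted_rho(-0.02, 1.0, 0.02)
        np.testing.assert_allclose(rho, -1 / np.sqrt(2))
        assert planted_rho(-0.02, 0.0, 0.0) == 0.0

    def test_matched_noise_inverts_planted_rho(self):
        sd = np.array([0.5, 1.0, 2.0])
        sigma = matched_noise_sd(sd, beta=-0.02, rho=-0.7)
        np.testing.assert_allclose(planted_rho(-0.02, sd, sigma), -0.7,
                                   atol=1e-12)

    def test_calibrated_sigma_hits_target_mean_rho(self, ico4, patches4):
        spec = default_fold_spec()
        depth = sulcal_depth(fold_surface(ico4, spec, 35.0))
        sigma = calibrate_noise_sd(depth, patches4, beta=-0.02,
                                   target_mean_rho=-0.7)
        sd = patch_depth_sd(depth, patches4)
        mean_rho = np.abs(planted_rho(-0.02, sd[sd > 0], sigma)).mean()
        np.testing.assert_allclose(mean_rho, 0.7, atol=1e-9)

    def test_unreachable_target_rejected(self, ico4, patches4):
        flat_depth = sulcal_depth(ico4.with_vertices(ico4.vertices * 30.0))
        with pytest.raises(ValueError):
            calibrate_noise_sd(flat_depth, patches4, beta=-0.02,
                               target_mean_rho=-0.7)


class TestCohortGeneration:
    def test_single_subject_manifest_and_files(self, tmp_path):
        manifest = make_cohort(tmp_path / "cohort", 1, template_level=3,
                               master_seed=9)
        assert len(manifest) == 1
        sdir = tmp_path / "cohort" / "sub-000"
        for name in ("surface.ply", "sulcal_depth.csv",
                     "sp_tissue_fraction.csv", "truth.json"):
            assert (sdir / name).exists()
        truth = json.loads((sdir / "truth.json").read_text())
        assert truth["master_seed"] == 9

    def test_same_seed_bitwise_identical(self, tmp_path):
        m1 = make_cohort(tmp_path / "a", 3, template_level=3, master_seed=4)
        m2 = make_cohort(tmp_path / "b", 3, template_level=3, master_seed=4)
        assert (m1["ga_weeks"] == m2["ga_weeks"]).all()
        for sid in m1["subject_id"]:
            f1 = (tmp_path / "a" / sid / "sp_tissue_fraction.csv").read_text()
            f2 = (tmp_path / "b" / sid / "sp_tissue_fraction.csv").read_text()
            assert f1 == f2

    def test_simulate_deterministic_golden(self):
        s1 = simulate_cohort(2, master_seed=13, template_level=3)
        s2 = simulate_cohort(2, master_seed=13, template_level=3)
        for a, b in zip(s1, s2):
            assert a.ga == b.ga
            np.testing.assert_array_equal(a.mesh.vertices, b.mesh.vertices)
            np.testing.assert_array_equal(a.sp_metric.values,
                                          b.sp_metric.values)

    def test_ga_distribution_uniform(self):
        # KS sanity across seeds at alpha = 0.01
        from scipy import stats as st

        pvals = []
        for seed in range(5):
            subs = simulate_cohort(112, master_seed=seed, template_level=0)
            gas = np.array([s.ga for s in subs])
            assert ((gas >= 24.0) & (gas <= 36.0)).all()
            pvals.append(st.kstest(gas, st.uniform(24.0, 12.0).cdf).pvalue)
        assert max(pvals) > 0.01  # not all rejected

    def test_vertex_metrics_respect_planted_model(self, ico3):
        depth = sulcal_depth(fold_surface(ico3, default_fold_spec(), 35.0))
        rng = np.random.default_rng(0)
        sp, cp = plant_vertex_metrics(depth, 30.0, beta=-0.02, noise_sd=0.0,
                                      rng=rng)
        np.testing.assert_allclose(
            sp.values, base_fraction(30.0, "sp") - 0.02 * depth.values,
            atol=1e-12)
        assert (cp.values >= 0).all() and (cp.values <= 1).all()

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(0)
        with pytest.raises(ValueError):
            simulate_cohort(1, observation="hologram")
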