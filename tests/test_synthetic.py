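"""The synthetic cohort generator: geometry, growth, and ground truth."""

import numpy as np
import pytest

from craniogrow.meshgeom import closed_mesh_volume, closest_on_mesh, \
    points_inside
from craniogrow.procrustes import centroid_size
from craniogrow.synthetic import (DAYS_PER_MONTH, default_params,
                                  generate_cohort, grow_skull,
                                  make_template_skull,
                                  superellipsoid_volume)


class TestTemplate:
    def test_has_88_named_landmarks(self, template_skull):
        assert len(template_skull.landmarks) == 88
        assert len(set(template_skull.landmarks.names)) == 88

    def test_mesh_watertight_genus_zero(self, template_skull):
        m = template_skull.mesh
        assert m.is_watertight
        assert m.euler_number == 2  # sphere topology

    def test_shell_volume_matches_closed_form(self, params_clean):
        spec = make_template_skull(4, params_clean)
        expect = superellipsoid_volume(params_clean.shell_axes,
                                       params_clean.shell_exponent)
        assert closed_mesh_volume(spec.mesh) == pytest.approx(expect,
                                                              rel=0.01)

    def test_landmarks_on_shell_surface(self, template_skull):
        _, d, _ = closest_on_mesh(template_skull.mesh,
                                  template_skull.landmarks.coords)
        # landmarks sit on the analytic surface; the subdiv-3 mesh chords
        # beneath it by up to ~0.5 mm
        assert d.max() < 0.6

    def test_invalid_resolution(self, params_clean):
        with pytest.raises(ValueError, match="resolution"):
            make_template_skull(1, params_clean)

    def test_month_convention(self, template_skull):
        assert template_skull.age_months == pytest.approx(
            365 / 30.41, abs=1e-9)


class TestGrowth:
    def test_identity_at_template_age(self, template_skull, params_clean):
        s = grow_skull(template_skull, template_skull.age_days, "F",
                       params_clean, rng_seed=9)
        assert np.abs(s.landmarks.coords
                      - template_skull.landmarks.coords).max() < 1e-9

    def test_seeded_determinism_bitwise(self, template_skull, params_noisy):
        a = grow_skull(template_skull, 700, "M", params_noisy, rng_seed=42,
                       build_meshes=False)
        b = grow_skull(template_skull, 700, "M", params_noisy, rng_seed=42,
                       build_meshes=False)
        assert np.array_equal(a.landmarks.coords, b.landmarks.coords)

    def test_centroid_size_follows_curve(self, template_skull, params_clean):
        s0 = grow_skull(template_skull, 0, "F", params_clean, 1,
                        build_meshes=False)
        s48 = grow_skull(template_skull, 1460, "F", params_clean, 1,
                         build_meshes=False)
        ratio = centroid_size(s48.landmarks) / centroid_size(s0.landmarks)
        curve = params_clean.size_curve
        expect = curve(1460 / DAYS_PER_MONTH) / curve(0.0)
        assert ratio == pytest.approx(expect, rel=1e-9)

    def test_male_size_offset(self, template_skull, params_clean):
        f = grow_skull(template_skull, 500, "F", params_clean, 1,
                       build_meshes=False)
        m = grow_skull(template_skull, 500, "M", params_clean, 1,
                       build_meshes=False)
        assert centroid_size(m.landmarks) / centroid_size(f.landmarks) == \
            pytest.approx(params_clean.sex_size_offset, rel=1e-9)

    def test_negative_age_rejected(self, template_skull, params_clean):
        with pytest.raises(ValueError):
            grow_skull(template_skull, -1, "F", params_clean, 1)

    def test_negative_noise_rejected(self, template_skull):
        bad = default_params(landmark_noise_sd=-0.1)
        with pytest.raises(ValueError):
            grow_skull(template_skull, 100, "F", bad, 1)

    def test_noise_rms_magnitude(self, template_skull):
        """RMS landmark displacement ~ noise_sd * sqrt(3) (3 coords)."""
        sd = 0.8
        noisy = default_params(landmark_noise_sd=sd)
        clean = default_params(landmark_noise_sd=0.0)
        disp = []
        for seed in range(30):
            a = grow_skull(template_skull, 400, "F", noisy, seed,
                           build_meshes=False)
            b = grow_skull(template_skull, 400, "F", clean, seed,
                           build_meshes=False)
            disp.append(a.landmarks.coords - b.landmarks.coords)
        rms = np.sqrt(np.mean(np.sum(np.concatenate(disp) ** 2, axis=1)))
        assert rms == pytest.approx(sd * np.sqrt(3), rel=0.05)

    def test_true_volumes_match_curves_exactly(self, template_skull,
                                               params_clean):
        for age in (0, 250, 800, 1460):
            s = grow_skull(template_skull, age, "F", params_clean, 1,
                           build_meshes=False)
            months = age / DAYS_PER_MONTH
            for name, curve in params_clean.volume_curves().items():
                assert s.true_volumes[name] == pytest.approx(
                    float(curve(months)), rel=1e-9)
                assert s.cavities[name].volume == pytest.approx(
                    float(curve(months)), rel=1e-9)

    @pytest.mark.parametrize("age_days", [0, 730, 1460])
    def test_cavities_inside_shell_and_disjoint(self, template_skull,
                                                params_clean, age_days):
        s = grow_skull(template_skull, age_days, "F", params_clean, 1)
        names = list(s.cavities)
        for name in names:
            mesh, _ = s.cavity_meshes[name]
            assert points_inside(s.mesh, mesh.vertices[::9]).all()
        rng = np.random.default_rng(0)
        u = rng.normal(size=(300, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        for i, a in enumerate(names):
            surf = s.cavities[a].center + u * s.cavities[a].semi_axes
            for j, b in enumerate(names):
                if i != j:
                    assert not s.cavities[b].contains(surf).any()


class TestCohort:
    def test_sex_counts_match_study(self, params_clean):
        coh = generate_cohort(217, params=params_clean, seed=3,
                              sex_ratio=123 / 217, build_meshes=False)
        sexes = coh.metadata["sex"].value_counts()
        assert sexes["M"] == 123 and sexes["F"] == 94

    def test_reproducible_under_fixed_seed(self, params_noisy):
        a = generate_cohort(10, params=params_noisy, seed=5,
                            build_meshes=False)
        b = generate_cohort(10, params=params_noisy, seed=5,
                            build_meshes=False)
        for sa, sb in zip(a.specimens, b.specimens):
            assert np.array_equal(sa.landmarks.coords, sb.landmarks.coords)
        assert a.metadata.equals(b.metadata)

    def test_too_small_cohort_rejected(self, params_clean):
        with pytest.raises(ValueError):
            generate_cohort(1, params=params_clean)

    def test_bad_sex_ratio_rejected(self, params_clean):
        with pytest.raises(ValueError):
            generate_cohort(10, params=params_clean, sex_ratio=1.0)

    def test_ages_in_range(self, params_clean):
        coh = generate_cohort(50, params=params_clean, seed=2,
                              build_meshes=False)
        ages = coh.metadata["age_days"]
        assert ages.between(0, 1460).all()

    def test_write_cohort_round_trip(self, tmp_path, params_noisy):
        from craniogrow.landmarks import read_landmarks_csv
        from craniogrow.synthetic import write_cohort
        coh = generate_cohort(3, params=params_noisy, seed=8, resolution=2)
        write_cohort(coh, tmp_path)
        assert (tmp_path / "metadata.csv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        for s in coh.specimens:
            assert (tmp_path / f"{s.specimen_id}.ply").exists()
            back = read_landmarks_csv(tmp_path / f"{s.specimen_id}_lms.csv")
            assert np.abs(back.coords - s.landmarks.coords).max() < 1e-9


class TestDivergence:
    def test_zero_divergence_shares_vector(self, params_clean):
        vf = params_clean.sex_allometric_vector("F")
        vm = params_clean.sex_allometric_vector("M")
        assert np.array_equal(vf, vm)

    def test_divergence_angle_is_injected(self):
        p = default_params(trajectory_divergence_deg=45.0)
        vf = p.sex_allometric_vector("F")
        vm = p.sex_allometric_vector("M")
        cos = np.sum(vf * vm)
        assert np.degrees(np.arccos(cos)) == pytest.approx(45.0, abs=1e-6)
        assert np.linalg.norm(vm) == pytest.approx(1.0, rel=1e-9)
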