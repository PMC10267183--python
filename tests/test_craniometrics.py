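"""Linear dimensions, indices, cavity volumes and volume transforms."""

import numpy as np
import pandas as pd
import pytest
import trimesh

from craniogrow.craniometrics import (cavity_volume, index_panel,
                                      linear_dimensions,
                                      load_dimension_table, volume_set)
from craniogrow.synthetic import grow_skull


class TestDimensions:
    def test_exactly_47_values(self, template_skull):
        dims = linear_dimensions(template_skull.landmarks,
                                 mesh=template_skull.mesh)
        assert len(dims) == 47
        assert dims.notna().all()
        assert (dims > 0).all()

    def test_table_endpoints_in_roster(self, template_skull):
        table = load_dimension_table()
        names = set(template_skull.landmarks.names)
        assert set(table["endpoint_a"]).issubset(names)
        assert set(table["endpoint_b"]).issubset(names)
        assert (table.loc[table["index"] == 3, "kind"]
                == "circumference").all()

    def test_left_right_symmetry(self, template_skull):
        dims = linear_dimensions(template_skull.landmarks)
        assert dims["Orbital breadth (left)"] == pytest.approx(
            dims["Orbital breadth (right)"], abs=1e-9)
        assert dims["Orbital height (left)"] == pytest.approx(
            dims["Orbital height (right)"], abs=1e-9)

    def test_matches_direct_distance(self, template_skull):
        dims = linear_dimensions(template_skull.landmarks)
        lm = template_skull.landmarks
        expect = np.sqrt(np.sum((lm["Euryon_L"] - lm["Euryon_R"]) ** 2))
        assert dims["Maximum cranial breadth"] == pytest.approx(
            expect, rel=1e-12)

    def test_missing_landmark_named(self, template_skull):
        short = template_skull.landmarks.subset(np.arange(50))
        with pytest.raises(KeyError):
            linear_dimensions(short)

    def test_uniform_scaling_linearity(self, template_skull):
        lm = template_skull.landmarks
        dims1 = linear_dimensions(lm)
        dims2 = linear_dimensions(lm.with_coords(lm.coords * 2.0))
        assert np.allclose(dims2.drop("Cranial circumference"),
                           2.0 * dims1.drop("Cranial circumference"),
                           rtol=1e-9)


class TestIndices:
    def _dims(self, **kw):
        base = {
            "Maximum cranial length": 90.0, "Maximum cranial breadth": 90.0,
            "Basion-bregma height": 90.0, "Bizygomatic breadth": 80.0,
            "Upper facial height": 40.0, "Orbital height (left)": 30.0,
            "Orbital breadth (left)": 35.0, "Nasal breadth": 12.0,
            "Nasal height": 24.0, "Internal palatal width": 25.0,
            "Maximum palatal length": 40.0, "Foramen magnum breadth": 28.0,
            "Foramen magnum length": 32.0,
        }
        base.update(kw)
        return pd.Series(base)

    def test_equal_axes_give_ci_100_cm_90(self):
        panel = index_panel(self._dims())
        assert panel.CI == pytest.approx(100.0)
        assert panel.CM == pytest.approx(90.0)

    def test_caption_formulas(self):
        panel = index_panel(self._dims())
        assert panel.NI == pytest.approx(12.0 / 24.0 * 100)  # = 50
        assert panel.CFI == pytest.approx(80.0 / 90.0 * 100)
        assert panel.UFI == pytest.approx(40.0 / 80.0 * 100)
        assert panel.LOI == pytest.approx(30.0 / 35.0 * 100)
        assert panel.PI == pytest.approx(25.0 / 40.0 * 100)
        assert panel.FMI == pytest.approx(28.0 / 32.0 * 100)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            index_panel(self._dims(**{"Maximum cranial length": 0.0}))

    def test_indices_scale_invariant(self, template_skull):
        lm = template_skull.landmarks
        d1 = linear_dimensions(lm)
        d2 = linear_dimensions(lm.with_coords(lm.coords * 1.7))
        p1, p2 = index_panel(d1), index_panel(d2)
        for key in ("CI", "CFI", "UFI", "LOI", "NI", "PI", "FMI"):
            assert getattr(p2, key) == pytest.approx(getattr(p1, key),
                                                     rel=1e-9)
        assert p2.CM == pytest.approx(1.7 * p1.CM, rel=1e-9)


class TestVolumeSet:
    def test_equal_volumes_quarter_each(self):
        vs = volume_set(50.0, 50.0, 50.0, 50.0)
        assert np.allclose(vs.cpvols, 25.0)

    def test_hand_arithmetic_example(self):
        vs = volume_set(1000.0, 8.0, 27.0, 64.0)
        assert np.allclose(vs.cvols, [10.0, 2.0, 3.0, 4.0])
        total = 10.0 + 2.0 + 3.0 + 4.0
        assert np.allclose(vs.cpvols,
                           [1000 / total, 200 / total, 300 / total,
                            400 / total])

    def test_cpvols_sum_100_random(self, rng):
        for _ in range(10):
            v = rng.uniform(1, 1e6, size=4)
            vs = volume_set(*v)
            assert vs.cpvols.sum() == pytest.approx(100.0, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            volume_set(1.0, 0.0, 2.0, 3.0)


class TestCavityVolume:
    def test_ellipsoid_closed_form(self):
        """Semi-axes (60, 45, 50): V = 4/3*pi*abc = 565,487 mm^3."""
        from craniogrow.synthetic import CavityShape, _build_cavity_mesh
        cav = CavityShape(name="test", center=np.zeros(3),
                          semi_axes=np.array([60.0, 45.0, 50.0]),
                          aperture_dir=np.array([0.0, 0.0, 1.0]))
        mesh, loops = _build_cavity_mesh(cav, resolution=5)
        v = cavity_volume(mesh, cav.center, loops=loops)
        assert v == pytest.approx(4 / 3 * np.pi * 60 * 45 * 50, rel=0.02)

    def test_sphere_with_small_aperture(self):
        """A ~5%-area polar aperture capped back: volume ~ full sphere."""
        from craniogrow.synthetic import CavityShape, _build_cavity_mesh
        # cap area fraction (1 - cos(theta))/2 = 0.05 -> cos(theta) = 0.9
        cav = CavityShape(name="s", center=np.zeros(3),
                          semi_axes=np.array([10.0, 10.0, 10.0]),
                          aperture_dir=np.array([0.0, 0.0, 1.0]),
                          aperture_cos=0.90)
        mesh, loops = _build_cavity_mesh(cav, resolution=5)
        v = cavity_volume(mesh, cav.center, loops=loops)
        assert v == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)

    def test_rigid_motion_invariance(self, template_skull, params_clean):
        from scipy.spatial.transform import Rotation
        s = grow_skull(template_skull, 600, "F", params_clean, rng_seed=1)
        mesh, loops = s.cavity_meshes["LOV"]
        v1 = cavity_volume(mesh, s.cavities["LOV"].center, loops=loops)
        q = Rotation.from_euler("xyz", [0.5, 0.2, -0.3]).as_matrix()
        shift = np.array([10.0, -20.0, 5.0])
        moved = trimesh.Trimesh(vertices=mesh.vertices @ q.T + shift,
                                faces=mesh.faces, process=False)
        v2 = cavity_volume(moved, s.cavities["LOV"].center @ q.T + shift,
                           loops=loops)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_seed_outside_rejected(self, template_skull, params_clean):
        s = grow_skull(template_skull, 600, "F", params_clean, rng_seed=1)
        mesh, loops = s.cavity_meshes["NCV"]
        with pytest.raises(ValueError, match="seed"):
            cavity_volume(mesh, np.array([1e4, 1e4, 1e4]), loops=loops)

    def test_combined_scene_selects_enclosing_cavity(self, template_skull,
                                                     params_clean):
        """With shell + cavity concatenated, the smallest watertight
        component containing the seed is the cavity, not the shell."""
        s = grow_skull(template_skull, 365, "F", params_clean, rng_seed=1)
        mesh, loops = s.cavity_meshes["ICV"]
        off = len(s.mesh.vertices)
        combined = trimesh.util.concatenate([s.mesh, mesh])
        loops2 = [[i + off for i in lp] for lp in loops]
        v = cavity_volume(combined, s.cavities["ICV"].center, loops=loops2)
        assert v == pytest.approx(s.true_volumes["ICV"], rel=0.02)

    def test_recovery_across_ages(self, template_skull, params_clean):
        for age in (0, 730, 1460):
            s = grow_skull(template_skull, age, "F", params_clean,
                           rng_seed=2)
            for name, (mesh, loops) in s.cavity_meshes.items():
                v = cavity_volume(mesh, s.cavities[name].center,
                                  loops=loops)
                assert v == pytest.approx(s.true_volumes[name], rel=0.02)
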