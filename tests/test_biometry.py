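import numpy as np
import pytest

from cervimetry.biometry import (
    compute_centrepoint,
    compute_midpoint,
    locate_end_interfaces,
    measure_cervical_length,
    measure_diameter,
    run_biometry,
)
from cervimetry.io import LabelVolume
from cervimetry.phantom import PhantomSpec, generate_phantom


class TestCervicalLength:
    @pytest.mark.parametrize(
        "a,m,b,expected",
        [
            ((0, 0, 0), (0, 0, 15), (0, 0, 30), 30.0),
            ((0, 0, 0), (0, 10, 10), (0, 20, 10), 10 * np.sqrt(2) + 10),
            ((1, 2, 3), (1, 2, 3), (4, 6, 3), 5.0),  # coincident inlet/midpoint
        ],
    )
    def test_two_line_length(self, a, m, b, expected):
        assert measure_cervical_length(
            np.array(a, float), np.array(m, float), np.array(b, float)
        ) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            measure_cervical_length(
                np.array([0.0, 0.0, np.nan]), np.zeros(3), np.ones(3)
            )


class TestCentrepoints:
    def test_mean_of_two_voxels(self):
        vol = LabelVolume(voxels=np.zeros((4, 4, 4), dtype=np.int16), affine=np.eye(4))
        roi = np.array([[0, 0, 0], [0, 2, 0]])
        assert np.allclose(compute_centrepoint(roi, vol), [0, 1, 0])

    def test_single_voxel(self):
        affine = np.eye(4)
        affine[:3, :3] *= 0.5
        vol = LabelVolume(voxels=np.zeros((4, 4, 4), dtype=np.int16), affine=affine)
        assert np.allclose(compute_centrepoint(np.array([[2, 1, 3]]), vol), [1.0, 0.5, 1.5])

    def test_empty_roi_rejected(self):
        vol = LabelVolume(voxels=np.zeros((4, 4, 4), dtype=np.int16), affine=np.eye(4))
        with pytest.raises(ValueError):
            compute_centrepoint(np.empty((0, 3)), vol)

    def test_inlet_centre_matches_phantom(self, straight_phantom):
        spec, vol, _ = straight_phantom
        roi_in, _ = locate_end_interfaces(vol)
        centre = compute_centrepoint(roi_in, vol)
        # lateral agreement is sub-voxel; axially the ROI sits half a voxel
        # inside the open cap
        assert np.linalg.norm(centre[:2] - np.array(spec.inlet_point)[:2]) < 0.5 * spec.spacing
        assert abs(centre[2] - spec.inlet_point[2]) < 1.5 * spec.spacing

    def test_midpoint_of_symmetric_tube(self, straight_phantom):
        spec, vol, _ = straight_phantom
        assert np.linalg.norm(compute_midpoint(vol) - np.array(spec.mid_point)) < 0.5 * spec.spacing

    def test_midpoint_of_single_voxel_canal(self):
        vox = np.zeros((30, 30, 30), dtype=np.int16)
        vox[10:28, 10:28, 10:28] = 0
        vox[15, 15, 15] = 1
        vol = LabelVolume(voxels=vox, affine=np.eye(4))
        assert np.allclose(compute_midpoint(vol), [15, 15, 15])

    def test_midpoint_off_axis_for_bent_canal(self, bent_phantom):
        """The canal centroid of a bent tube is pulled inside the bend."""
        spec, vol, _ = bent_phantom
        mid = compute_midpoint(vol)
        assert np.linalg.norm(mid - np.array(spec.mid_point)) > 1.0


class TestEndInterfaces:
    def test_straight_tube_ends_at_extremes(self, straight_phantom):
        spec, vol, _ = straight_phantom
        roi_in, roi_out = locate_end_interfaces(vol)
        c_in = compute_centrepoint(roi_in, vol)
        c_out = compute_centrepoint(roi_out, vol)
        # default rule: inlet is the superior (larger z) end
        assert c_in[2] > c_out[2]
        assert c_in[2] == pytest.approx(15.0, abs=1.0)
        assert c_out[2] == pytest.approx(-15.0, abs=1.0)

    def test_enclosed_canal_has_no_interfaces(self):
        vox = np.zeros((24, 24, 24), dtype=np.int16)
        vox[4:20, 4:20, 4:20] = 2  # stroma shell
        vox[8:16, 8:16, 8:16] = 1  # canal fully enclosed
        vol = LabelVolume(voxels=vox, affine=np.eye(4))
        with pytest.raises(ValueError, match="closed or capped"):
            locate_end_interfaces(vol)

    def test_no_canal_rejected(self):
        vol = LabelVolume(voxels=np.zeros((8, 8, 8), dtype=np.int16), affine=np.eye(4))
        with pytest.raises(ValueError, match="canal"):
            locate_end_interfaces(vol)

    def test_cyst_at_inlet_included_in_roi(self):
        """A cyst flush against the open inlet contributes interface voxels."""
        spec = PhantomSpec(cysts=(((0.0, 0.0, 14.2), 1.5),))
        vol, _ = generate_phantom(spec)
        roi_in, _ = locate_end_interfaces(vol)
        labels = vol.voxels[tuple(roi_in.T)]
        assert (labels == 4).any()
        assert (labels == 1).any()


class TestDiameter:
    def test_straight_phantom_inlet_diameter(self, straight_phantom):
        spec, vol, truth = straight_phantom
        res = run_biometry(vol)
        assert res.inlet_diameter_mm == pytest.approx(6.0, abs=2 * spec.spacing)
        assert res.outlet_diameter_mm == pytest.approx(6.0, abs=2 * spec.spacing)

    def test_doubling_radius_doubles_diameter(self):
        measured = {}
        for r in (2.0, 4.0):
            spec = PhantomSpec(canal_radius=r)
            vol, _ = generate_phantom(spec)
            measured[r] = run_biometry(vol).inlet_diameter_mm
        assert measured[4.0] == pytest.approx(2 * measured[2.0], abs=2 * 0.8)

    def test_centre_in_stroma_rejected(self, straight_phantom):
        _, vol, _ = straight_phantom
        centre = np.array([0.0, 7.5, 0.0])  # mid outer stroma
        with pytest.raises(ValueError, match="outside canal"):
            measure_diameter(vol, centre, np.array([0.0, 0.0, 1.0]),
                             np.array([1.0, 0.0, 0.0]))

    def test_parallel_axis_and_normal_rejected(self, straight_phantom):
        _, vol, _ = straight_phantom
        with pytest.raises(ValueError, match="parallel"):
            measure_diameter(vol, np.zeros(3), np.array([0.0, 0.0, 1.0]),
                             np.array([0.0, 0.0, 1.0]))


class TestRunBiometry:
    def test_straight_phantom_full_pipeline(self, straight_phantom):
        spec, vol, truth = straight_phantom
        res = run_biometry(vol)
        tol = 2 * spec.spacing
        assert res.cervical_length_mm == pytest.approx(truth.length_mm, abs=tol)
        assert res.inlet_diameter_mm == pytest.approx(truth.inlet_diameter_mm, abs=tol)
        assert res.outlet_diameter_mm == pytest.approx(truth.outlet_diameter_mm, abs=tol)

    def test_length_consistent_with_stored_landmarks(self, bent_phantom):
        _, vol, _ = bent_phantom
        res = run_biometry(vol)
        lm = res.landmarks
        assert res.cervical_length_mm == measure_cervical_length(
            lm.inlet_centre, lm.midpoint, lm.outlet_centre
        )

    def test_rigid_rotation_invariance(self):
        """Rotating the phantom 45 degrees changes measurements < 1 voxel."""
        spec0 = PhantomSpec(grid_size=72)
        base = run_biometry(generate_phantom(spec0)[0])
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        rot = PhantomSpec(
            inlet_point=tuple(R @ spec0.inlet_point),
            mid_point=tuple(R @ spec0.mid_point),
            outlet_point=tuple(R @ spec0.outlet_point),
            grid_size=72,
        )
        res = run_biometry(generate_phantom(rot)[0])
        assert res.cervical_length_mm == pytest.approx(base.cervical_length_mm, abs=0.8)
        assert res.inlet_diameter_mm == pytest.approx(base.inlet_diameter_mm, abs=0.8)
        assert res.outlet_diameter_mm == pytest.approx(base.outlet_diameter_mm, abs=0.8)

    def test_translation_invariance(self):
        spec0 = PhantomSpec(grid_size=72)
        base = run_biometry(generate_phantom(spec0)[0])
        shift = np.array([3.3, -2.1, 1.7])
        moved = PhantomSpec(
            inlet_point=tuple(np.array(spec0.inlet_point) + shift),
            mid_point=tuple(np.array(spec0.mid_point) + shift),
            outlet_point=tuple(np.array(spec0.outlet_point) + shift),
            grid_size=72,
        )
        res = run_biometry(generate_phantom(moved)[0])
        assert res.cervical_length_mm == pytest.approx(base.cervical_length_mm, abs=0.8)
        assert res.inlet_diameter_mm == pytest.approx(base.inlet_diameter_mm, abs=0.8)

    def test_collinear_length_equals_euclidean(self, straight_phantom):
        _, vol, _ = straight_phantom
        res = run_biometry(vol)
        lm = res.landmarks
        euclid = np.linalg.norm(lm.inlet_centre - lm.outlet_centre)
        assert res.cervical_length_mm == pytest.approx(euclid, abs=0.1)

    def test_result_serialises(self, straight_phantom, tmp_path):
        _, vol, _ = straight_phantom
        res = run_biometry(vol)
        out = tmp_path / "biometry.json"
        res.to_json(out, input="phantom")
        import json

        d = json.loads(out.read_text())
        assert d["cervical_length_mm"] == pytest.approx(res.cervical_length_mm)
        assert d["provenance"]["input"] == "phantom"
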