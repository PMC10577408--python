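"""Vessel-tree construction, rasterization and NIfTI round trips."""

import numpy as np
import pytest

import coroflow as cf
from coroflow.geometry import (
    GeometryError,
    SegmentSpec,
    StenosisSpec,
    VesselTreeSpec,
    bifurcation_spec,
    build_tree,
    read_mask,
    straight_tube_spec,
    voxelize,
    write_mask,
)


class TestBuildTree:
    def test_no_stenosis_radius_equals_taper(self):
        spec = straight_tube_spec(radius=1.5, length=30.0, ds=None)
        tree = build_tree(spec)
        seg = tree.root
        assert np.allclose(seg.radius, seg.taper)

    def test_tapered_segment_interpolates_linearly(self):
        seg = SegmentSpec(
            id="s", control_points=((0, 0, 0), (20, 0, 0)),
            reference_radius_proximal=2.0, reference_radius_distal=1.0,
        )
        tree = build_tree(VesselTreeSpec(segments=(seg,), inlet_segment_id="s"))
        assert np.isclose(float(tree.root.radius_at(10.0)), 1.5, atol=1e-9)

    def test_throat_radius_is_one_minus_ds_times_reference(self):
        spec = straight_tube_spec(radius=1.5, length=40.0, ds=0.5, lesion_length=10.0)
        tree = build_tree(spec)
        assert np.isclose(tree.min_radius(), 0.75, atol=1e-4)

    @pytest.mark.parametrize("shape", ["cosine", "gaussian"])
    def test_window_support_is_exactly_the_lesion(self, shape):
        st = StenosisSpec(center_arclength=20.0, length=10.0,
                          diameter_reduction=0.5, shape=shape)
        s = np.array([14.9, 15.0, 20.0, 25.0, 25.1])
        w = st.window(s)
        assert w[0] == 0.0 and w[-1] == 0.0
        assert np.isclose(w[2], 1.0)

    def test_bifurcation_shares_junction_point(self):
        tree = build_tree(bifurcation_spec())
        junction = tree.segments["parent"].points[-1]
        for child in ("child_a", "child_b"):
            start = tree.segments[child].points[0]
            assert np.linalg.norm(start - junction) < 1e-9
        assert len(tree.segments) == 3
        assert [leaf.spec.id for leaf in tree.leaves()] == ["child_a", "child_b"]

    def test_overlapping_stenoses_rejected(self):
        seg = SegmentSpec(
            id="s", control_points=((0, 0, 0), (40, 0, 0)),
            reference_radius_proximal=1.5, reference_radius_distal=1.5,
            stenoses=(
                StenosisSpec(center_arclength=18.0, length=10.0, diameter_reduction=0.4),
                StenosisSpec(center_arclength=24.0, length=10.0, diameter_reduction=0.3),
            ),
        )
        with pytest.raises(GeometryError, match="overlap"):
            build_tree(VesselTreeSpec(segments=(seg,), inlet_segment_id="s"))

    def test_stenosis_outside_segment_rejected(self):
        seg = SegmentSpec(
            id="s", control_points=((0, 0, 0), (20, 0, 0)),
            reference_radius_proximal=1.5, reference_radius_distal=1.5,
            stenoses=(StenosisSpec(center_arclength=19.0, length=6.0,
                                   diameter_reduction=0.4),),
        )
        with pytest.raises(GeometryError, match="outside"):
            build_tree(VesselTreeSpec(segments=(seg,), inlet_segment_id="s"))

    def test_sub_2mm_reference_at_lesion_rejected(self):
        seg = SegmentSpec(
            id="s", control_points=((0, 0, 0), (20, 0, 0)),
            reference_radius_proximal=0.9, reference_radius_distal=0.9,
            stenoses=(StenosisSpec(center_arclength=10.0, length=6.0,
                                   diameter_reduction=0.4),),
        )
        with pytest.raises(GeometryError, match="2.0 mm"):
            build_tree(VesselTreeSpec(segments=(seg,), inlet_segment_id="s"))

    def test_two_roots_rejected(self):
        a = SegmentSpec(id="a", control_points=((0, 0, 0), (10, 0, 0)),
                        reference_radius_proximal=1.5, reference_radius_distal=1.5)
        b = SegmentSpec(id="b", control_points=((0, 5, 0), (10, 5, 0)),
                        reference_radius_proximal=1.5, reference_radius_distal=1.5)
        with pytest.raises(GeometryError, match="root"):
            build_tree(VesselTreeSpec(segments=(a, b), inlet_segment_id="a"))

    def test_json_round_trip(self):
        spec = straight_tube_spec(radius=1.5, length=30.0, ds=0.4)
        again = VesselTreeSpec.from_json(spec.to_json())
        assert again == spec


class TestVoxelize:
    def test_cross_section_area_matches_circle(self):
        tree = build_tree(straight_tube_spec(radius=1.5, length=20.0, ds=None))
        mask = voxelize(tree, spacing=0.375, padding=1.0)
        area_true = np.pi * 1.5**2
        counts = mask.grid.sum(axis=(1, 2))
        interior = counts[5:-5] * 0.375**2
        assert np.all(np.abs(interior - area_true) / area_true < 0.15)

    def test_deterministic(self):
        tree = build_tree(straight_tube_spec(radius=1.5, length=15.0, ds=0.3))
        m1 = voxelize(tree, spacing=0.35)
        m2 = voxelize(tree, spacing=0.35)
        assert np.array_equal(m1.grid, m2.grid)
        assert m1.origin == m2.origin

    def test_volume_converges_with_refinement(self):
        tree = build_tree(straight_tube_spec(radius=1.5, length=15.0, ds=None))
        v_true = np.pi * 1.5**2 * 15.0
        errs = []
        for sp in (0.6, 0.4, 0.25):
            m = voxelize(tree, spacing=sp)
            errs.append(abs(m.grid.sum() * sp**3 - v_true) / v_true)
        assert errs[0] > errs[1] > errs[2]

    def test_coarse_spacing_names_the_throat(self):
        tree = build_tree(straight_tube_spec(radius=1.5, length=30.0, ds=0.7))
        with pytest.raises(GeometryError, match="seg0"):
            voxelize(tree, spacing=0.3)

    def test_mask_touches_boundary_only_at_ends(self):
        tree = build_tree(straight_tube_spec(radius=1.5, length=15.0, ds=None))
        mask = voxelize(tree, spacing=0.3, padding=1.0)
        assert sorted(mask.boundary_faces_touched()) == ["+x", "-x"]


class TestNiftiRoundTrip:
    def test_round_trip_preserves_everything(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = rng.random((32, 32, 32)) > 0.7
        mask = cf.VoxelMask(grid=grid, spacing=(0.35, 0.35, 0.5),
                            origin=(-3.1, 0.0, 12.25))
        path = tmp_path / "m.nii.gz"
        write_mask(mask, path)
        back = read_mask(path)
        assert np.array_equal(back.grid, mask.grid)
        assert np.allclose(back.spacing, mask.spacing, atol=1e-6)
        assert np.allclose(back.origin, mask.origin, atol=1e-6)

    def test_non_binary_volume_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.arange(8, dtype=np.float32).reshape(2, 2, 2),
                              np.eye(4))
        nib.save(img, tmp_path / "bad.nii.gz")
        with pytest.raises(GeometryError, match="binary"):
            read_mask(tmp_path / "bad.nii.gz")
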