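import numpy as np
import pytest

from slnatlas import (
    CorrespondenceMap,
    CTVMask,
    SLNPoint,
    centroid_distance_to_ctv,
    classify_covered,
    coverage_report,
    sphere_fraction_inside,
)
from slnatlas.ctv_geometry import read_mask, read_points, write_mask, write_points
from slnatlas.synthetic import Box, GeometrySimSpec, _rasterize

GRID = GeometrySimSpec(shape=(60, 60, 60), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


def cube_mask(lo=9.5, hi=49.5, label="L1", side="L", spec=GRID):
    # faces at voxel midplanes so the rasterized boundary equals the analytic one
    return _rasterize(Box(label, side, (lo,) * 3, (hi,) * 3), spec)


def sln(x, y, z, field="axilla-I-anterior", side="L", d=5.0):
    return SLNPoint(x, y, z, field, side, diameter_mm=d)


def cap_fraction(r, d):
    """Volume fraction of a sphere on the foreground side of a plane at
    signed distance d from the centre (d > 0: centre inside)."""
    h = r + d
    return h * h * (3 * r - h) / (4 * r**3)


class TestSphereFraction:
    def test_fully_interior_sphere(self):
        assert sphere_fraction_inside(sln(30, 30, 30), cube_mask()) == 1.0

    def test_fully_outside_sphere(self):
        assert sphere_fraction_inside(sln(55, 55, 55), cube_mask()) == 0.0

    def test_centred_on_planar_face_is_half(self):
        frac = sphere_fraction_inside(sln(49.5, 30, 30), cube_mask())
        assert frac == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("d", np.linspace(-2.2, 2.2, 9).round(3).tolist())
    def test_spherical_cap_oracle(self, d):
        """Lattice fraction vs the closed-form cap volume for a single plane cut."""
        frac = sphere_fraction_inside(sln(49.5 - d, 30, 30), cube_mask())
        assert frac == pytest.approx(cap_fraction(2.5, d), abs=0.02)

    def test_lattice_refinement_is_stable(self):
        mask = cube_mask()
        for d in (-1.7, -0.4, 0.0, 0.9, 2.1):
            p = sln(49.5 - d, 30, 30)
            f1 = sphere_fraction_inside(p, mask, n_lattice=1000)
            f2 = sphere_fraction_inside(p, mask, n_lattice=10000)
            assert abs(f1 - f2) < 0.01

    def test_empty_mask_scores_zero(self):
        empty = CTVMask(
            data=np.zeros((8, 8, 8), dtype=bool),
            spacing=np.ones(3),
            origin=np.zeros(3),
            direction=np.eye(3),
        )
        assert sphere_fraction_inside(sln(4, 4, 4), empty) == 0.0

    def test_rigid_axis_permutation_invariance(self):
        """Permuting mask axes while permuting the direction matrix leaves
        physical geometry, hence every fraction, exactly unchanged."""
        mask = cube_mask(lo=9.5, hi=39.5)
        perm = (2, 0, 1)
        P = np.eye(3)[list(perm)]
        permuted = CTVMask(
            data=np.transpose(mask.data, perm),
            spacing=mask.spacing[list(perm)],
            origin=mask.origin,
            direction=mask.direction @ P.T,
            label=mask.label,
            side=mask.side,
        )
        for p in [sln(39.5, 20, 20), sln(38.2, 20, 20), sln(20, 20, 20)]:
            assert sphere_fraction_inside(p, permuted) == sphere_fraction_inside(p, mask)


class TestClassification:
    @pytest.mark.parametrize("frac,covered", [(0.51, True), (0.5, False), (0.0, False), (1.0, True)])
    def test_strictly_greater_than_half(self, frac, covered):
        assert classify_covered(frac) is covered

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_covered(1.2)


class TestCentroidDistance:
    def test_outside_cube_face(self):
        # nearest boundary voxel centre sits at x = 49, i.e. 7 mm away
        d = centroid_distance_to_ctv(sln(56.0, 30, 30), [cube_mask()])
        assert d == pytest.approx(7.0, abs=0.5)

    def test_inside_foreground_is_zero(self):
        assert centroid_distance_to_ctv(sln(30, 30, 30), [cube_mask()]) == 0.0

    def test_minimum_over_masks(self):
        near = cube_mask(lo=9.5, hi=29.5)
        far = cube_mask(lo=49.5, hi=58.5, label="L2")
        # boundary voxel centres at x = 29 (near) and x = 50 (far)
        d = centroid_distance_to_ctv(sln(34.0, 20, 20), [near, far])
        assert d == pytest.approx(5.0, abs=0.5)

    def test_all_empty_masks_rejected(self):
        empty = CTVMask(
            data=np.zeros((8, 8, 8), dtype=bool),
            spacing=np.ones(3),
            origin=np.zeros(3),
            direction=np.eye(3),
        )
        with pytest.raises(ValueError):
            centroid_distance_to_ctv(sln(4, 4, 4), [empty])

    def test_matches_brute_force_on_small_masks(self):
        """KD-tree distance equals exhaustive nearest-boundary-voxel search."""
        rng = np.random.default_rng(5)
        spec = GeometrySimSpec(shape=(24, 24, 24), spacing=(1.0, 1.5, 2.0))
        for _ in range(3):
            data = np.zeros(spec.shape, dtype=bool)
            lo = rng.integers(2, 8, size=3)
            hi = lo + rng.integers(4, 10, size=3)
            data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            mask = CTVMask(
                data=data, spacing=np.array(spec.spacing), origin=np.zeros(3), direction=np.eye(3)
            )
            from scipy import ndimage

            boundary = data & ~ndimage.binary_erosion(data)
            coords = np.argwhere(boundary) * np.array(spec.spacing)
            for _ in range(5):
                p = sln(*(rng.uniform(0, 24) * np.array(spec.spacing)))
                got = centroid_distance_to_ctv(p, [mask])
                if mask.contains(p.centroid):
                    assert got == 0.0
                else:
                    brute = np.sqrt(((coords - p.centroid) ** 2).sum(axis=1)).min()
                    assert got == pytest.approx(brute, abs=1e-12)


class TestCoverageReport:
    def make_points(self):
        # 4 spheres fully inside L1, one 3 mm outside the x=49.5 face
        inside = [sln(20 + i, 30, 30) for i in range(4)]
        outside = [sln(52.5, 30, 30)]
        return inside + outside

    def test_counts_pct_and_single_noncovered_footnote(self):
        rows = coverage_report(self.make_points(), [cube_mask()])
        row = next(r for r in rows if r.node_field == "axilla-I-anterior" and r.scope == "corresponding" and r.side == "both")
        assert (row.n, row.n_inside) == (5, 4)
        assert row.pct_inside == pytest.approx(80.0)
        assert row.dist_mean_mm == pytest.approx(3.0, abs=0.5)
        assert row.dist_sd_mm is None  # single non-covered SLN: SD omitted

    def test_distances_omitted_when_all_covered(self):
        rows = coverage_report([sln(30, 30, 30)], [cube_mask()])
        row = next(r for r in rows if r.node_field == "all" and r.scope == "all" and r.side == "both")
        assert row.n_inside == row.n == 1
        assert row.dist_mean_mm is None and row.dist_sd_mm is None

    def test_all_ctvs_coverage_dominates_corresponding(self):
        # L1 misses some anterior SLNs that the (non-corresponding) L2 box catches
        l1 = cube_mask(lo=9.5, hi=29.5, label="L1")
        l2 = cube_mask(lo=29.5, hi=49.5, label="L2")
        pts = [sln(20, 20, 20), sln(40, 40, 40), sln(35, 35, 35)]
        rows = coverage_report(pts, [l1, l2])
        for field in {r.node_field for r in rows}:
            for side in ("both", "L"):
                pair = {
                    r.scope: r.pct_inside
                    for r in rows
                    if r.node_field == field and r.side == side
                }
                if pair:
                    assert pair["all"] >= pair["corresponding"]

    def test_mediastinal_and_interval_excluded(self, caplog):
        pts = [sln(30, 30, 30), sln(30, 30, 30, field="mediastinal"), sln(30, 30, 30, field="interval")]
        rows = coverage_report(pts, [cube_mask()])
        fields = {r.node_field for r in rows}
        assert "mediastinal" not in fields and "interval" not in fields
        all_row = next(r for r in rows if r.node_field == "all" and r.side == "both" and r.scope == "all")
        assert all_row.n == 1

    def test_sides_scored_independently(self):
        left = cube_mask(lo=9.5, hi=29.5, side="L")
        right = cube_mask(lo=29.5, hi=49.5, side="R")
        pts = [sln(20, 20, 20, side="L"), sln(40, 40, 40, side="R"), sln(40, 40, 40, side="L")]
        rows = coverage_report(pts, [left, right])
        both = next(r for r in rows if r.node_field == "all" and r.side == "both" and r.scope == "all")
        # the left SLN at (40,40,40) is not covered by the left CTV
        assert (both.n, both.n_inside) == (3, 2)

    def test_unknown_field_rejected_at_construction(self):
        with pytest.raises(ValueError):
            sln(1, 2, 3, field="axillaIA")


class TestIO:
    def test_mask_roundtrip(self, tmp_path):
        mask = cube_mask()
        path = tmp_path / "mask.nii"
        write_mask(mask, path)
        back = read_mask(path, label="L1", side="L")
        assert back.data.sum() == mask.data.sum()
        assert np.allclose(back.spacing, mask.spacing)
        assert np.allclose(back.origin, mask.origin)
        assert np.allclose(back.direction, mask.direction)

    def test_points_roundtrip(self, tmp_path):
        pts = [sln(12.5, -40.0, 88.2, field="internal-mammary")]
        path = tmp_path / "pts.csv"
        write_points(pts, path)
        back = read_points(path)
        assert back == pts

    def test_header_only_points_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "pts.csv"
        path.write_text("x_mm,y_mm,z_mm,node_field,side\n")
        with pytest.warns(UserWarning):
            assert read_points(path) == []

    def test_correspondence_map_rejects_unknown_field(self):
        with pytest.raises(ValueError):
            CorrespondenceMap(mapping={"axillaIA": frozenset({"L1"})})
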