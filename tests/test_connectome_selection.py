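"""ROI streamline selection, fingerprints, peaks, conjugation, projection."""

import numpy as np
import pytest

from vatmap.connectome_selection import (
    conjugation,
    find_peaks,
    group_fingerprint,
    project_to_surface,
    read_ascii_mesh,
    select_by_sphere,
)
from vatmap.density_mapping import RasterConfig, gaussian_smooth
from vatmap.errors import FormatError, GeometryError, ParameterError
from vatmap.geometry import resample_polyline
from vatmap.spatial_io import DensityVolume, GridSpec, Tractogram
from vatmap.vat_model import StimulationSite

from conftest import make_random_tractogram


def make_site(center, radius=1.0, pid="p0", hemi="L"):
    return StimulationSite(pid, hemi, tuple(center), 1.0, radius)


class TestSelectBySphere:
    def test_far_center_selects_nothing(self, random_tractogram):
        out = select_by_sphere(random_tractogram, (500.0, 500.0, 500.0))
        assert len(out) == 0

    def test_streamline_through_center_selected(self):
        sl = np.array([[-5.0, 1.0, 2.0], [5.0, 1.0, 2.0]])
        out = select_by_sphere(Tractogram([sl]), (0.0, 1.0, 2.0), diameter=2.0)
        assert len(out) == 1
        assert np.array_equal(out.streamlines[0], sl)  # original points preserved

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_distance_oracle(self, seed):
        rng = np.random.default_rng(700 + seed)
        t = make_random_tractogram(rng, n_streamlines=12)
        center = rng.uniform(-15, 15, 3)
        diameter = float(rng.uniform(1.0, 8.0))
        out = select_by_sphere(t, center, diameter)
        expected = []
        for s in t:
            pts = resample_polyline(s, 0.5)
            if np.linalg.norm(pts - center, axis=1).min() <= diameter / 2.0:
                expected.append(s)
        assert len(out) == len(expected)
        for a, b in zip(out, expected):
            assert np.array_equal(a, b)

    def test_monotone_in_diameter(self, rng):
        t = make_random_tractogram(rng, n_streamlines=15)
        center = (0.0, 0.0, 0.0)
        small = {id_ for id_, s in enumerate(t) if any(np.array_equal(s, u) for u in select_by_sphere(t, center, 4.0))}
        large = {id_ for id_, s in enumerate(t) if any(np.array_equal(s, u) for u in select_by_sphere(t, center, 12.0))}
        assert small <= large


class TestGroupFingerprint:
    CFG = RasterConfig(voxel_size=1.0, smoothing_sigma=0.0,
                       bbox=((-30.0,) * 3, (30.0,) * 3), mode="terminal")

    def test_single_selected_streamline_has_mass_two(self):
        sl = np.array([[0.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
        t = Tractogram([sl])
        fp = group_fingerprint(t, [make_site((0.0, 0.0, 0.0))], self.CFG)
        assert fp.total_mass() == 2.0

    def test_disjoint_selections_add(self):
        a = np.array([[0.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
        b = np.array([[20.0, 0.0, 0.0], [20.0, 10.0, 0.0]])
        t = Tractogram([a, b])
        sites = [make_site((0.0, 0.0, 0.0)), make_site((20.0, 0.0, 0.0), pid="p1")]
        fp = group_fingerprint(t, sites, self.CFG)
        assert fp.total_mass() == 4.0

    def test_streamline_selected_by_both_sites_counted_once(self):
        sl = np.array([[0.0, 0.0, 0.0], [0.0, 20.0, 0.0]])
        t = Tractogram([sl])
        sites = [make_site((0.0, 0.0, 0.0)), make_site((0.0, 20.0, 0.0), pid="p1")]
        fp = group_fingerprint(t, sites, self.CFG)
        assert fp.total_mass() == 2.0  # union semantics, not 4

    def test_empty_selection_gives_empty_fingerprint(self):
        t = Tractogram([np.array([[0.0, 0.0, 0.0], [0.0, 10.0, 0.0]])])
        fp = group_fingerprint(t, [make_site((500.0, 0.0, 0.0))], self.CFG)
        assert fp.total_mass() == 0.0


def _impulse_volume(idx, dims=(31, 31, 31), value=1.0):
    grid = GridSpec(origin=(-15.0, -15.0, -15.0), voxel_size=1.0, dims=dims)
    vals = np.zeros(dims)
    vals[idx] = value
    return DensityVolume(grid, vals)


class TestFindPeaks:
    def test_smoothed_impulse_yields_single_peak(self):
        vol = gaussian_smooth(_impulse_volume((15, 15, 15)), 2.0)
        peaks = find_peaks(vol, min_value=1e-6)
        assert len(peaks) == 1
        assert peaks[0].coordinate == pytest.approx((0.0, 0.0, 0.0))

    def test_constant_volume_has_no_peaks(self):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), voxel_size=1.0, dims=(9, 9, 9))
        vol = DensityVolume(grid, np.ones((9, 9, 9)))
        assert find_peaks(vol, min_value=0.5) == []

    def test_two_planted_blobs_recovered(self):
        vol = _impulse_volume((5, 15, 15))
        vol.values[25, 15, 15] = 0.8  # second blob 20 mm away
        sm = gaussian_smooth(vol, 2.0)
        peaks = find_peaks(sm, min_value=1e-6, min_separation_mm=10.0)
        assert len(peaks) == 2
        found = sorted(p.coordinate[0] for p in peaks)
        assert found == pytest.approx([-10.0, 10.0])
        assert peaks[0].value > peaks[1].value  # sorted by value descending

    def test_close_peaks_suppressed_keeping_larger(self):
        vol = _impulse_volume((13, 15, 15))
        vol.values[17, 15, 15] = 2.0  # 4 mm away, larger
        peaks = find_peaks(vol, min_value=0.5, min_separation_mm=6.0)
        assert len(peaks) == 1
        assert peaks[0].coordinate[0] == pytest.approx(2.0)

    def test_scale_invariant_coordinates(self, rng):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), voxel_size=1.0, dims=(15, 15, 15))
        vol = gaussian_smooth(DensityVolume(grid, rng.random((15, 15, 15))), 1.5)
        a = find_peaks(vol, min_value=1e-9)
        b = find_peaks(DensityVolume(grid, 13.0 * vol.values), min_value=13e-9)
        assert [p.coordinate for p in a] == [p.coordinate for p in b]


class TestConjugation:
    def test_identical_volumes_self_pair(self):
        vol = gaussian_smooth(_impulse_volume((15, 15, 15)), 2.0)
        report = conjugation(vol, vol, threshold_quantile=0.5, pairing_mm=2.0)
        assert len(report.peaks_a) == len(report.conjugations) == 1
        pa, pb = report.conjugations[0]
        assert pa.coordinate == pb.coordinate

    def test_disjoint_supports_give_nothing(self):
        va = gaussian_smooth(_impulse_volume((5, 15, 15)), 1.5)
        vb = gaussian_smooth(_impulse_volume((25, 15, 15)), 1.5)
        report = conjugation(va, vb, threshold_quantile=0.9, pairing_mm=5.0)
        assert report.overlap_mask.total_mass() == 0.0
        assert report.conjugations == []

    def test_shared_blob_among_several_is_the_conjugation(self):
        va = _impulse_volume((15, 15, 15))
        va.values[5, 15, 15] = 1.0  # A-only blob
        vb = _impulse_volume((15, 15, 15))
        vb.values[25, 15, 15] = 1.0  # B-only blob
        va, vb = gaussian_smooth(va, 1.5), gaussian_smooth(vb, 1.5)
        report = conjugation(va, vb, threshold_quantile=0.9, pairing_mm=4.0,
                             min_separation_mm=4.0)
        assert len(report.conjugations) == 1
        pa, pb = report.conjugations[0]
        assert pa.coordinate == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)
        assert pb.coordinate == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_grid_mismatch_rejected(self):
        va = _impulse_volume((15, 15, 15))
        grid = GridSpec(origin=(0.0, 0.0, 0.0), voxel_size=1.0, dims=(31, 31, 31))
        vb = DensityVolume(grid, va.values)
        with pytest.raises(GeometryError):
            conjugation(va, vb)


class TestProjectToSurface:
    GRID = GridSpec(origin=(0.0, 0.0, 0.0), voxel_size=2.0, dims=(5, 5, 5))

    def test_constant_volume_projects_constant(self):
        vol = DensityVolume(self.GRID, np.full((5, 5, 5), 1.75))
        verts = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        assert project_to_surface(vol, verts) == pytest.approx([1.75, 1.75])

    def test_vertex_on_voxel_center_exact(self, rng):
        vol = DensityVolume(self.GRID, rng.random((5, 5, 5)))
        out = project_to_surface(vol, np.array([[4.0, 2.0, 6.0]]))  # voxel (2,1,3)
        assert out[0] == pytest.approx(vol.values[2, 1, 3], abs=1e-12)

    def test_midpoint_is_mean_of_neighbors(self, rng):
        vol = DensityVolume(self.GRID, rng.random((5, 5, 5)))
        out = project_to_surface(vol, np.array([[3.0, 2.0, 2.0]]))  # between (1,1,1),(2,1,1)
        assert out[0] == pytest.approx((vol.values[1, 1, 1] + vol.values[2, 1, 1]) / 2, abs=1e-12)

    def test_outside_vertices_get_zero(self, rng):
        vol = DensityVolume(self.GRID, rng.random((5, 5, 5)) + 0.5)
        out = project_to_surface(vol, np.array([[100.0, 0.0, 0.0]]))
        assert out[0] == 0.0

    def test_empty_mesh_rejected(self, rng):
        vol = DensityVolume(self.GRID, rng.random((5, 5, 5)))
        with pytest.raises(ParameterError):
            project_to_surface(vol, np.empty((0, 3)))


class TestAsciiMesh:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "m.mesh"
        path.write_text("3 1\n0 0 0\n1 0 0\n0 1 0\n0 1 2\n")
        verts, faces = read_ascii_mesh(path)
        assert verts.shape == (3, 3)
        assert faces.tolist() == [[0, 1, 2]]

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "bad.mesh"
        path.write_text("3 1\n0 0 0\n1 0 0\n")
        with pytest.raises(FormatError):
            read_ascii_mesh(path)

    def test_out_of_range_face_rejected(self, tmp_path):
        path = tmp_path / "bad2.mesh"
        path.write_text("2 1\n0 0 0\n1 0 0\n0 1 5\n")
        with pytest.raises(FormatError):
            read_ascii_mesh(path)
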