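"""Synthetic-data generators: meshes, ground truth, runs, volumes, clusters."""

import numpy as np
import pytest

from retmap import coding, evaluate as ev, synth, wrap_phase
from retmap.types import AREA_CODES, BAND_ORDER, ParameterError, StimulusParams


class TestBuildFlatPatch:
    @pytest.mark.parametrize(
        "w,h,s,nv,nf",
        [(60, 40, 1, 61 * 41, 4800), (2, 2, 1, 9, 8)],
    )
    def test_grid_counts(self, w, h, s, nv, nf):
        mesh = synth.build_flat_patch(w, h, s)
        assert mesh.n_vertices == nv
        assert mesh.n_faces == nf

    def test_spacing_larger_than_extent_rejected(self):
        with pytest.raises(ParameterError):
            synth.build_flat_patch(10, 10, 20)
        with pytest.raises(ParameterError):
            synth.build_flat_patch(10, 10, 0)

    def test_mesh_invariants_hold(self):
        # validate() checks index ranges, manifoldness and flat areas
        mesh = synth.build_flat_patch(12, 8, 2)
        mesh.validate()
        # the 3-D lift is not trivially the flat embedding
        assert np.any(np.abs(mesh.vertex_xyz[:, 2]) > 1e-6)
        assert np.allclose(mesh.vertex_xyz[:, :2], mesh.vertex_flat)


class TestGroundTruth:
    def test_eccentricity_spans_stimulus_range(self, default_mesh, ground_truth, stim):
        vf, _ = ground_truth
        x = default_mesh.vertex_flat[:, 0]
        assert np.allclose(vf.eccentricity[x == 0], stim.ecc_min_deg)
        assert np.allclose(vf.eccentricity[x == x.max()], stim.ecc_max_deg)

    def test_eccentricity_follows_exponential_law(self, default_mesh, ground_truth, stim):
        vf, _ = ground_truth
        x = default_mesh.vertex_flat[:, 0]
        w = x.max()
        expected = stim.ecc_min_deg * np.exp(
            x / w * np.log(stim.ecc_max_deg / stim.ecc_min_deg)
        )
        assert np.allclose(vf.eccentricity, expected, rtol=1e-12)

    def test_field_signs_alternate_between_adjacent_bands(self, ground_truth):
        _, truth = ground_truth
        signs = []
        for name in BAND_ORDER:
            s = np.unique(truth.sign[truth.labels == AREA_CODES[name]])
            assert s.size == 1  # uniform sign within a band
            signs.append(int(s[0]))
        for a, b in zip(signs, signs[1:]):
            assert a == -b

    def test_v1_strictly_largest(self, ground_truth):
        _, truth = ground_truth
        counts = {
            name: int(np.count_nonzero(truth.labels == AREA_CODES[name]))
            for name in BAND_ORDER
        }
        assert all(counts["V1"] > c for n, c in counts.items() if n != "V1")

    def test_quarter_vs_full_hemifield_coverage(self, ground_truth):
        # bands are half-open toward the next band, so a band of width w
        # sampled at spacing 1 covers its span minus one row's worth —
        # except the last band (V4), whose far edge is inclusive
        vf, truth = ground_truth
        for name, span, width, inclusive in [
            ("V1", np.pi, 16, False),
            ("V4", np.pi, 14, True),
            ("V2v", np.pi / 2, 8, False),
            ("V3d", np.pi / 2, 8, False),
        ]:
            th = vf.polar_angle[truth.labels == AREA_CODES[name]]
            expected = span if inclusive else span * (width - 1) / width
            assert np.ptp(th) == pytest.approx(expected, rel=1e-9)

    def test_v1_not_widest_rejected(self, default_mesh):
        widths = dict(synth.BandLayout().band_widths_mm)
        widths["V4"] = widths["V1"] + 1
        with pytest.raises(ParameterError):
            synth.BandLayout(band_widths_mm=widths)

    def test_unknown_band_rejected(self):
        with pytest.raises(ParameterError):
            synth.BandLayout(band_widths_mm={"V5": 10.0})


class TestSimulateRuns:
    def test_noiseless_forward_phase_is_closed_form(self, noiseless_runs, ground_truth, stim):
        from retmap import phase as ph

        vf, _ = ground_truth
        run = noiseless_runs[("eccentricity", "forward")]
        m = ph.dft_phase_snr(run)
        phi_e = coding.eccentricity_to_phase(vf.eccentricity, stim)
        phi_h = 2 * np.pi * stim.hemo_delay_s / stim.period_s
        expected = wrap_phase(-(phi_e + phi_h))
        ok = vf.valid
        assert np.nanmax(np.abs(wrap_phase(m.phase[ok] - expected[ok]))) < 1e-9

    def test_forward_backward_phases_sum_to_minus_twice_delay(
        self, noiseless_runs, ground_truth, stim
    ):
        # oracle: direct evaluation of the two closed-form phases
        from retmap import phase as ph

        vf, _ = ground_truth
        mf = ph.dft_phase_snr(noiseless_runs[("polar", "forward")])
        mb = ph.dft_phase_snr(noiseless_runs[("polar", "backward")])
        phi_h = 2 * np.pi * stim.hemo_delay_s / stim.period_s
        total = wrap_phase(mf.phase + mb.phase + 2 * phi_h)
        assert np.nanmax(np.abs(total[vf.valid])) < 1e-9

    def test_seeding_contract(self, ground_truth, stim):
        vf, _ = ground_truth
        a = synth.simulate_runs(vf, stim, noise_sd=1.0, seed=3)
        b = synth.simulate_runs(vf, stim, noise_sd=1.0, seed=3)
        c = synth.simulate_runs(vf, stim, noise_sd=1.0, seed=4)
        key = ("polar", "backward")
        assert np.array_equal(a[key].series, b[key].series)
        assert not np.array_equal(a[key].series, c[key].series)


class TestRasterize:
    def test_lone_vertex_voxel_keeps_value(self, small_mesh):
        vals = np.arange(small_mesh.n_vertices, dtype=float)
        grid = synth.rasterize_to_volume(small_mesh, vals, voxel_size_mm=0.5)
        # 0.5 mm voxels on a 2 mm grid: every occupied voxel has one vertex
        got = grid.values[grid.valid]
        assert np.array_equal(np.sort(got), vals)

    def test_circular_mean_of_two_phases(self):
        mesh = synth.build_flat_patch(2, 2, 1)
        phases = np.zeros(mesh.n_vertices)
        phases[1] = np.pi / 2
        grid = synth.rasterize_to_volume(mesh, phases, voxel_size_mm=50.0, circular=True)
        # one voxel holds everything: mean phasor of {0 x8, pi/2 x1}
        expected = np.angle(np.mean(np.exp(1j * phases)))
        assert grid.values[grid.valid][0] == pytest.approx(expected)

    def test_two_phase_voxel_is_bisector(self):
        from retmap.types import SurfaceMesh

        mesh = SurfaceMesh(
            vertex_xyz=np.array([[0.0, 0, 0], [0.2, 0.4, 0], [5.0, 0, 0]]),
            vertex_flat=np.array([[0.0, 0], [0.2, 0.4], [5.0, 0]]),
            faces=np.array([[0, 1, 2]]),
        )
        phases = np.array([0.0, np.pi / 2, 2.0])
        grid = synth.rasterize_to_volume(mesh, phases, voxel_size_mm=1.0, circular=True)
        # the voxel holding the first two vertices averages phasors 0 and pi/2
        assert grid.values[0, 0, 0] == pytest.approx(np.pi / 4)

    def test_affine_round_trip(self, small_mesh):
        grid = synth.rasterize_to_volume(
            small_mesh, np.zeros(small_mesh.n_vertices), voxel_size_mm=3.0
        )
        centers = grid.voxel_centers_mm().reshape(-1, 3)
        idx = grid.mm_to_index(centers)
        expected = np.stack(
            np.meshgrid(*[np.arange(d) for d in grid.dims], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        assert np.array_equal(idx, expected)

    def test_nonpositive_voxel_rejected(self, small_mesh):
        with pytest.raises(ParameterError):
            synth.rasterize_to_volume(small_mesh, np.zeros(small_mesh.n_vertices), 0.0)


class TestActivationClusters:
    @pytest.mark.parametrize("frac,area_ok", [(1.0, {"V4"}), (0.0, {"V2v", "V3v"})])
    def test_pure_fraction_extremes(self, default_mesh, ground_truth, frac, area_ok):
        _, truth = ground_truth
        mask = synth.make_activation_clusters(
            default_mesh, truth, n_clusters=3, fraction_in_v4=frac,
            cluster_radius_mm=3.0, seed=11,
        )
        names = {
            name
            for name in BAND_ORDER
            if np.any(truth.labels[mask.member_ids] == AREA_CODES[name])
        }
        assert names <= area_ok

    def test_clusters_disjoint_and_counted_by_brute_force(self, default_mesh, ground_truth):
        _, truth = ground_truth
        mask = synth.make_activation_clusters(
            default_mesh, truth, n_clusters=4, fraction_in_v4=0.5,
            cluster_radius_mm=3.0, seed=2,
        )
        assert mask.cluster_sizes.sum() == mask.member_ids.size  # pairwise disjoint
        # brute-force: every member is within radius of some cluster's vertices
        flat = default_mesh.vertex_flat
        labels_ventral = np.isin(
            truth.labels[mask.member_ids],
            [AREA_CODES["V2v"], AREA_CODES["V3v"], AREA_CODES["V4"]],
        )
        assert labels_ventral.all()

    def test_impossible_placement_rejected(self, default_mesh, ground_truth):
        _, truth = ground_truth
        with pytest.raises(ParameterError):
            synth.make_activation_clusters(
                default_mesh, truth, n_clusters=50, fraction_in_v4=1.0,
                cluster_radius_mm=5.0, seed=0,
            )

    def test_measured_fraction_tracks_request(self, default_mesh, ground_truth):
        _, truth = ground_truth
        mask = synth.make_activation_clusters(
            default_mesh, truth, n_clusters=4, fraction_in_v4=0.25,
            cluster_radius_mm=3.0, seed=5,
        )
        measured = ev.v4_overlap_fraction(mask, truth)
        one_cluster_pct = 100.0 * mask.cluster_sizes.max() / mask.member_ids.size
        assert abs(measured - 25.0) <= one_cluster_pct


def test_noise_sd_for_snr_matches_measured_snr(ground_truth, stim):
    """The white-noise inversion lands the measured median SNR near target."""
    from retmap import phase as ph

    vf, _ = ground_truth
    sd = synth.noise_sd_for_snr(3.0, 1.0, stim)
    runs = synth.simulate_runs(vf, stim, noise_sd=sd, seed=9)
    m = ph.dft_phase_snr(runs[("eccentricity", "forward")])
    assert np.median(m.snr[vf.valid]) == pytest.approx(3.0, rel=0.15)
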