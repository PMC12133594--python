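"""Stress coarse-graining, fluctuation measures and extrusion statistics."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechcomp import stress_stats as ss
from mechcomp import synthetic as syn


class TestCoarseGrainStress:
    def test_zero_tractions_give_zero_stress(self):
        t = np.zeros((8, 8, 6, 3))
        sf = ss.coarse_grain_stress(t)
        assert np.all(sf.components == 0)

    def test_single_traction_matches_neighbour_enumeration(self):
        # one traction vector T at node p contributes r (x) T / a0^3 to the
        # stress at each of its 2d nearest neighbours q, with r = x_q - x_p
        t = np.zeros((8, 8, 6, 3))
        p = (4, 3, 2)
        T = np.array([1.5, -2.0, 0.7])
        t[p] = T
        sf = ss.coarse_grain_stress(t, spacing=1.0)
        c = sf.components
        expected_nonzero = 0
        for axis, e in enumerate(np.eye(3, dtype=int)):
            for sgn in (+1, -1):
                q = tuple((np.array(p) + sgn * e) % np.array([8, 8, 6]))
                r = sgn * np.eye(3)[axis]
                assert np.allclose(c[q], np.outer(r, T)), (axis, sgn)
                expected_nonzero += 1
        assert np.count_nonzero(np.abs(c).sum(axis=(-1, -2))) == expected_nonzero

    def test_uniform_traction_gives_uniform_stress_2d(self):
        t = np.tile(np.array([2.0, -1.0]), (16, 16, 1))
        sf = ss.coarse_grain_stress(t, periodic=(True, True))
        c = sf.components
        assert np.allclose(c, c[0, 0])

    def test_linearity_in_tractions(self):
        rng = np.random.default_rng(0)
        t1 = rng.standard_normal((6, 6, 4, 3))
        t2 = rng.standard_normal((6, 6, 4, 3))
        s12 = ss.coarse_grain_stress(2 * t1 - 3 * t2).components
        s1 = ss.coarse_grain_stress(t1).components
        s2 = ss.coarse_grain_stress(t2).components
        assert np.allclose(s12, 2 * s1 - 3 * s2, atol=1e-12)


class TestIsotropicStress:
    def test_isotropic_tensor_returns_pressure(self):
        p = np.full((5, 5), 3.25)
        comp = np.zeros((5, 5, 2, 2))
        comp[..., 0, 0] = p
        comp[..., 1, 1] = p
        iso = ss.isotropic_stress(ss.StressField(comp), "2d-half-trace")
        assert np.allclose(iso, 3.25)

    def test_pure_shear_has_zero_isotropic_part(self):
        comp = np.zeros((5, 5, 2, 2))
        comp[..., 0, 0] = 1.0
        comp[..., 1, 1] = -1.0
        comp[..., 0, 1] = comp[..., 1, 0] = 0.4
        assert np.allclose(ss.isotropic_stress(ss.StressField(comp)), 0.0)

    def test_random_field_matches_elementwise_formula(self):
        rng = np.random.default_rng(1)
        comp = rng.standard_normal((4, 4, 3, 3, 3))
        iso = ss.isotropic_stress(ss.StressField(comp), "3d-in-plane")
        assert np.allclose(iso, 0.5 * (comp[..., 0, 0] + comp[..., 1, 1]))

    def test_dimension_mismatch_rejected(self):
        comp = np.zeros((4, 4, 3, 3))
        with pytest.raises(ValueError):
            ss.isotropic_stress(ss.StressField(comp), "2d-half-trace")


class TestSusceptibility:
    def test_constant_field_has_zero_susceptibility(self):
        assert ss.susceptibility(np.full(100, 7.0)) == 0.0

    def test_two_sample_hand_computation(self):
        # chi = N * population variance: {0, 2} has var 1, N = 2
        assert ss.susceptibility(np.array([0.0, 2.0]), N=2) == pytest.approx(2.0)

    def test_iid_normal_sampling_law(self):
        rng = np.random.default_rng(42)
        v = 2.5
        n = 40_000
        x = rng.normal(0.0, np.sqrt(v), n)
        chi = ss.susceptibility(x, N=n)
        assert abs(chi / n - v) < 3 * v * np.sqrt(2 / n)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            ss.susceptibility(np.array([1.0]))

    @given(st.floats(-50, 50), st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_invariance_and_quadratic_scaling(self, shift, scale):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(256)
        chi = ss.susceptibility(x)
        assert ss.susceptibility(x + shift) == pytest.approx(chi, rel=1e-6, abs=1e-9)
        assert ss.susceptibility(scale * x) == pytest.approx(scale**2 * chi, rel=1e-9)


class TestInterfaceGeometry:
    def test_interface_pixels_have_zero_distance(self):
        occ = syn.gen_occupancy_bands((32, 64))
        iface = ss.interface_mask(occ)
        dist = ss.interface_distance_map(occ)
        assert iface.any()
        assert np.all(dist[iface] == 0)

    def test_distance_is_lipschitz_between_neighbours(self):
        occ = syn.gen_occupancy_bands((32, 64), 0.4)
        d = ss.interface_distance_map(occ)
        assert np.all(np.abs(np.diff(d, axis=0)) <= 1.0 + 1e-9)
        assert np.all(np.abs(np.diff(d, axis=1)) <= 1.0 + 1e-9)

    def test_single_population_has_no_interface(self):
        with pytest.raises(ValueError):
            ss.interface_distance_map(np.full((16, 16), 1, dtype=np.int8))


class TestSusceptibilityProfile:
    def test_homogeneous_field_gives_flat_profile(self):
        occ = syn.gen_occupancy_bands((64, 128))
        frames, _ = syn.gen_gaussian_field((64, 128), ell=0.0, n_frames=40, seed=3)
        prof = ss.susceptibility_profile(frames, occ, bin_width=8.0)[2]
        good = prof.counts > 200
        vals = prof.values[good] / prof.counts[good]  # per-pixel variance
        assert vals.max() / vals.min() < 1.5

    def test_interface_variance_boost_is_recovered(self):
        occ = syn.gen_occupancy_bands((64, 128))
        boost, band = 4.0, 16.0
        frames, _ = syn.gen_interface_variance_field(
            (64, 128), occ, boost=boost, band_width=band, n_frames=60, seed=4
        )
        for t in (1, 2):
            prof = ss.susceptibility_profile(frames, occ, bin_width=16.0)[t]
            per_pix = prof.values / prof.counts
            assert np.nanargmax(per_pix) == 0  # peak in the interface bin
            ratio = per_pix[0] / np.nanmean(per_pix[1:][prof.counts[1:] > 200])
            assert ratio == pytest.approx(boost, rel=0.25)

    def test_max_normalization(self):
        occ = syn.gen_occupancy_bands((64, 64))
        frames, _ = syn.gen_gaussian_field((64, 64), ell=0.0, n_frames=10, seed=5)
        prof = ss.susceptibility_profile(frames, occ, bin_width=8.0, normalize=True)[1]
        assert np.nanmax(prof.values) == pytest.approx(1.0)


class TestAutocorrelation:
    def test_white_noise_decorrelates_within_a_pixel(self):
        frames, _ = syn.gen_gaussian_field((128, 128), ell=0.0, n_frames=5, seed=6)
        radii, C, length = ss.autocorrelation_and_length(frames)
        assert C[0] == 1.0
        assert abs(C[1]) < 0.05
        assert length < 2.0

    def test_zero_lag_is_exactly_one(self):
        frames, _ = syn.gen_gaussian_field((64, 64), ell=4.0, n_frames=2, seed=7)
        _, C, _ = ss.autocorrelation_and_length(frames)
        assert C[0] == 1.0

    def test_correlation_length_monotone_in_generator_length(self):
        lengths = {}
        for ell in (4.0, 8.0, 16.0):
            frames, _ = syn.gen_gaussian_field((256, 256), ell=ell, n_frames=4, seed=8)
            lengths[ell] = ss.autocorrelation_and_length(frames)[2]
        assert lengths[4.0] < lengths[8.0] < lengths[16.0]

    def test_mask_too_small_rejected(self):
        frames = np.zeros((1, 16, 16))
        with pytest.raises(ValueError):
            ss.autocorrelation_and_length(frames)


def _toy_trajectory(contacts, zs, xy=None, types=None):
    n_saves, n_cells = contacts.shape
    if xy is None:
        xy = np.zeros((n_saves, n_cells, 2))
    return SimpleNamespace(
        contact_series=np.asarray(contacts, dtype=float),
        z_com_series=np.asarray(zs, dtype=float),
        xy_com_series=np.asarray(xy, dtype=float),
        saved_steps=np.arange(n_saves) * 10,
        cell_ids=np.arange(n_cells),
        cell_types=np.array(types if types is not None else [1] * n_cells),
        config=SimpleNamespace(R0=8.0),
    )


class TestDetectExtrusion:
    def test_cell_lifted_off_substrate_is_flagged_once(self):
        # cell 1 loses contact and rises above the median by > R0/2 at save 2
        contacts = np.array([[10.0, 10.0, 10.0]] * 4)
        contacts[2:, 1] = 0.05
        zs = np.full((4, 3), 12.0)
        zs[2:, 1] = 12.0 + 8.0
        ev = ss.detect_extrusion_sim(_toy_trajectory(contacts, zs))
        assert len(ev) == 1
        assert ev.iloc[0]["id"] == 1 and ev.iloc[0]["step"] == 20

    def test_contact_loss_alone_is_not_an_extrusion(self):
        contacts = np.array([[10.0, 10.0], [10.0, 0.05]])
        zs = np.full((2, 2), 12.0)
        assert len(ss.detect_extrusion_sim(_toy_trajectory(contacts, zs))) == 0

    def test_catalog_invariant_under_id_relabeling(self):
        contacts = np.array([[10.0, 10.0, 10.0]] * 3)
        contacts[1:, 0] = 0.01
        zs = np.full((3, 3), 12.0)
        zs[1:, 0] = 20.0
        t = _toy_trajectory(contacts, zs)
        ev1 = ss.detect_extrusion_sim(t)
        perm = [2, 1, 0]
        t2 = _toy_trajectory(contacts[:, perm], zs[:, perm])
        ev2 = ss.detect_extrusion_sim(t2)
        assert len(ev1) == len(ev2) == 1
        assert ev1.iloc[0]["step"] == ev2.iloc[0]["step"]


class TestExtrusionDistancePdf:
    def test_uniform_catalog_gives_flat_pdf(self):
        occ = syn.gen_occupancy_bands((96, 192))
        cat, _ = syn.gen_extrusion_catalog(occ, 4000, type_label=2, bias="uniform", seed=9)
        prof = ss.extrusion_distance_pdf(cat, occ, bin_width=12.0)[2]
        good = ~np.isnan(prof.values)
        vals = prof.values[good]
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)
        assert vals.max() / vals.min() < 1.35  # flat within multinomial error

    def test_exponential_bias_decay_recovered(self):
        occ = syn.gen_occupancy_bands((128, 256))
        decay = 16.0  # 2 R0 at R0 = 8 px
        rates = []
        for seed in range(4):
            cat, _ = syn.gen_extrusion_catalog(
                occ, 500, type_label=2, bias="exp", decay=decay, seed=seed
            )
            prof = ss.extrusion_distance_pdf(cat, occ, bin_width=8.0)[2]
            good = ~np.isnan(prof.values) & (prof.values > 0)
            x, y = prof.bin_centers[good], np.log(prof.values[good])
            w = prof.counts[good]  # weight by event support
            slope = np.polyfit(x, y, 1, w=np.sqrt(w))[0]
            rates.append(-1.0 / slope)
        assert np.mean(rates) == pytest.approx(decay, rel=0.25)

    def test_pdf_sums_to_one(self):
        occ = syn.gen_occupancy_bands((64, 128))
        cat, _ = syn.gen_extrusion_catalog(occ, 300, type_label=1, seed=10)
        prof = ss.extrusion_distance_pdf(cat, occ, bin_width=10.0)[1]
        assert np.nansum(prof.values) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_null_passes_goodness_of_fit(self):
        occ = syn.gen_occupancy_bands((96, 192))
        hits = 0
        n_trials = 40
        for seed in range(n_trials):
            cat, _ = syn.gen_extrusion_catalog(occ, 400, type_label=2, seed=seed)
            if ss.uniformity_gof_pvalue(cat, occ, bin_width=12.0, type_label=2) > 0.01:
                hits += 1
        assert hits >= int(0.95 * n_trials)


class TestExtrusionRate:
    def test_rate_arithmetic(self):
        # 10 events in 1 h over 0.5 mm^2 -> 20 per h per mm^2
        occ = np.ones((4, 100, 100), dtype=np.int8)
        ev = pd.DataFrame({"frame": np.arange(10) % 4, "x": 5.0, "y": 5.0, "type": 1})
        pixel_area = 0.5 / (100 * 100)  # mm^2 per pixel
        df = ss.extrusion_rate(ev, occ, interval_frames=4, frame_duration=0.25,
                               pixel_area=pixel_area, types=(1,))
        assert df["rate"].iloc[0] == pytest.approx(20.0)

    def test_doubling_area_halves_rate(self):
        occ = np.ones((2, 50, 50), dtype=np.int8)
        ev = pd.DataFrame({"frame": [0, 1], "x": 1.0, "y": 1.0, "type": 1})
        r1 = ss.extrusion_rate(ev, occ, 2, 1.0, pixel_area=1.0, types=(1,))["rate"].iloc[0]
        r2 = ss.extrusion_rate(ev, occ, 2, 1.0, pixel_area=2.0, types=(1,))["rate"].iloc[0]
        assert r1 == pytest.approx(2 * r2)

    def test_field_of_view_area_conversion(self):
        # 10x objective field of view: 0.514188 mm^2
        assert ss.area_from_fraction(1.0) == pytest.approx(0.514188)
        assert ss.area_from_fraction(0.5) == pytest.approx(0.257094)


class TestEnsembleStressMap:
    def test_constant_field_maps_to_constant(self):
        occ = syn.gen_occupancy_bands((64, 64))
        frames = np.full((10, 64, 64), 2.5)
        ev = pd.DataFrame({"frame": [5, 5], "x": [30.0, 34.0], "y": [30.0, 40.0], "type": 2})
        res = ss.ensemble_stress_map(frames, ev, occ, window_half=8, epoch=(-2, -1))
        assert np.allclose(res["map"], 2.5)

    def test_random_positions_on_zero_mean_field_average_out(self):
        rng = np.random.default_rng(11)
        occ = syn.gen_occupancy_bands((128, 128))
        frames = rng.standard_normal((6, 128, 128))
        n = 80
        ev = pd.DataFrame(
            {
                "frame": 4,
                "x": rng.uniform(30, 98, n),
                "y": rng.uniform(30, 98, n),
                "type": 2,
            }
        )
        res = ss.ensemble_stress_map(frames, ev, occ, window_half=6, epoch=(-2, 0),
                                     align=False, reduce="mean")
        n_used = res["n_events"]
        assert abs(res["map"].mean()) < 3.0 / np.sqrt(n_used * 2)

    def test_alignment_puts_opponent_in_fixed_half_plane(self):
        occ = syn.gen_occupancy_bands((128, 128))
        field = np.where(occ == 1, 1.0, -1.0)[None].repeat(8, axis=0)
        # B-type events hugging both interfaces; opponent direction differs
        ev = pd.DataFrame(
            {
                "frame": [4] * 6,
                "x": [28.0, 28.0, 28.0, 99.0, 99.0, 99.0],
                "y": [40.0, 60.0, 80.0] * 2,
                "type": 2,
            }
        )
        res = ss.ensemble_stress_map(field, ev, occ, window_half=10, epoch=(-2, -1))
        m = res["map"]
        h = m.shape[0] // 2
        assert m[h + 3 :].mean() > 0.5  # opponent half
        assert m[: h - 3].mean() < -0.5

    def test_event_near_edge_excluded_and_counted(self):
        occ = syn.gen_occupancy_bands((64, 64))
        frames = np.zeros((6, 64, 64))
        ev = pd.DataFrame({"frame": [4, 4], "x": [2.0, 32.0], "y": [2.0, 32.0], "type": 1})
        res = ss.ensemble_stress_map(frames, ev, occ, window_half=8, epoch=(-2, -1))
        assert res["n_events"] == 1 and res["n_excluded"] == 1


class TestLocalSusceptibilityTimecourse:
    def test_stationary_field_is_flat(self):
        rng = np.random.default_rng(12)
        frames = rng.standard_normal((30, 96, 96))
        ev = pd.DataFrame({"frame": [15, 16], "x": [48.0, 40.0], "y": [48.0, 56.0], "type": 2})
        t, chi = ss.local_susceptibility_timecourse(frames, ev, window_half=20, t_range=(-8, 4))
        assert chi[0] == pytest.approx(1.0)
        assert np.all(np.abs(chi - 1) < 0.25)

    def test_variance_ramp_is_tracked(self):
        rng = np.random.default_rng(13)
        n_frames = 24
        gain = np.linspace(1.0, np.sqrt(3.0), n_frames)  # variance ramps x3
        frames = rng.standard_normal((n_frames, 96, 96)) * gain[:, None, None]
        ev = pd.DataFrame({"frame": [20], "x": [48.0], "y": [48.0], "type": 1})
        t, chi = ss.local_susceptibility_timecourse(frames, ev, window_half=20, t_range=(-20, 0))
        assert chi[0] == pytest.approx(1.0)
        assert chi[-1] == pytest.approx(3.0, rel=0.2)


class TestSigmaZzDistributions:
    def _tensor_frames(self, zz_values, iso_value=-1.0, shape=(16, 16, 4)):
        comps = np.zeros(shape + (3, 3))
        comps[..., 0, 0] = iso_value
        comps[..., 1, 1] = iso_value
        comps[..., 2, 2] = zz_values
        return [ss.StressField(comps)]

    def test_zero_out_of_plane_stress_is_a_point_mass(self):
        occ = syn.gen_occupancy_bands((16, 16))
        out = ss.sigma_zz_distributions(self._tensor_frames(0.0), occ, region_width=8.0)
        assert np.all(out[1]["values"] == 0.0)

    def test_normalization_by_max_inplane_compression(self):
        occ = syn.gen_occupancy_bands((16, 16))
        out = ss.sigma_zz_distributions(self._tensor_frames(2.0, iso_value=-2.0), occ, 8.0)
        # sigma_zz = 2, max in-plane compression = 2 -> normalized value 1
        assert np.allclose(out[2]["values"], 1.0)

    def test_pdf_integrates_to_one(self):
        rng = np.random.default_rng(14)
        comps = np.zeros((32, 32, 4, 3, 3))
        comps[..., 2, 2] = rng.standard_normal((32, 32, 4))
        comps[..., 0, 0] = comps[..., 1, 1] = rng.standard_normal((32, 32, 4))
        occ = syn.gen_occupancy_bands((32, 32))
        out = ss.sigma_zz_distributions([ss.StressField(comps)], occ, 16.0)
        for t in (1, 2):
            hist, edges = out[t]["pdf"], out[t]["edges"]
            assert np.sum(hist * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_2d_input_unsupported(self):
        occ = syn.gen_occupancy_bands((16, 16))
        with pytest.raises(ValueError):
            ss.sigma_zz_distributions(np.zeros((2, 16, 16)), occ, 8.0)


class TestInterfaceConvexity:
    def test_disk_is_convex(self):
        from skimage.draw import disk

        mask = np.zeros((128, 128), dtype=bool)
        mask[disk((64, 64), 45)] = True
        assert ss.interface_convexity(mask) == pytest.approx(1.0, abs=0.02)

    def test_square_is_convex(self):
        mask = np.zeros((96, 96), dtype=bool)
        mask[20:76, 20:76] = True
        assert ss.interface_convexity(mask) == pytest.approx(1.0, abs=0.02)

    def test_star_matches_analytic_perimeter_ratio(self):
        from skimage.draw import polygon

        R, r, n_points = 80.0, 35.0, 4
        ang = np.arange(2 * n_points) * np.pi / n_points
        rad = np.where(np.arange(2 * n_points) % 2 == 0, R, r)
        ys = 100 + rad * np.sin(ang)
        xs = 100 + rad * np.cos(ang)
        mask = np.zeros((200, 200), dtype=bool)
        rr, cc = polygon(ys, xs)
        mask[rr, cc] = True
        side = np.sqrt(R**2 + r**2 - 2 * R * r * np.cos(np.pi / n_points))
        star_perim = 2 * n_points * side
        hull_perim = n_points * R * np.sqrt(2.0) * 2 * np.sin(np.pi / n_points) / np.sqrt(2.0)
        # hull is the square through the 4 outer points: side R*sqrt(2)
        hull_perim = 4 * R * np.sqrt(2.0)
        expected = hull_perim / star_perim
        assert ss.interface_convexity(mask) == pytest.approx(expected, rel=0.03)

    def test_indented_region_scores_below_one(self):
        mask = np.zeros((96, 96), dtype=bool)
        mask[20:76, 20:76] = True
        mask[40:56, 50:76] = False  # bite out of one side
        assert ss.interface_convexity(mask) < 0.95

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:15, 5:15] = True
        mask[40:50, 40:50] = True
        with pytest.raises(ValueError):
            ss.interface_convexity(mask)
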