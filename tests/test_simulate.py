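"""Simulator: telegraph switching, image formation, structures, titrations."""

import numpy as np
import pytest
from scipy import stats

from blinkkit.camera import CameraModel
from blinkkit.errors import InvalidParameterError
from blinkkit.simulate import (
    EmitterTruth, StructureSpec, always_on_trace, duty_from_ph,
    generate_titration, make_structure, rates_for_duty, render_movie,
    sample_csr_sphere, simulate_switching, traces_to_localizations,
)

from oracles import point_to_polyline_distance


class TestSwitching:
    def test_absorbing_off_state(self):
        tr = simulate_switching(0.0, 100.0, 1.0, initial_state="off", seed=0)
        assert tr.intervals == ()

    def test_absorbing_on_state(self):
        tr = simulate_switching(10.0, 0.0, 2.5, initial_state="on", seed=0)
        assert tr.intervals == ((0.0, 2.5),)

    def test_mean_on_dwell_matches_rate(self):
        # rate_off = 100/s -> mean on-time 10 ms; compare the sample mean
        # of >= 1e4 interior dwells with the oracle: direct exponential
        # draws from the same generator seed.
        rate_on, rate_off = 1000.0, 100.0
        tr = simulate_switching(rate_on, rate_off, 200.0, seed=42)
        dwells = np.array([t1 - t0 for t0, t1 in tr.intervals[:-1]])
        assert dwells.size >= 10_000
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 0.01) < 2 * se + 1e-12

    def test_on_dwells_are_exponential(self):
        # KS test against Exponential(rate_off) must not reject at alpha=.01
        tr = simulate_switching(500.0, 100.0, 300.0, seed=7)
        dwells = np.array([t1 - t0 for t0, t1 in tr.intervals[:-1]])
        assert dwells.size >= 10_000
        p = stats.kstest(dwells, "expon", args=(0, 0.01)).pvalue
        assert p > 0.01

    def test_seed_determinism(self):
        a = simulate_switching(5.0, 50.0, 20.0, seed=123)
        b = simulate_switching(5.0, 50.0, 20.0, seed=123)
        assert a == b

    @pytest.mark.parametrize("bad", [dict(rate_on=-1, rate_off=1,
                                          duration=1),
                                     dict(rate_on=1, rate_off=1,
                                          duration=0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            simulate_switching(**bad)


class TestDutyFromPh:
    def test_midpoint_is_unity(self):
        assert duty_from_ph(5.15, 1.0, 5.15) == 1.0

    def test_two_units_above_pka_gives_one_percent(self):
        assert duty_from_ph(5.15, 1.0, 7.15) == pytest.approx(1e-2)

    def test_strictly_decreasing_in_ph(self, rng):
        ph = np.sort(rng.uniform(2, 10, 50))
        r = duty_from_ph(5.0, 1.3, ph)
        assert np.all(np.diff(r) < 0)

    def test_rates_reproduce_requested_duty_exactly(self):
        for duty in [1e-4, 1e-3, 1e-2]:
            r_on, r_off = rates_for_duty(duty, 0.01)
            assert r_on / r_off == pytest.approx(duty, rel=1e-12)
            assert 1.0 / r_off == pytest.approx(0.01)

    def test_invalid_hill(self):
        with pytest.raises(InvalidParameterError):
            duty_from_ph(5.0, 0.0, 7.0)


class TestRenderMovie:
    def test_empty_scene_is_pure_offset(self, clean_camera):
        st = render_movie([], [], 130.0, clean_camera, 5, (16, 16),
                          noise=False)
        assert np.all(st.data == clean_camera.offset)

    def test_photon_conservation(self, clean_camera):
        # frame sum minus offset = photon_rate * exposure * QE * conversion
        em = EmitterTruth(800.0, 810.0, 0, 0, 0, 1e5)
        st = render_movie([em], [always_on_trace(0.05)], 130.0,
                          clean_camera, 5, (16, 16), noise=False)
        expect = 1e5 * clean_camera.exposure
        got = st.data[0].sum() - clean_camera.offset * 256
        assert got == pytest.approx(expect, rel=5e-3)

    def test_dark_frames_are_background_only(self, clean_camera):
        # emitter on only during frames 10-12; other frames must be
        # statistically indistinguishable from background
        from blinkkit.simulate import SwitchTrace
        tr = SwitchTrace(((0.10, 0.13),), 0.3)
        em = EmitterTruth(800.0, 800.0, 0, 0, 0, 1e5)
        rng = np.random.default_rng(0)
        sums_dark, sums_bg = [], []
        for _ in range(100):
            st = render_movie([em], [tr], 130.0, clean_camera, 30, (16, 16),
                              background=5.0, noise=True, seed=rng)
            tot = st.data.sum(axis=(1, 2))
            sums_dark.append(tot[:10].mean())
            sums_bg.append(tot[15:].mean())
            assert tot[10:13].min() > tot[:10].max()  # signal frames brighter
        diff = np.mean(sums_dark) - np.mean(sums_bg)
        se = np.std(sums_dark) / 10
        assert abs(diff) < 3 * se

    def test_mismatched_traces_rejected(self, clean_camera):
        with pytest.raises(InvalidParameterError):
            render_movie([EmitterTruth(0, 0)], [], 130.0, clean_camera,
                         5, (8, 8))

    def test_em_gain_scales_expectation(self):
        cam = CameraModel(pixel_size=100, exposure=0.01, cycle=0.01,
                          em_gain=50.0, quantum_efficiency=1.0,
                          read_noise=0.0, offset=0.0, conversion=1.0)
        em = EmitterTruth(400, 400, 0, 0, 0, 1e4)
        st = render_movie([em], [always_on_trace(0.01)], 130.0, cam, 1,
                          (8, 8), noise=False)
        assert st.data.sum() == pytest.approx(1e4 * 0.01 * 50.0, rel=5e-3)


class TestStructures:
    def test_sphere_points_inside_radius(self):
        spec = StructureSpec("sphere_volume", n=1000, radius=500.0)
        pts = make_structure(spec, seed=1)
        assert np.all(np.linalg.norm(pts, axis=1) <= 500.0 + 1e-9)

    def test_point_field_count_from_density(self):
        # 10 emitters/um^2 over 2 um x 3 um -> 60 points
        spec = StructureSpec("point_field", field_size=(2000.0, 3000.0),
                             density=10.0)
        pts = make_structure(spec, seed=2)
        assert len(pts) == 60

    def test_filament_points_near_polyline(self, rng):
        # >= 99% of points within 3x the stated width of some filament;
        # oracle: exact point-to-polyline distance on regenerated lines
        from blinkkit.simulate import _filament_polyline
        spec = StructureSpec("filaments", field_size=(5000.0, 5000.0),
                             n=500, n_filaments=4, filament_width=50.0)
        seed = 99
        pts = make_structure(spec, seed=seed)
        gen = np.random.default_rng(seed)
        lines = [_filament_polyline(gen, 5000.0, 5000.0) for _ in range(4)]
        dists = [min(point_to_polyline_distance(p[:2], pl) for pl in lines)
                 for p in pts]
        assert np.mean(np.array(dists) <= 3 * 50.0) >= 0.99

    def test_unknown_pattern_rejected(self):
        with pytest.raises(InvalidParameterError):
            StructureSpec("helix", n=10)


class TestCsrSphere:
    def test_all_inside(self):
        pts = sample_csr_sphere(500, 800.0, seed=3)
        assert np.all(np.linalg.norm(pts, axis=1) <= 800.0)

    def test_inner_half_radius_volume_fraction(self):
        n = 8000
        pts = sample_csr_sphere(n, 1000.0, seed=4)
        inner = np.sum(np.linalg.norm(pts, axis=1) <= 500.0)
        se = np.sqrt(n * (1 / 8) * (7 / 8))
        assert abs(inner - n / 8) < 3 * se

    def test_invalid_n(self):
        with pytest.raises(InvalidParameterError):
            sample_csr_sphere(0, 100.0)


class TestTitrationGenerator:
    def test_midpoint_value(self):
        c = generate_titration(5.0, 1.0, 1.0, 0.2, [3.0, 4.0, 5.0, 6.0])
        assert c.absorbance[2] == pytest.approx(0.6)

    def test_acid_limit_is_a_max(self):
        c = generate_titration(5.0, 1.0, 0.9, 0.1, [-20.0, 4.0, 5.0, 6.0])
        assert c.absorbance[0] == pytest.approx(0.9)

    def test_noise_sd_calibration(self, rng):
        reps = np.array([generate_titration(5.0, 1.0, 10.0, 1.0,
                                            [4.0, 5.0, 6.0, 7.0],
                                            noise_sd=0.05, seed=rng
                                            ).absorbance
                         for _ in range(3000)])
        sds = reps.std(axis=0)
        assert np.all(np.abs(sds - 0.05) < 0.1 * 0.05)

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_titration(5.0, 1.0, 1.0, 0.0, [])


class TestTracesToLocalizations:
    def test_every_overlapped_frame_yields_one_row(self, slow_camera):
        from blinkkit.simulate import SwitchTrace
        tr = SwitchTrace(((0.030, 0.070),), 0.27)  # frames 1 and 2
        df = traces_to_localizations([[0.0, 0.0, 0.0]], [tr], slow_camera,
                                     10, loc_sigma=0.0, seed=0)
        assert sorted(df["frame"]) == [1, 2]
        assert df.attrs["cycle_s"] == slow_camera.cycle
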