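"""Spot detection, MLE fitting, filtering, drift correction, rendering."""

import numpy as np
import pandas as pd
import pytest

from blinkkit.errors import InsufficientDataError, InvalidParameterError
from blinkkit.localize import (
    FiducialTrack, correct_drift, detect_spots, filter_localizations,
    find_fiducials, fit_spot, localize_stack, render,
)
from blinkkit.simulate import EmitterTruth, always_on_trace, render_movie, \
    simulate_switching, rates_for_duty


def one_spot_stack(camera, photons_per_frame, pos=(3210.0, 3170.0),
                   background=0.0, noise=False, n_frames=1, seed=None,
                   shape=(64, 64), psf_sigma=200.0):
    em = EmitterTruth(pos[0], pos[1], 0, 0, 0,
                      photons_per_frame / camera.exposure)
    return render_movie([em], [always_on_trace(n_frames * camera.cycle)],
                        psf_sigma, camera, n_frames, shape,
                        background=background, noise=noise, seed=seed)


class TestDetect:
    def test_uniform_frame_gives_nothing(self):
        assert len(detect_spots(np.full((32, 32), 100.0))) == 0

    def test_single_snr10_spot_found_within_one_pixel(self, clean_camera):
        st = one_spot_stack(clean_camera, 500.0, background=5.0,
                            noise=True, seed=5)
        cands = detect_spots(st.data[0], dog_sigma=1.2, dynamic_factor=1.7)
        assert len(cands) == 1
        assert abs(cands[0][0] - 31.5) <= 1.5 and abs(cands[0][1] - 32) <= 1.5

    def test_two_separated_spots(self, clean_camera):
        ems = [EmitterTruth(1000, 1000, 0, 0, 0, 5e4),
               EmitterTruth(3000, 3000, 0, 0, 0, 5e4)]
        st = render_movie(ems, [always_on_trace(0.01)] * 2, 200.0,
                          clean_camera, 1, (64, 64), background=5.0,
                          noise=True, seed=6)
        assert len(detect_spots(st.data[0])) == 2


class TestFit:
    def test_noiseless_fit_is_exact(self, clean_camera):
        st = one_spot_stack(clean_camera, 1000.0)
        loc = fit_spot(st.data[0], (31, 32), clean_camera, sigma_start=2.0)
        assert loc["fit_ok"]
        assert abs(loc["x_nm"] - 3210.0) < 1.0   # 0.01 px
        assert abs(loc["y_nm"] - 3170.0) < 1.0
        assert loc["photons"] == pytest.approx(1000.0, rel=0.01)

    def test_pure_background_roi_flagged(self, clean_camera, rng):
        frame = rng.poisson(5.0, (32, 32)) + clean_camera.offset
        loc = fit_spot(frame.astype(float), (16, 16), clean_camera)
        assert (not loc["fit_ok"]) or loc["photons"] < 30.0

    def test_edge_candidate_dropped(self, clean_camera):
        st = one_spot_stack(clean_camera, 1000.0)
        loc = fit_spot(st.data[0], (1, 1), clean_camera, roi_size=7)
        assert not loc["fit_ok"]

    def test_reported_uncertainty_tracks_empirical_sd(self, clean_camera):
        # Monte-Carlo: empirical SD of fitted x within 20% of the mean
        # reported Mortensen uncertainty (N=500, bg=5)
        rng = np.random.default_rng(17)
        errs, uncs = [], []
        for _ in range(400):
            st = one_spot_stack(clean_camera, 500.0, background=5.0,
                                noise=True, seed=rng, psf_sigma=130.0)
            loc = fit_spot(st.data[0], (31, 32), clean_camera,
                           sigma_start=1.3)
            errs.append(loc["x_nm"] - 3210.0)
            uncs.append(loc["uncertainty_nm"])
        assert np.std(errs) == pytest.approx(np.mean(uncs), rel=0.20)

    def test_rmse_tracks_mortensen_bound_across_photon_counts(
            self, clean_camera):
        rng = np.random.default_rng(31)
        for n_ph in (200, 500, 2000):
            errs, uncs = [], []
            for _ in range(150):
                st = one_spot_stack(clean_camera, n_ph, background=5.0,
                                    noise=True, seed=rng, psf_sigma=130.0)
                loc = fit_spot(st.data[0], (31, 32), clean_camera,
                               sigma_start=1.3)
                errs.append(loc["x_nm"] - 3210.0)
                uncs.append(loc["uncertainty_nm"])
            rmse = float(np.sqrt(np.mean(np.square(errs))))
            assert rmse == pytest.approx(np.mean(uncs), rel=0.25)


class TestFilter:
    def make(self, unc, ph):
        return pd.DataFrame({
            "frame": range(len(unc)), "x_nm": 0.0, "y_nm": 0.0,
            "z_nm": np.nan, "sigma_nm": 130.0, "photons": ph,
            "background": 1.0, "uncertainty_nm": unc,
            "fit_ok": True})

    def test_quoted_thresholds(self):
        # <40 nm and >100 photons keep/drop exactly as stated
        t = self.make([39.0, 41.0, 39.0], [150.0, 500.0, 90.0])
        kept, rep = filter_localizations(t, 40.0, 100.0)
        assert list(kept.index) == [0]
        assert rep["removed_uncertainty"] == 1
        assert rep["removed_photons"] == 1

    def test_empty_table(self):
        kept, rep = filter_localizations(self.make([], []), 40.0, 100.0)
        assert len(kept) == 0 and rep["n_in"] == 0

    def test_idempotent(self):
        t = self.make(np.linspace(5, 80, 30), np.linspace(10, 500, 30))
        once, _ = filter_localizations(t, 40.0, 100.0)
        twice, rep = filter_localizations(once, 40.0, 100.0)
        pd.testing.assert_frame_equal(once, twice)
        assert rep["n_in"] == rep["n_out"]


class TestDrift:
    def table_with_drift(self, drift, n_frames, fid_pos, noise_sd=0.0,
                         rng=None):
        rows = []
        for k in range(n_frames):
            for fx, fy in fid_pos:
                dx = dy = 0.0
                if noise_sd and rng is not None:
                    dx, dy = rng.normal(0, noise_sd, 2)
                rows.append((k, fx + drift[k, 0] + dx,
                             fy + drift[k, 1] + dy))
        df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])
        df["photons"] = 1000.0
        return df

    def test_linear_drift_cancels_exactly(self):
        n = 1000
        drift = np.column_stack([0.5 * np.arange(n), -0.2 * np.arange(n)])
        df = self.table_with_drift(drift, n, [(5000.0, 5000.0)])
        tracks = find_fiducials(df, n)
        assert len(tracks) == 1
        corr, est = correct_drift(df, tracks)
        resid = corr[corr["frame"] >= 0]["x_nm"].to_numpy() - \
            corr["x_nm"].to_numpy().mean()
        assert np.sqrt(np.mean(resid ** 2)) < 0.1

    def test_zero_drift_leaves_coordinates(self):
        n = 200
        drift = np.zeros((n, 2))
        df = self.table_with_drift(drift, n, [(1000.0, 2000.0)])
        corr, est = correct_drift(df, find_fiducials(df, n))
        assert np.allclose(corr["x_nm"], 1000.0, atol=1e-9)
        assert np.allclose(est, 0.0)

    def test_no_fiducials_is_an_error(self):
        df = self.table_with_drift(np.zeros((10, 2)), 10, [(0.0, 0.0)])
        with pytest.raises(InsufficientDataError):
            correct_drift(df, [])

    def test_random_walk_drift_reduced(self):
        # 3 noisy fiducials, random-walk drift: corrected RMS beats
        # uncorrected in >= 29/30 seeded repeats
        wins = 0
        n = 600
        for seed in range(30):
            rng = np.random.default_rng(seed)
            drift = np.cumsum(rng.normal(0, 1.0, (n, 2)), axis=0)
            fids = [(2000.0, 2000.0), (20000.0, 4000.0), (9000.0, 18000.0)]
            df = self.table_with_drift(drift, n, fids, noise_sd=5.0,
                                       rng=rng)
            tracks = find_fiducials(df, n)
            corr, est = correct_drift(df, tracks, smooth_window=50)
            resid = est - (drift - drift.mean(axis=0))
            rms_corr = np.sqrt(np.mean(resid ** 2))
            rms_raw = np.sqrt(np.mean((drift - drift.mean(axis=0)) ** 2))
            wins += rms_corr < rms_raw
        assert wins >= 29


class TestRender:
    def table(self, rng, n=500):
        return pd.DataFrame({
            "frame": np.zeros(n, int),
            "x_nm": rng.uniform(0, 2000, n),
            "y_nm": rng.uniform(0, 2000, n),
            "uncertainty_nm": rng.uniform(8, 25, n)})

    def test_histogram_conserves_counts(self, rng):
        t = self.table(rng)
        img = render(t, "histogram", 20.0, bounds=(0, 2000, 0, 2000))
        assert img.sum() == len(t)

    def test_ash_conserves_counts(self, rng):
        t = self.table(rng)
        img = render(t, "ash", 20.0, magnification=3, shift=1,
                     bounds=(-200, 2200, -200, 2200))
        assert img.sum() == pytest.approx(len(t), rel=1e-6)

    def test_gaussian_integral_matches_count(self, rng):
        t = self.table(rng, n=200)
        img = render(t, "gaussian", 10.0, bounds=(-300, 2300, -300, 2300))
        assert img.sum() == pytest.approx(len(t), rel=0.01)

    def test_empty_table_renders_zeros(self):
        img = render(pd.DataFrame(columns=["frame", "x_nm", "y_nm"]),
                     "histogram", 10.0, bounds=(0, 100, 0, 100))
        assert img.shape == (10, 10) and not img.any()

    def test_invalid_pixel(self, rng):
        with pytest.raises(InvalidParameterError):
            render(self.table(rng), "histogram", 0.0)


class TestEndToEnd:
    def test_recall_on_sparse_blinking_movie(self, clean_camera):
        # SNR ~10 sparse movie: >= 95% of true on-frames recovered within
        # 50 nm; < 2% spurious localizations
        rng = np.random.default_rng(8)
        r_on, r_off = rates_for_duty(0.05, 0.03)
        n_frames = 120
        pos = np.array([[1200.0, 1400.0], [4200.0, 1100.0],
                        [2500.0, 4600.0], [5200.0, 4200.0]])
        ems = [EmitterTruth(x, y, 0, r_on, r_off, 500.0 / 0.01)
               for x, y in pos]
        trs = [simulate_switching(r_on, r_off, n_frames * 0.01, seed=rng)
               for _ in ems]
        st = render_movie(ems, trs, 150.0, clean_camera, n_frames, (64, 64),
                          background=5.0, noise=True, seed=rng)
        table = localize_stack(st)
        table, _ = filter_localizations(table, 40.0, 100.0)
        truth = []
        for i, tr in enumerate(trs):
            on = tr.on_seconds_per_frame(n_frames, clean_camera.exposure,
                                         clean_camera.cycle)
            truth += [(k, i) for k, sec in on.items()
                      if sec > 0.5 * clean_camera.exposure]
        hits = 0
        for k, i in truth:
            sub = table[np.abs(table["frame"] - k) <= 1]
            d = np.hypot(sub["x_nm"] - pos[i, 0], sub["y_nm"] - pos[i, 1])
            hits += bool((d < 50.0).any())
        assert hits / len(truth) >= 0.95
        d_all = np.min(np.hypot(
            table["x_nm"].to_numpy()[:, None] - pos[None, :, 0],
            table["y_nm"].to_numpy()[:, None] - pos[None, :, 1]), axis=1)
        assert np.mean(d_all > 150.0) < 0.02
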