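"""Spot detection, Poisson-MLE fitting, filtering, drift correction, rendering.

The localization table — the lingua franca of the downstream stages — is a
:class:`pandas.DataFrame` with columns ``frame`` (0-based int), ``x_nm``,
``y_nm``, ``z_nm`` (NaN for 2D), ``sigma_nm``, ``photons``, ``background``
(photons/pixel), ``uncertainty_nm`` (lateral precision sigma) and
``fit_ok`` (bool).  Acquisition metadata (``pixel_nm``, ``cycle_s``)
travels in ``DataFrame.attrs``.

A single fitter (maximum-likelihood, integrated-Gaussian PSF, Poisson
noise) serves both the fast (2-ms) and slow (25-ms) acquisition styles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.ndimage import gaussian_filter, uniform_filter1d
from scipy.special import erf
from skimage.feature import peak_local_max
from sklearn.cluster import DBSCAN

from .camera import CameraModel
from .errors import InvalidParameterError, InsufficientDataError
from .simulate import FrameStack

__all__ = [
    "LOCALIZATION_COLUMNS", "empty_table", "detect_spots", "fit_spot",
    "localize_stack", "filter_localizations", "FiducialTrack",
    "find_fiducials", "correct_drift", "render",
]

LOCALIZATION_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "sigma_nm",
                        "photons", "background", "uncertainty_nm", "fit_ok"]


def empty_table(pixel_nm: float | None = None,
                cycle_s: float | None = None) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="float64")
                       for c in LOCALIZATION_COLUMNS})
    df["frame"] = df["frame"].astype(int)
    df["fit_ok"] = df["fit_ok"].astype(bool)
    if pixel_nm is not None:
        df.attrs["pixel_nm"] = pixel_nm
    if cycle_s is not None:
        df.attrs["cycle_s"] = cycle_s
    return df


def detect_spots(frame: np.ndarray, dog_sigma: float = 1.2,
                 dynamic_factor: float = 1.7,
                 min_distance: int | None = None) -> np.ndarray:
    """Difference-of-Gaussians blob candidates in one frame.

    The frame is band-passed with Gaussians of sigma and 2*sigma; local
    maxima of the filtered frame above ``dynamic_factor`` times a robust
    noise scale (1.4826 * median absolute deviation of the *raw* frame)
    survive, with non-maximum suppression within roughly one PSF radius.
    Measuring the noise on the raw frame keeps the threshold meaningful:
    the band-pass attenuates white noise several-fold, so a factor of 1.7
    on the raw scale corresponds to a comfortably strict cut on the
    filtered scale.

    Returns an (n, 2) int array of (row, col) candidates.
    """
    if dog_sigma <= 0 or dynamic_factor <= 0:
        raise InvalidParameterError("dog_sigma and dynamic_factor must be > 0")
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim != 2:
        raise InvalidParameterError("frame must be 2-D")
    dog = gaussian_filter(f, dog_sigma) - gaussian_filter(f, 2.0 * dog_sigma)
    if np.ptp(dog) == 0:  # constant frame: nothing to detect
        return np.empty((0, 2), dtype=int)
    med = float(np.median(dog))
    noise = 1.4826 * float(np.median(np.abs(f - np.median(f))))
    # noiseless synthetic frames have zero MAD; use a tiny fraction of the
    # dynamic range as the noise floor so real structure still registers
    noise = max(noise, 1e-6 * float(np.ptp(dog)))
    if min_distance is None:
        min_distance = max(1, int(round(2.0 * dog_sigma)))
    return peak_local_max(dog, min_distance=min_distance,
                          threshold_abs=med + dynamic_factor * noise,
                          exclude_border=False)


def _model_roi(params, nx, ny, sigma_px):
    x, y, n_ph, bg = params
    s = sigma_px * math.sqrt(2.0)
    ex = 0.5 * np.diff(erf((np.arange(nx + 1) - x) / s))
    ey = 0.5 * np.diff(erf((np.arange(ny + 1) - y) / s))
    return n_ph * np.outer(ey, ex) + bg


def _mortensen_sigma(n_photons: float, bg_per_px: float, sigma_nm: float,
                     pixel_nm: float) -> float:
    """Mortensen MLE lateral precision (nm) for an integrated-Gaussian fit."""
    sa2 = sigma_nm ** 2 + pixel_nm ** 2 / 12.0
    tau = 2.0 * math.pi * sa2 * max(bg_per_px, 0.0) / (n_photons * pixel_nm ** 2)
    var = sa2 / n_photons * (1.0 + 4.0 * tau
                             + math.sqrt(2.0 * tau / (1.0 + 4.0 * tau))
                             if tau > 0 else 1.0)
    return math.sqrt(var)


def fit_spot(frame: np.ndarray, candidate, camera: CameraModel,
             roi_size: int = 7, sigma_start: float = 2.0,
             max_iterations: int = 25, fit_sigma: bool = False) -> dict:
    """Poisson maximum-likelihood fit of one candidate spot.

    Fits position, photon count and per-pixel background of an
    integrated-Gaussian PSF on a ``roi_size`` square ROI; the PSF width is
    fixed at ``sigma_start`` pixels unless ``fit_sigma``.  ADU are converted
    to detected photons via offset, conversion gain, EM gain and quantum
    efficiency before fitting.  The returned ``uncertainty_nm`` is the
    Mortensen MLE precision from the fitted photons, background and width.

    Returns a localization-row dict; ``fit_ok`` is False when the ROI
    leaves the frame, the optimizer fails, or the photon count is not
    positive.
    """
    r, c = int(candidate[0]), int(candidate[1])
    half = roi_size // 2
    h, w = frame.shape
    px = camera.pixel_size

    def failed():
        return dict(frame=0, x_nm=(c + 0.5) * px, y_nm=(r + 0.5) * px,
                    z_nm=np.nan, sigma_nm=sigma_start * px, photons=0.0,
                    background=0.0, uncertainty_nm=np.nan, fit_ok=False)

    if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
        return failed()
    roi = np.asarray(frame[r - half:r + half + 1, c - half:c + half + 1],
                     dtype=np.float64)
    gain = camera.conversion * camera.em_gain * camera.quantum_efficiency
    photons = np.clip((roi - camera.offset) / gain, 0.0, None)

    bg0 = float(np.median(np.concatenate([photons[0], photons[-1],
                                          photons[:, 0], photons[:, -1]])))
    n0 = max(float(photons.sum() - bg0 * roi.size), 1.0)
    p0 = [half + 0.5, half + 0.5, n0, max(bg0, 1e-3)]
    bounds = [(0.0, roi_size), (0.0, roi_size), (1e-6, None), (0.0, None)]
    if fit_sigma:
        p0.append(sigma_start)
        bounds.append((0.3, roi_size))

    def nll(p):
        sig = p[4] if fit_sigma else sigma_start
        mu = np.clip(_model_roi(p[:4], roi_size, roi_size, sig), 1e-9, None)
        return float(np.sum(mu - photons * np.log(mu)))

    res = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iterations})
    p = res.x
    sig_px = p[4] if fit_sigma else sigma_start
    if not np.isfinite(res.fun) or p[2] <= 0:
        return failed()
    bg = float(p[3])
    unc = _mortensen_sigma(float(p[2]), bg, sig_px * px, px)
    return dict(frame=0,
                x_nm=(c - half + p[0]) * px,
                y_nm=(r - half + p[1]) * px,
                z_nm=np.nan, sigma_nm=sig_px * px, photons=float(p[2]),
                background=bg, uncertainty_nm=unc, fit_ok=True)


def localize_stack(stack: FrameStack, dog_sigma: float = 1.2,
                   dynamic_factor: float = 1.7, roi_size: int = 7,
                   sigma_start: float = 2.0, max_iterations: int = 25,
                   fit_sigma: bool = False) -> pd.DataFrame:
    """Detect and fit blink events in every frame of a movie.

    Candidates whose ROI exits the frame are dropped (and counted in
    ``df.attrs['n_edge_dropped']``).
    """
    cam = stack.camera
    rows = []
    n_edge = 0
    for k in range(stack.n_frames):
        frame = stack.data[k]
        for cand in detect_spots(frame, dog_sigma, dynamic_factor):
            half = roi_size // 2
            if (cand[0] - half < 0 or cand[1] - half < 0
                    or cand[0] + half >= frame.shape[0]
                    or cand[1] + half >= frame.shape[1]):
                n_edge += 1
                continue
            loc = fit_spot(frame, cand, cam, roi_size, sigma_start,
                           max_iterations, fit_sigma)
            loc["frame"] = k
            rows.append(loc)
    df = (pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS) if rows
          else empty_table())
    df["frame"] = df["frame"].astype(int)
    df["fit_ok"] = df["fit_ok"].astype(bool)
    df.attrs["pixel_nm"] = cam.pixel_size
    df.attrs["cycle_s"] = cam.cycle
    df.attrs["n_edge_dropped"] = n_edge
    return df


def filter_localizations(table: pd.DataFrame, max_uncertainty: float = 40.0,
                         min_photons: float = 100.0,
                         ) -> tuple[pd.DataFrame, dict]:
    """Keep well-localized, bright rows; report per-criterion removals.

    Keeps rows with ``uncertainty_nm < max_uncertainty`` and
    ``photons > min_photons`` (and ``fit_ok``); row order is preserved.
    The operation is idempotent.
    """
    if len(table) == 0:
        return table.copy(), {"n_in": 0, "removed_fit": 0,
                              "removed_uncertainty": 0,
                              "removed_photons": 0, "n_out": 0}
    ok = table["fit_ok"].astype(bool) if "fit_ok" in table else pd.Series(
        True, index=table.index)
    good_unc = table["uncertainty_nm"] < max_uncertainty
    good_ph = table["photons"] > min_photons
    keep = ok & good_unc & good_ph
    report = {
        "n_in": int(len(table)),
        "removed_fit": int((~ok).sum()),
        "removed_uncertainty": int((ok & ~good_unc).sum()),
        "removed_photons": int((ok & good_unc & ~good_ph).sum()),
        "n_out": int(keep.sum()),
    }
    out = table[keep].copy()
    out.attrs.update(table.attrs)
    return out, report


@dataclass
class FiducialTrack:
    """Per-frame (x, y) nm of one always-on marker, gap-interpolated."""

    xy: np.ndarray            # (n_frames, 2), nm
    completeness: float       # fraction of frames with a direct observation

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise InvalidParameterError("xy must be (n_frames, 2)")


def find_fiducials(table: pd.DataFrame, n_frames: int,
                   min_presence: float = 0.95,
                   search_radius: float = 300.0) -> list[FiducialTrack]:
    """Identify always-on markers in a localization table.

    Localizations are clustered spatially (radius ``search_radius``); a
    cluster observed in more than ``min_presence`` of all frames is taken
    as a fiducial.  Frames with several member localizations contribute
    their mean; frames with none are linearly interpolated.
    """
    if len(table) == 0:
        return []
    xy = table[["x_nm", "y_nm"]].to_numpy(float)
    labels = DBSCAN(eps=search_radius, min_samples=1).fit(xy).labels_
    frames = table["frame"].to_numpy(int)
    tracks = []
    for lab in np.unique(labels):
        sel = labels == lab
        fr = frames[sel]
        n_present = np.unique(fr).size
        if n_present <= min_presence * n_frames:
            continue
        pts = xy[sel]
        track = np.full((n_frames, 2), np.nan)
        sums = np.zeros((n_frames, 2))
        counts = np.zeros(n_frames)
        np.add.at(sums, fr, pts)
        np.add.at(counts, fr, 1)
        seen = counts > 0
        track[seen] = sums[seen] / counts[seen, None]
        idx = np.arange(n_frames)
        for d in range(2):
            track[~seen, d] = np.interp(idx[~seen], idx[seen], track[seen, d])
        tracks.append(FiducialTrack(track, n_present / n_frames))
    return tracks


def correct_drift(table: pd.DataFrame, fiducials: list[FiducialTrack],
                  smooth_window: int | None = None,
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Subtract fiducial-derived sample drift from a localization table.

    The per-frame drift is the mean over fiducials of (position minus that
    fiducial's time-average), optionally smoothed with a moving average of
    ``smooth_window`` frames.  Returns the corrected table and the
    (n_frames, 2) drift trace.
    """
    if not fiducials:
        raise InsufficientDataError(
            "no fiducial tracks given; to proceed without drift correction "
            "skip this call explicitly")
    per_fid = np.stack([t.xy - t.xy.mean(axis=0) for t in fiducials])
    drift = per_fid.mean(axis=0)
    if smooth_window and smooth_window > 1:
        drift = uniform_filter1d(drift, smooth_window, axis=0, mode="nearest")
    out = table.copy()
    fr = out["frame"].to_numpy(int)
    out["x_nm"] = out["x_nm"].to_numpy(float) - drift[fr, 0]
    out["y_nm"] = out["y_nm"].to_numpy(float) - drift[fr, 1]
    out.attrs.update(table.attrs)
    return out, drift


def render(table: pd.DataFrame, mode: str = "histogram",
           out_pixel: float = 10.0, magnification: int = 3, shift: int = 1,
           bounds: tuple[float, float, float, float] | None = None,
           ) -> np.ndarray:
    """Render a localization table to a super-resolution image.

    Modes: ``histogram`` (2D count histogram; conserves total count),
    ``gaussian`` (each localization a unit-integral Gaussian of width =
    its ``uncertainty_nm``) and ``ash`` (average shifted histograms with
    the stated ``magnification`` and lateral ``shift``; equivalent to a
    box-smoothed fine histogram and likewise count-conserving).

    ``bounds`` is (x_min, x_max, y_min, y_max) nm; by default the table's
    extent.  Returns an image indexed [row=y, col=x].
    """
    if out_pixel <= 0:
        raise InvalidParameterError("out_pixel must be > 0")
    if mode not in ("histogram", "gaussian", "ash"):
        raise InvalidParameterError(f"unknown render mode {mode!r}")
    if len(table) == 0:
        if bounds is None:
            return np.zeros((1, 1))
        x0, x1, y0, y1 = bounds
        nx = max(1, int(math.ceil((x1 - x0) / out_pixel)))
        ny = max(1, int(math.ceil((y1 - y0) / out_pixel)))
        return np.zeros((ny, nx))
    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)
    if bounds is None:
        pad = out_pixel
        bounds = (x.min() - pad, x.max() + pad, y.min() - pad, y.max() + pad)
    x0, x1, y0, y1 = bounds

    if mode in ("histogram", "ash"):
        sub = magnification if mode == "ash" else 1
        p = out_pixel / sub
        nx = max(1, int(math.ceil((x1 - x0) / p)))
        ny = max(1, int(math.ceil((y1 - y0) / p)))
        img, _, _ = np.histogram2d(y, x, bins=(ny, nx),
                                   range=((y0, y0 + ny * p),
                                          (x0, x0 + nx * p)))
        if mode == "ash":
            from scipy.ndimage import uniform_filter
            # averaging the magnification/shift shifted coarse histograms on
            # the fine grid equals a box filter of that many fine bins
            size = max(1, magnification // max(1, shift))
            img = uniform_filter(img, size=size, mode="constant") * 1.0
        return img

    # gaussian mode
    nx = max(1, int(math.ceil((x1 - x0) / out_pixel)))
    ny = max(1, int(math.ceil((y1 - y0) / out_pixel)))
    img = np.zeros((ny, nx))
    unc = table["uncertainty_nm"].to_numpy(float)
    unc = np.where(np.isfinite(unc) & (unc > 0), unc, out_pixel)
    for xi, yi, si in zip(x, y, unc):
        s_px = si / out_pixel
        cx = (xi - x0) / out_pixel
        cy = (yi - y0) / out_pixel
        reach = max(2, int(math.ceil(4 * s_px)))
        j0 = max(0, int(cx) - reach)
        j1 = min(nx, int(cx) + reach + 1)
        i0 = max(0, int(cy) - reach)
        i1 = min(ny, int(cy) + reach + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        s = s_px * math.sqrt(2.0)
        gx = 0.5 * np.diff(erf((np.arange(j0, j1 + 1) - cx) / s))
        gy = 0.5 * np.diff(erf((np.arange(i0, i1 + 1) - cy) / s))
        img[i0:i1, j0:j1] += np.outer(gy, gx)
    return img
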