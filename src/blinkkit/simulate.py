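"""Synthetic ground truth: telegraph blinking, camera movies, structures.

The simulator mirrors the regimes the analysis stages target: exponential
on-times around 10 ms, on:off ratios between 1e-2 and 1e-4, frame clocks of
3 ms (2-ms exposure) and 27 ms (25-ms exposure), pixel sizes around
100-160 nm, EMCCD noise, fiducial markers and slow sample drift.

Coordinate convention: continuous positions in nm with the origin at the
corner of pixel (0, 0); pixel (i, j) spans ``[j*px, (j+1)*px) x
[i*px, (i+1)*px)``, x runs rightward along columns, y downward along rows.
Frames are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .camera import CameraModel
from .errors import InvalidParameterError

__all__ = [
    "EmitterTruth", "SwitchTrace", "FrameStack", "StructureSpec",
    "TitrationCurve", "simulate_switching", "always_on_trace",
    "duty_from_ph", "rates_for_duty", "render_movie", "make_structure",
    "sample_csr_sphere", "sample_thomas_sphere", "generate_titration",
    "traces_to_localizations",
]


@dataclass(frozen=True)
class EmitterTruth:
    """Ground-truth emitter.

    ``rate_on`` is the off->on transition rate (mean off-time = 1/rate_on),
    ``rate_off`` the on->off rate (mean on-time = 1/rate_off); both 1/s.
    ``photon_rate`` is emitted photons per second while on.
    """

    x: float
    y: float
    z: float = 0.0
    rate_on: float = 0.0
    rate_off: float = 0.0
    photon_rate: float = 0.0

    def __post_init__(self):
        if self.rate_on < 0 or self.rate_off < 0:
            raise InvalidParameterError("switching rates must be >= 0")
        if self.photon_rate < 0:
            raise InvalidParameterError("photon_rate must be >= 0")

    @property
    def on_off_ratio(self) -> float:
        """rate_on / rate_off = mean on-time / mean off-time."""
        if self.rate_on == 0 or self.rate_off == 0:
            return math.nan
        return self.rate_on / self.rate_off


@dataclass(frozen=True)
class SwitchTrace:
    """Fluorescent ('on') intervals of one emitter over ``[0, duration]``.

    ``intervals`` is an ordered tuple of disjoint ``(t_start, t_end)`` pairs
    in seconds.
    """

    intervals: tuple[tuple[float, float], ...]
    duration: float

    def __post_init__(self):
        prev = 0.0
        for t0, t1 in self.intervals:
            if not (0.0 <= t0 < t1 <= self.duration) or t0 < prev:
                raise InvalidParameterError(
                    "intervals must be disjoint, increasing and inside "
                    "[0, duration]")
            prev = t1

    def total_on_time(self) -> float:
        return sum(t1 - t0 for t0, t1 in self.intervals)

    def state_at(self, t: float) -> bool:
        """Instantaneous state (True = on) at time ``t``."""
        for t0, t1 in self.intervals:
            if t0 <= t < t1:
                return True
            if t0 > t:
                break
        return False

    def on_seconds_per_frame(self, n_frames: int, exposure: float,
                             cycle: float) -> dict[int, float]:
        """Overlap (s) of on-intervals with each frame's exposure window.

        Only frames with a non-zero overlap appear in the result; frame k
        integrates over ``[k*cycle, k*cycle + exposure)``.
        """
        out: dict[int, float] = {}
        for t0, t1 in self.intervals:
            k0 = max(0, int(math.floor(t0 / cycle)))
            k1 = min(n_frames - 1, int(math.floor(t1 / cycle)))
            for k in range(k0, k1 + 1):
                w0 = k * cycle
                ov = min(t1, w0 + exposure) - max(t0, w0)
                if ov > 0:
                    out[k] = out.get(k, 0.0) + ov
        return out


@dataclass
class FrameStack:
    """A camera movie: ``data`` is (frames, height, width) in ADU."""

    data: np.ndarray
    camera: CameraModel

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidParameterError("data must be (frames, h, w)")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("frame data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def simulate_switching(rate_on: float, rate_off: float, duration: float,
                       initial_state: str = "off",
                       seed: int | np.random.Generator | None = None,
                       ) -> SwitchTrace:
    """Simulate a two-state telegraph process with exponential dwells.

    ``rate_on`` governs off->on transitions, ``rate_off`` on->off.  A zero
    rate makes the corresponding state absorbing.  Returns the on-intervals
    truncated to ``[0, duration]``.
    """
    if rate_on < 0 or rate_off < 0:
        raise InvalidParameterError("rates must be >= 0")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if initial_state not in ("on", "off"):
        raise InvalidParameterError("initial_state must be 'on' or 'off'")
    rng = np.random.default_rng(seed)

    intervals: list[tuple[float, float]] = []
    t = 0.0
    state_on = initial_state == "on"
    while t < duration:
        if state_on:
            if rate_off == 0:
                intervals.append((t, duration))
                break
            dwell = rng.exponential(1.0 / rate_off)
            intervals.append((t, min(t + dwell, duration)))
            t += dwell
            state_on = False
        else:
            if rate_on == 0:
                break
            t += rng.exponential(1.0 / rate_on)
            state_on = True
    return SwitchTrace(tuple(intervals), duration)


def always_on_trace(duration: float) -> SwitchTrace:
    """Trace of a non-blinking emitter (e.g. a fiducial marker)."""
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    return SwitchTrace(((0.0, duration),), duration)


def duty_from_ph(pka: float, hill: float, ph: float | np.ndarray):
    """On:off ratio implied by the protonation equilibrium at a given pH.

    The fluorescent (open, protonated) form is favoured in acid, so the
    duty cycle falls with pH: ``ratio = 10**(-hill * (ph - pka))``, equal to
    1 at ``ph == pka``.
    """
    if hill <= 0:
        raise InvalidParameterError("hill must be > 0")
    return 10.0 ** (-hill * (np.asarray(ph, dtype=float) - pka))


def rates_for_duty(duty: float, mean_on: float) -> tuple[float, float]:
    """Split an on:off ratio into (rate_on, rate_off) at fixed mean on-time.

    ``rate_off = 1/mean_on`` and ``rate_on = duty * rate_off`` so that
    ``rate_on / rate_off == duty`` exactly.
    """
    if duty <= 0 or mean_on <= 0:
        raise InvalidParameterError("duty and mean_on must be > 0")
    rate_off = 1.0 / mean_on
    return duty * rate_off, rate_off


def _integrated_gaussian_stamp(x_px: float, y_px: float, sigma_px: float,
                               shape: tuple[int, int], reach: int):
    """Per-pixel integral of a unit 2D Gaussian near (x_px, y_px).

    Returns (rows, cols, weights-outer-product factors) restricted to a
    window of +-reach pixels; pixel (i, j) covers [j, j+1) x [i, i+1) px.
    """
    h, w = shape
    j0 = max(0, int(math.floor(x_px)) - reach)
    j1 = min(w, int(math.floor(x_px)) + reach + 1)
    i0 = max(0, int(math.floor(y_px)) - reach)
    i1 = min(h, int(math.floor(y_px)) + reach + 1)
    if j0 >= j1 or i0 >= i1:
        return None
    s = sigma_px * math.sqrt(2.0)
    ex = 0.5 * (erf((np.arange(j0, j1 + 1) - x_px) / s))
    ey = 0.5 * (erf((np.arange(i0, i1 + 1) - y_px) / s))
    return i0, i1, j0, j1, np.diff(ey), np.diff(ex)


def render_movie(emitters: Sequence[EmitterTruth],
                 traces: Sequence[SwitchTrace],
                 psf_sigma: float,
                 camera: CameraModel,
                 n_frames: int,
                 shape: tuple[int, int],
                 drift: np.ndarray | None = None,
                 fiducials: Sequence[EmitterTruth] = (),
                 background: float = 0.0,
                 noise: bool = True,
                 seed: int | np.random.Generator | None = None,
                 dtype=np.float32) -> FrameStack:
    """Render a camera movie from emitters and their switching traces.

    Image formation: expected signal photons of emitter i in frame k equal
    ``photon_rate * overlap(on-intervals, exposure window k)``; converted to
    photoelectrons by the quantum efficiency and spread over pixels by a 2D
    Gaussian PSF integrated per pixel.  ``background`` is in expected
    photons/pixel/frame.  With ``noise=True`` the electron counts are
    Poisson, multiplied through a gamma-distributed EM register when
    ``em_gain > 1``, and read noise is added; ADU = electrons * conversion
    + offset.  ``noise=False`` gives the deterministic expectation (EM gain
    applied as a plain factor, no read noise).

    ``drift`` is an (n_frames, 2) array of per-frame (dx, dy) sample drift
    in nm, applied to emitters and fiducials alike.  ``fiducials`` are
    rendered as always-on emitters.
    """
    if len(emitters) != len(traces):
        raise InvalidParameterError("need exactly one trace per emitter")
    if psf_sigma <= 0:
        raise InvalidParameterError("psf_sigma must be > 0")
    if n_frames <= 0:
        raise InvalidParameterError("n_frames must be > 0")
    if background < 0:
        raise InvalidParameterError("background must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    px = camera.pixel_size
    sigma_px = psf_sigma / px
    reach = max(3, int(math.ceil(4.0 * sigma_px)))
    qe = camera.quantum_efficiency

    if drift is not None:
        drift = np.asarray(drift, dtype=float)
        if drift.shape != (n_frames, 2):
            raise InvalidParameterError("drift must be (n_frames, 2)")

    duration = n_frames * camera.cycle
    all_emitters = list(emitters) + list(fiducials)
    all_traces = list(traces) + [always_on_trace(duration) for _ in fiducials]

    # expected photoelectrons per pixel per frame
    expected = np.full((n_frames, h, w), background * qe, dtype=np.float64)
    for em, tr in zip(all_emitters, all_traces):
        on = tr.on_seconds_per_frame(n_frames, camera.exposure, camera.cycle)
        for k, sec in on.items():
            dx, dy = (drift[k] if drift is not None else (0.0, 0.0))
            stamp = _integrated_gaussian_stamp(
                (em.x + dx) / px, (em.y + dy) / px, sigma_px, shape, reach)
            if stamp is None:
                continue
            i0, i1, j0, j1, wy, wx = stamp
            expected[k, i0:i1, j0:j1] += (
                em.photon_rate * sec * qe) * np.outer(wy, wx)

    out = np.empty((n_frames, h, w), dtype=dtype)
    if not noise:
        out[:] = expected * (camera.em_gain * camera.conversion) + camera.offset
    else:
        for k in range(n_frames):  # per-frame to bound peak memory
            electrons = rng.poisson(expected[k]).astype(np.float64)
            if camera.em_gain > 1:
                pos = electrons > 0
                electrons[pos] = rng.gamma(electrons[pos], camera.em_gain)
            if camera.read_noise > 0:
                electrons += rng.normal(0.0, camera.read_noise, size=(h, w))
            out[k] = electrons * camera.conversion + camera.offset
    return FrameStack(out, camera)


@dataclass(frozen=True)
class StructureSpec:
    """Geometry of a labeled structure to scatter emitters over.

    ``pattern`` is one of ``point_field`` (uniform 2D field, e.g. nuclear
    histone sites), ``filaments`` (points jittered around random polylines,
    ER-tubule-like) or ``sphere_volume`` (uniform 3D ball, condensate-like).
    Densities are emitters/um^2 (2D patterns) or /um^3 (sphere); ``n``
    overrides the density-derived count when given.
    """

    pattern: str
    field_size: tuple[float, float] | None = None  # (width, height) nm
    density: float | None = None
    n: int | None = None
    n_filaments: int = 5
    filament_width: float = 50.0  # nm, transverse Gaussian sigma = width/2
    radius: float | None = None   # nm, sphere_volume only

    def __post_init__(self):
        if self.pattern not in ("point_field", "filaments", "sphere_volume"):
            raise InvalidParameterError(
                f"unknown pattern {self.pattern!r}")
        if self.pattern in ("point_field", "filaments"):
            if self.field_size is None or min(self.field_size) <= 0:
                raise InvalidParameterError("field_size must be positive")
        if self.pattern == "sphere_volume":
            if self.radius is None or self.radius <= 0:
                raise InvalidParameterError("radius must be positive")
        if self.n is None and self.density is None:
            raise InvalidParameterError("give n or density")
        if self.n is not None and self.n <= 0:
            raise InvalidParameterError("n must be positive")
        if self.density is not None and self.density <= 0:
            raise InvalidParameterError("density must be positive")
        if self.filament_width <= 0 or self.n_filaments <= 0:
            raise InvalidParameterError("filament parameters must be positive")


def _filament_polyline(rng, width_nm, height_nm, n_seg=12):
    """A persistent random walk across the field (one ER-like tubule)."""
    pos = rng.uniform([0, 0], [width_nm, height_nm])
    ang = rng.uniform(0, 2 * math.pi)
    step = max(width_nm, height_nm) / n_seg
    pts = [pos.copy()]
    for _ in range(n_seg):
        ang += rng.normal(0, 0.5)
        pos = pos + step * np.array([math.cos(ang), math.sin(ang)])
        pos = np.clip(pos, [0, 0], [width_nm, height_nm])
        pts.append(pos.copy())
    return np.array(pts)


def make_structure(spec: StructureSpec,
                   seed: int | np.random.Generator | None = None,
                   ) -> np.ndarray:
    """Sample emitter positions (N, 3) nm for a structure specification."""
    rng = np.random.default_rng(seed)
    if spec.pattern == "point_field":
        wx, wy = spec.field_size
        n = spec.n
        if n is None:
            n = int(round(spec.density * (wx * wy * 1e-6)))
        xy = rng.uniform([0, 0], [wx, wy], size=(n, 2))
        return np.column_stack([xy, np.zeros(n)])
    if spec.pattern == "sphere_volume":
        n = spec.n
        if n is None:
            vol_um3 = (4.0 / 3.0) * math.pi * (spec.radius * 1e-3) ** 3
            n = int(round(spec.density * vol_um3))
        return sample_csr_sphere(n, spec.radius, rng)
    # filaments
    wx, wy = spec.field_size
    polylines = [_filament_polyline(rng, wx, wy)
                 for _ in range(spec.n_filaments)]
    seg_starts, seg_vecs, seg_lens = [], [], []
    for pl in polylines:
        v = np.diff(pl, axis=0)
        ln = np.linalg.norm(v, axis=1)
        keep = ln > 0
        seg_starts.append(pl[:-1][keep])
        seg_vecs.append(v[keep])
        seg_lens.append(ln[keep])
    seg_starts = np.concatenate(seg_starts)
    seg_vecs = np.concatenate(seg_vecs)
    seg_lens = np.concatenate(seg_lens)
    n = spec.n
    if n is None:
        n = int(round(spec.density * (wx * wy * 1e-6)))
    seg_idx = rng.choice(len(seg_lens), size=n, p=seg_lens / seg_lens.sum())
    t = rng.uniform(size=(n, 1))
    base = seg_starts[seg_idx] + t * seg_vecs[seg_idx]
    jitter = rng.normal(0.0, spec.filament_width / 2.0, size=(n, 2))
    return np.column_stack([base + jitter, np.zeros(n)])


def sample_csr_sphere(n: int, radius: float,
                      seed: int | np.random.Generator | None = None,
                      center: Sequence[float] = (0.0, 0.0, 0.0),
                      ) -> np.ndarray:
    """Complete spatial randomness: n independent uniform points in a ball."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if radius <= 0:
        raise InvalidParameterError("radius must be > 0")
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return np.asarray(center, dtype=float) + d * r


def sample_thomas_sphere(n_parents: int, offspring_per_parent: int,
                         offspring_sigma: float, radius: float,
                         seed: int | np.random.Generator | None = None,
                         ) -> np.ndarray:
    """Thomas cluster process inside a ball (a clustered alternative to CSR).

    Parents are CSR in the ball; each parent gets a fixed number of
    offspring displaced by isotropic Gaussians of sd ``offspring_sigma``.
    """
    if n_parents < 1 or offspring_per_parent < 1:
        raise InvalidParameterError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    parents = sample_csr_sphere(n_parents, radius, rng)
    pts = (np.repeat(parents, offspring_per_parent, axis=0)
           + rng.normal(0.0, offspring_sigma,
                        size=(n_parents * offspring_per_parent, 3)))
    return pts


@dataclass(frozen=True)
class TitrationCurve:
    """Paired (pH, absorbance) measurements; replicates repeat pH values."""

    ph: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ph", np.asarray(self.ph, dtype=float))
        object.__setattr__(self, "absorbance",
                           np.asarray(self.absorbance, dtype=float))
        if self.ph.shape != self.absorbance.shape or self.ph.ndim != 1:
            raise InvalidParameterError("ph and absorbance must match 1-D")
        if self.ph.size < 4:
            raise InvalidParameterError("need at least 4 titration points")
        if np.any(self.absorbance < 0):
            raise InvalidParameterError("absorbance must be >= 0")

    def sorted(self) -> "TitrationCurve":
        order = np.argsort(self.ph, kind="stable")
        return TitrationCurve(self.ph[order], self.absorbance[order])


def generate_titration(pka: float, hill: float, a_max: float, a_min: float,
                       ph_grid: Sequence[float], noise_sd: float = 0.0,
                       seed: int | np.random.Generator | None = None,
                       ) -> TitrationCurve:
    """Synthetic sigmoidal titration.

    ``A(pH) = a_min + (a_max - a_min) / (1 + 10**(hill*(pH - pKa)))`` plus
    i.i.d. Gaussian noise of sd ``noise_sd`` (clipped at 0 absorbance).
    """
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size == 0:
        raise InvalidParameterError("ph_grid must not be empty")
    if a_max <= a_min or a_min < 0:
        raise InvalidParameterError("require a_max > a_min >= 0")
    if hill <= 0:
        raise InvalidParameterError("hill must be > 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    a = a_min + (a_max - a_min) / (1.0 + 10.0 ** (hill * (ph - pka)))
    if noise_sd > 0:
        a = np.clip(a + rng.normal(0.0, noise_sd, size=ph.shape), 0.0, None)
    return TitrationCurve(ph, a)


def traces_to_localizations(positions: np.ndarray,
                            traces: Sequence[SwitchTrace],
                            camera: CameraModel,
                            n_frames: int,
                            photon_rate: float = 1e5,
                            loc_sigma: float = 10.0,
                            min_on_fraction: float = 0.0,
                            p_miss: float = 0.0,
                            seed: int | np.random.Generator | None = None,
                            ) -> pd.DataFrame:
    """Idealized localization table straight from ground-truth traces.

    Bypasses image formation: every frame whose exposure overlap with an
    on-interval exceeds ``min_on_fraction * exposure`` yields one
    localization at the emitter position plus Gaussian jitter of sd
    ``loc_sigma`` nm, carrying ``photon_rate * overlap`` photons.  Each
    qualifying frame is then dropped with probability ``p_miss`` to emulate
    missed detections.  Useful for testing the kinetics stages at scale.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) != len(traces):
        raise InvalidParameterError("one trace per position required")
    if not (0 <= p_miss < 1):
        raise InvalidParameterError("p_miss must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for m, (pos, tr) in enumerate(zip(positions, traces)):
        on = tr.on_seconds_per_frame(n_frames, camera.exposure, camera.cycle)
        for k in sorted(on):
            if on[k] < min_on_fraction * camera.exposure:
                continue
            if p_miss > 0 and rng.uniform() < p_miss:
                continue
            rows.append((k,
                         pos[0] + rng.normal(0, loc_sigma),
                         pos[1] + rng.normal(0, loc_sigma),
                         photon_rate * on[k], m))
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "photons",
                                     "true_id"])
    df["frame"] = df["frame"].astype(int)
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    df.attrs["cycle_s"] = camera.cycle
    df.attrs["pixel_nm"] = camera.pixel_size
    return df
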