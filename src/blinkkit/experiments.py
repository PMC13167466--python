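"""Canned study-condition experiments built from the library stages.

These encode complete simulation-plus-analysis runs at the conditions the
package is designed around, so they can be rerun identically from tests,
scripts or a shell.
"""

from __future__ import annotations

import numpy as np

from .camera import CameraModel
from .simulate import EmitterTruth, StructureSpec, make_structure, \
    rates_for_duty, render_movie, simulate_switching
from .sofi import decorrelation, foreground_mask

__all__ = ["sofi_tau_floor"]


def sofi_tau_floor(seed: int, duty: float = 1e-3, mean_on: float = 0.01,
                   frame_rate: float = 100.0, n_frames: int = 10_000,
                   n_emitters: int = 200, shape: tuple[int, int] = (128, 128),
                   pixel_nm: float = 100.0, psf_sigma: float = 130.0,
                   photon_rate: float = 5e5, background: float = 5.0,
                   max_lag: int = 20):
    """Decorrelation tau (frames) of sparse low-duty-cycle emitters.

    Simulates ``n_emitters`` telegraph emitters with exponential on-times
    of mean ``mean_on`` and on:off ratio ``duty`` on a uniform field,
    renders a Poisson-noise movie at ``frame_rate``, and fits the
    blinking period tau to the second-order decorrelation curve over
    foreground pixels for lags ``1..max_lag``.

    With the frame clock matched to the on-time (10 ms at 100 Hz) and
    minimal signal overlap at low duty cycle, tau sits at its ~1-frame
    floor.  Returns the fitted :class:`~blinkkit.sofi.DecorrCurve`.
    """
    rng = np.random.default_rng(seed)
    cycle = 1.0 / frame_rate
    cam = CameraModel(pixel_size=pixel_nm, exposure=cycle, cycle=cycle,
                      quantum_efficiency=0.9, read_noise=0.0,
                      offset=100.0, conversion=0.5)
    field = (shape[1] * pixel_nm, shape[0] * pixel_nm)
    pos = make_structure(StructureSpec("point_field", field_size=field,
                                       n=n_emitters), rng)
    rate_on, rate_off = rates_for_duty(duty, mean_on)
    duration = n_frames * cycle
    emitters = [EmitterTruth(p[0], p[1], 0.0, rate_on, rate_off,
                             photon_rate) for p in pos]
    traces = [simulate_switching(rate_on, rate_off, duration, seed=rng)
              for _ in emitters]
    stack = render_movie(emitters, traces, psf_sigma, cam, n_frames, shape,
                         background=background, noise=True, seed=rng)
    mask = foreground_mask(stack.data)
    return decorrelation(stack.data, max_lag=max_lag, mask=mask)
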