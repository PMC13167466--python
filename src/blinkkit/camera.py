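"""Camera model and acquisition-time arithmetic.

All spatial quantities are in nanometres, times in seconds, signals in
photons / photoelectrons / ADU as stated per field.  The frame clock is
``cycle`` seconds per frame of which the first ``exposure`` seconds
integrate light (frame k integrates over ``[k*cycle, k*cycle + exposure)``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class CameraModel:
    """Integrating camera with EMCCD-style gain.

    Parameters
    ----------
    pixel_size : float
        Back-projected pixel size at the sample, nm.
    exposure : float
        Light-integration time per frame, s.
    cycle : float
        Frame-to-frame period, s; ``exposure <= cycle``.
    em_gain : float
        Electron-multiplication gain (>= 1; 1 disables the gain register).
    quantum_efficiency : float
        Photon -> photoelectron conversion probability, in (0, 1].
    read_noise : float
        Gaussian read noise, electrons rms at the output node (>= 0).
    offset : float
        Camera bias level, ADU.
    conversion : float
        ADU per electron at the output node (> 0).
    """

    pixel_size: float
    exposure: float
    cycle: float
    em_gain: float = 1.0
    quantum_efficiency: float = 0.9
    read_noise: float = 0.0
    offset: float = 100.0
    conversion: float = 0.5

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.exposure <= 0 or self.cycle <= 0:
            raise InvalidParameterError("exposure and cycle must be > 0")
        if self.exposure > self.cycle:
            raise InvalidParameterError("exposure must not exceed cycle")
        if self.em_gain < 1:
            raise InvalidParameterError("em_gain must be >= 1")
        if not (0 < self.quantum_efficiency <= 1):
            raise InvalidParameterError("quantum_efficiency must be in (0, 1]")
        if self.read_noise < 0:
            raise InvalidParameterError("read_noise must be >= 0")
        if self.conversion <= 0:
            raise InvalidParameterError("conversion must be > 0")

    @property
    def frame_rate(self) -> float:
        """Frames per second."""
        return 1.0 / self.cycle


def acquisition_duration(n_frames: int, cycle: float | None = None,
                         frame_rate: float | None = None) -> float:
    """Wall-clock duration of an acquisition, in seconds.

    Exactly one of ``cycle`` (s per frame) or ``frame_rate`` (Hz) must be
    given.  E.g. 100,000 frames at a 27-ms cycle last 2,700 s (45 min).
    """
    if (cycle is None) == (frame_rate is None):
        raise InvalidParameterError("give exactly one of cycle or frame_rate")
    if n_frames < 0:
        raise InvalidParameterError("n_frames must be >= 0")
    if cycle is None:
        if frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be > 0")
        cycle = 1.0 / frame_rate
    if cycle <= 0:
        raise InvalidParameterError("cycle must be > 0")
    return n_frames * cycle
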