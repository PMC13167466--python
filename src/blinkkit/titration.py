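"""pKa estimation from pH-titration absorbance curves.

Spontaneously blinking Si-rhodamines absorb in their protonated (open)
form, so absorbance falls sigmoidally with pH.  The model fit here is a
four-parameter logistic in pH with base-10 slope (Henderson-Hasselbalch
form)::

    A(pH) = a_min + (a_max - a_min) / (1 + 10**(hill * (pH - pKa)))

Curves with an interior absorbance maximum (e.g. a rise to a peak near
pH 4 followed by a decline, as seen for some dyes whose ring nitrogens
protonate at very low pH) are refused rather than forced through the
single-equilibrium model; only an *apparent* pKa would be meaningful for
those and this module deliberately does not define one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import median_filter

from .errors import ComplexTitrationError, DegenerateDataError
from .simulate import TitrationCurve

__all__ = ["PkaFit", "MonotonicityReport", "logistic_absorbance",
           "check_monotonic", "fit_pka"]


def logistic_absorbance(ph, pka, hill, a_max, a_min):
    """Four-parameter logistic titration model (decreasing in pH)."""
    return a_min + (a_max - a_min) / (1.0 + 10.0 ** (hill * (np.asarray(ph) - pka)))


@dataclass(frozen=True)
class MonotonicityReport:
    """Outcome of the interior-extremum check on a titration curve."""

    monotonic: bool
    extremum_ph: float | None = None
    rise: float = 0.0  # largest pH-ordered increase, absorbance units


@dataclass(frozen=True)
class PkaFit:
    """Least-squares titration fit with a covariance-based 95% CI."""

    pka: float
    hill: float
    a_max: float
    a_min: float
    ci95_pka: tuple[float, float]
    rss: float
    monotonic: bool = True

    def __post_init__(self):
        if not (self.ci95_pka[0] <= self.pka <= self.ci95_pka[1]):
            raise ValueError("CI must bracket the estimate")


def check_monotonic(curve: TitrationCurve,
                    tolerance: float = 0.05) -> MonotonicityReport:
    """Flag titrations that are not non-increasing in pH.

    A curve is accepted as monotonic when no absorbance value exceeds any
    earlier (lower-pH) value by more than ``tolerance`` times the dynamic
    range.  A centred 3-point median filter is applied first so that
    single-point noise excursions do not masquerade as structure (an
    interior maximum spans several pH points and survives the filter).
    For rejected curves the pH of the interior maximum is reported.
    """
    c = curve.sorted()
    raw = c.absorbance
    rng = float(raw.max() - raw.min())
    if rng == 0:
        return MonotonicityReport(True, None, 0.0)
    a = median_filter(raw, size=3, mode="nearest")
    run_min = np.minimum.accumulate(a)
    rises = a - run_min
    worst = int(np.argmax(rises))
    if rises[worst] > tolerance * rng:
        peak = int(np.argmax(a))
        return MonotonicityReport(False, float(c.ph[peak]),
                                  float(rises[worst]))
    return MonotonicityReport(True, None, float(rises[worst]))


def fit_pka(curve: TitrationCurve, monotonic_tolerance: float = 0.05,
            flat_tolerance: float = 0.02) -> PkaFit:
    """Fit the logistic titration model and report pKa with a 95% CI.

    The CI comes from the parameter covariance of the least-squares fit
    with a Student-t critical value at ``n - 4`` degrees of freedom.

    Raises
    ------
    DegenerateDataError
        If the absorbance range is below ``flat_tolerance`` times the
        maximum absorbance (no transition to fit).
    ComplexTitrationError
        If the curve has an interior maximum (see :func:`check_monotonic`).
    """
    c = curve.sorted()
    ph, a = c.ph, c.absorbance
    if np.unique(ph).size < 4:
        raise DegenerateDataError("need >= 4 distinct pH points")
    rng = float(a.max() - a.min())
    if rng <= flat_tolerance * max(float(a.max()), 1e-300):
        raise DegenerateDataError("flat titration curve: no transition")
    mono = check_monotonic(c, monotonic_tolerance)
    if not mono.monotonic:
        raise ComplexTitrationError(
            "interior absorbance maximum near pH "
            f"{mono.extremum_ph:.2f}; single-pKa fit refused "
            "(see check_monotonic)", extremum_ph=mono.extremum_ph)

    half = a.min() + rng / 2.0
    below = np.nonzero(a <= half)[0]
    pka0 = float(ph[below[0]]) if below.size else float(np.median(ph))
    p0 = [pka0, 1.0, float(a.max()), float(a.min())]
    popt, pcov = optimize.curve_fit(
        logistic_absorbance, ph, a, p0=p0, maxfev=10000,
        bounds=([ph.min() - 5, 1e-3, 0.0, 0.0],
                [ph.max() + 5, 20.0, np.inf, np.inf]))
    resid = a - logistic_absorbance(ph, *popt)
    rss = float(resid @ resid)
    dof = max(ph.size - 4, 1)
    se_pka = float(np.sqrt(max(pcov[0, 0], 0.0)))
    tcrit = float(stats.t.ppf(0.975, dof))
    ci = (popt[0] - tcrit * se_pka, popt[0] + tcrit * se_pka)
    return PkaFit(pka=float(popt[0]), hill=float(popt[1]),
                  a_max=float(popt[2]), a_min=float(popt[3]),
                  ci95_pka=ci, rss=rss, monotonic=True)
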