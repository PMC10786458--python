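"""Fluorescence thermometry: dye calibration, profiles, gradients.

Temperature-sensitive dyes (rhodamine B in the chamber, mCherry-H2b inside
the nucleus) lose fluorescence with temperature; for mCherry the quantum
efficiency drops ~1.3 % per °C.  Intensities are converted to temperature
changes through a linear calibration, spatial profiles perpendicular to
the heating line are fitted with a smooth model, and gradients are taken
analytically from the fit rather than from raw data — finite differences
of noisy temperatures would be useless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import integrate, interpolate, optimize

from .errors import CalibrationError, InvalidReferenceError

#: fractional mCherry intensity loss per °C
DEFAULT_MCHERRY_SLOPE = 0.013
#: thermal volumetric expansion coefficient of water, 1/°C
WATER_EXPANSION_PER_C = 3.5e-4


def volumetric_expansion_bound(delta_T_c: float,
                               alpha_per_c: float = WATER_EXPANSION_PER_C
                               ) -> float:
    """Upper bound on thermally driven volumetric strain, alpha * dT.

    For the typical 2 °C nuclear heating this is 7e-4 (0.07 %), far below
    the percent-level strains the method measures — thermal expansion of
    the aqueous phase cannot explain them.
    """
    return alpha_per_c * delta_T_c


@dataclass
class CalibrationCurve:
    """Linear dye calibration: relative intensity vs temperature change.

    ``slope`` is the fractional intensity decrease per °C;
    ``thermophoretic_correction`` multiplies measured intensities before
    conversion (dye migration in the gradient changes concentration,
    not quantum yield).
    """

    reference_temperature: float
    slope: float = DEFAULT_MCHERRY_SLOPE
    thermophoretic_correction: float = 1.0
    intensity_at_reference: float = 1.0

    def __post_init__(self) -> None:
        if self.thermophoretic_correction <= 0:
            raise CalibrationError("correction must be > 0")


def calibrate_dye(intensities: np.ndarray, temperatures: np.ndarray,
                  reference_temperature: Optional[float] = None,
                  thermophoretic_correction: float = 1.0) -> CalibrationCurve:
    """Least-squares linear calibration of dye intensity vs temperature.

    Fits I vs T by ordinary least squares and reports the fractional slope
    -d(I/I_ref)/dT with I_ref the fitted intensity at the reference
    temperature (the coolest calibration point by default).
    """
    I = np.asarray(intensities, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    if I.size != T.size or I.size < 3:
        raise CalibrationError("need >= 3 (intensity, temperature) pairs")
    if np.ptp(T) < 0.5:
        raise CalibrationError(
            f"temperature span {np.ptp(T):.3g} °C < 0.5 °C: ill-conditioned")
    if reference_temperature is None:
        reference_temperature = float(T.min())
    b1, b0 = np.polyfit(T, I, 1)
    I_ref = b0 + b1 * reference_temperature
    if I_ref <= 0:
        raise CalibrationError("non-positive fitted reference intensity")
    slope = -b1 / I_ref
    if slope <= 1e-12:  # below any real dye sensitivity
        warnings.warn("non-thermosensitive dye: slope ~ 0", stacklevel=2)
        slope = max(slope, 0.0)
        if slope <= 1e-12:
            slope = 0.0
    return CalibrationCurve(reference_temperature=reference_temperature,
                            slope=slope,
                            thermophoretic_correction=thermophoretic_correction,
                            intensity_at_reference=I_ref)


def intensity_to_temperature(I, I_ref, curve: CalibrationCurve):
    """Temperature change dT = (1 - I*correction/I_ref) / slope, °C."""
    I = np.asarray(I, dtype=float)
    if np.any(np.asarray(I_ref) <= 0):
        raise InvalidReferenceError("reference intensity must be > 0")
    if curve.slope == 0:
        raise CalibrationError("zero calibration slope")
    rel = I * curve.thermophoretic_correction / I_ref
    out = (1.0 - rel) / curve.slope
    return float(out) if np.isscalar(I_ref) and out.ndim == 0 else out


def temperature_to_intensity(delta_T, I_ref, curve: CalibrationCurve):
    """Inverse of :func:`intensity_to_temperature` (for synthesis/round trips)."""
    delta_T = np.asarray(delta_T, dtype=float)
    return I_ref * (1.0 - curve.slope * delta_T) / curve.thermophoretic_correction


# ---------------------------------------------------------------------------
# spatial profiles
# ---------------------------------------------------------------------------

def _two_sided_exp(x, T0, amp, x0, ell):
    return T0 + amp * np.exp(-np.abs(x - x0) / ell)


@dataclass
class TemperatureProfile:
    """A fitted spatial temperature profile and its analytic gradient.

    ``gradient`` is the derivative of the fitted model evaluated at the
    sample positions; the callables ``evaluate`` / ``gradient_at`` give the
    fit at arbitrary positions.
    """

    positions: np.ndarray
    temperature: np.ndarray
    fitted_params: dict
    model: str
    evaluate: Callable = field(repr=False)
    gradient_at: Callable = field(repr=False)

    @property
    def fitted(self) -> np.ndarray:
        return self.evaluate(self.positions)

    @property
    def gradient(self) -> np.ndarray:
        return self.gradient_at(self.positions)


def fit_profile_and_gradient(positions: np.ndarray, T: np.ndarray,
                             model: str = "auto") -> TemperatureProfile:
    """Fit a smooth temperature profile and differentiate it analytically.

    Default model: offset plus two-sided exponential decay about the
    heating line, ``T(x) = T0 + A exp(-|x - x0| / l)``; a smoothing-spline
    fallback is selected by AIC when the exponential fits poorly
    (``model='auto'``), or forced with ``model='spline'``.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(T, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 profile samples")
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")

    candidates = []

    if np.ptp(y) == 0:  # exactly constant profile
        T0 = float(y[0])
        return TemperatureProfile(
            positions=x, temperature=y, fitted_params={"T0": T0},
            model="constant",
            evaluate=lambda q: np.full_like(np.asarray(q, float), T0),
            gradient_at=lambda q: np.zeros_like(np.asarray(q, float)))

    if model in ("auto", "exp"):
        span = x[-1] - x[0]
        p0 = [float(y.min()), float(np.ptp(y)), float(x[np.argmax(y)]),
              max(span / 4.0, 1e-6)]
        try:
            popt, _ = optimize.curve_fit(
                _two_sided_exp, x, y, p0=p0,
                bounds=([-np.inf, -np.inf, x[0] - span, 1e-9],
                        [np.inf, np.inf, x[-1] + span, np.inf]),
                maxfev=20000)
            rss = float(np.sum((_two_sided_exp(x, *popt) - y) ** 2))
            aic = x.size * np.log(max(rss, 1e-300) / x.size) + 2 * 4
            T0, amp, x0, ell = map(float, popt)

            def ev(q, p=(T0, amp, x0, ell)):
                return _two_sided_exp(np.asarray(q, float), *p)

            def gr(q, p=(T0, amp, x0, ell)):
                q = np.asarray(q, float)
                T0_, amp_, x0_, ell_ = p
                sign = np.where(q >= x0_, 1.0, -1.0)  # right branch at kink
                return -sign * (amp_ / ell_) \
                    * np.exp(-np.abs(q - x0_) / ell_)

            candidates.append((aic, "exp",
                               {"T0": T0, "amplitude": amp, "x0": x0,
                                "decay_length": ell}, ev, gr))
        except RuntimeError:
            pass

    if model in ("auto", "spline") or not candidates:
        noise = np.std(np.diff(y)) / np.sqrt(2.0)
        spl = interpolate.UnivariateSpline(x, y, k=3,
                                           s=x.size * max(noise, 1e-12) ** 2)
        rss = float(np.sum((spl(x) - y) ** 2))
        k_eff = len(spl.get_coeffs())
        aic = x.size * np.log(max(rss, 1e-300) / x.size) + 2 * k_eff
        dspl = spl.derivative()
        candidates.append((aic, "spline", {"n_coeffs": k_eff},
                           lambda q: spl(np.asarray(q, float)),
                           lambda q: dspl(np.asarray(q, float))))

    if model == "exp":
        candidates = [c for c in candidates if c[1] == "exp"]
    elif model == "spline":
        candidates = [c for c in candidates if c[1] == "spline"]
    aic, name, params, ev, gr = min(candidates, key=lambda c: c[0])
    return TemperatureProfile(positions=x, temperature=y,
                              fitted_params=params, model=name,
                              evaluate=ev, gradient_at=gr)


def window_average(profile: TemperatureProfile, window: float = 20.0,
                   center: Optional[float] = None) -> float:
    """Mean of the fitted profile over a window (µm) centred on the nucleus.

    The 20 µm default reflects a typical nuclear diameter: chamber
    thermometry is averaged over it so it compares directly with in-nucleus
    measurements.  Zero window degenerates to point evaluation.
    """
    x = profile.positions
    if center is None:
        center = float(0.5 * (x[0] + x[-1]))
    lo, hi = center - window / 2.0, center + window / 2.0
    if lo < x[0] - 1e-9 or hi > x[-1] + 1e-9:
        raise ValueError("window extends beyond the profile support")
    if window == 0:
        return float(profile.evaluate(center))
    val, _ = integrate.quad(lambda q: float(profile.evaluate(q)), lo, hi,
                            limit=200)
    return float(val / window)
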