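"""Temporal dynamics: image differences, Kelvin-Voigt fits, tracking.

The deformation response to a square temperature-stimulus pulse is
quantified by scalar time series (mean absolute image difference,
displacement magnitudes, feature-centroid traces) and summarized by a
Kelvin-Voigt viscoelastic model — a spring of modulus E and a dashpot of
viscosity eta in parallel, creep

    eps(t) = (1/E) * (1 - exp(-t / tau_c)),   t from stimulus onset,

and exponential recovery eps(t1) * exp(-t / tau_r) from stimulus offset,
with tau = eta / E.  Creep and relaxation are fitted independently because
their characteristic times differ in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage import measure

from .core import DEFAULT_T_OFF_S, DEFAULT_T_ON_S, ImageStack, TimeSeries
from .errors import FitError, SegmentationError

# amplitude below which a trace is considered flat, as a fraction of the
# baseline noise scale
_FLAT_SNR = 2.0


# ---------------------------------------------------------------------------
# image differences
# ---------------------------------------------------------------------------

def image_difference_series(stack: ImageStack,
                            mask: Optional[np.ndarray] = None) -> TimeSeries:
    """Mean absolute intensity change per frame relative to frame 0.

    The absolute value is taken before averaging — a signed mean would let
    intensity gains and losses cancel.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames")
    if mask is None:
        mask = np.ones(stack.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask")
    ref = stack.frames[0]
    vals = np.array([np.abs(f - ref)[mask].mean() for f in stack.frames])
    return TimeSeries(t=stack.timestamps, value=vals, label="image difference")


# ---------------------------------------------------------------------------
# Kelvin-Voigt model
# ---------------------------------------------------------------------------

def kv_creep(t: np.ndarray, amplitude: float, tau_c: float) -> np.ndarray:
    """Creep response amplitude*(1-exp(-t/tau_c)); t measured from onset;
    amplitude = 1/E."""
    return amplitude * (1.0 - np.exp(-np.asarray(t, float) / tau_c))


def kv_relaxation(t: np.ndarray, amplitude: float, tau_r: float) -> np.ndarray:
    """Recovery response amplitude*exp(-t/tau_r); t measured from offset."""
    return amplitude * np.exp(-np.asarray(t, float) / tau_r)


@dataclass
class KelvinVoigtParams:
    """Fitted viscoelastic parameters of a creep/recovery trace.

    ``E`` is the relative elastic constant (creep plateau = 1/E in the
    trace's units), ``eta = E * tau_c`` the viscosity equivalent.
    """

    E: float
    tau_c: float
    tau_r: float
    eta: float
    fit_rmse: float
    baseline: float = 0.0
    creep_amplitude: float = 0.0
    relax_amplitude: float = 0.0
    flat: bool = False


class KelvinVoigtModel:
    """Kelvin-Voigt creep/recovery model of a stimulus-response trace.

    Parameters
    ----------
    series
        A :class:`~nucleostrain.core.TimeSeries` covering baseline,
        stimulation and recovery; ``series.stimulus_window`` supplies
        (t_on, t_off).
    """

    def __init__(self, series: TimeSeries):
        self.series = series
        self.t_on = series.t_on
        self.t_off = series.t_off
        pre = series.t < self.t_on
        self.baseline = float(series.value[pre].mean()) if pre.any() else 0.0
        self._y = series.value - self.baseline
        self._creep_sel = (series.t >= self.t_on) & (series.t <= self.t_off)
        self._relax_sel = series.t > self.t_off
        if not self._creep_sel.any() or not self._relax_sel.any():
            raise ValueError("series must cover both creep and relaxation")

    def _response(self, t, amplitude, tau_c, tau_r):
        """Baseline-free creep/recovery response; the relaxation branch
        starts from the creep endpoint eps(t_off), as the model demands."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        creep = (t >= self.t_on) & (t <= self.t_off)
        out[creep] = kv_creep(t[creep] - self.t_on, amplitude, tau_c)
        eps_off = kv_creep(self.t_off - self.t_on, amplitude, tau_c)
        relax = t > self.t_off
        out[relax] = kv_relaxation(t[relax] - self.t_off, eps_off, tau_r)
        return out

    def fit(self, tau_starts=(0.1, 1.0, 10.0)) -> "KelvinVoigtResults":
        """Nonlinear least squares over (amplitude, tau_c, tau_r).

        The creep and relaxation branches share the amplitude through the
        continuity condition eps(t_off) = (1/E)(1 - exp(-(t_off-t_on)/tau_c));
        tau_c and tau_r remain independent parameters.  Multi-start over a
        grid of initial time constants guards against local minima.
        """
        t = self.series.t
        y = self._y
        sel = self._creep_sel | self._relax_sel
        yc = y[self._creep_sel]
        a0 = yc.max() if yc.size and yc.max() > 0 else 1.0
        best = None
        for tc0 in tau_starts:
            for tr0 in tau_starts:
                try:
                    popt, pcov = optimize.curve_fit(
                        self._response, t[sel], y[sel], p0=[a0, tc0, tr0],
                        bounds=([-np.inf, 1e-6, 1e-6],
                                [np.inf, np.inf, np.inf]),
                        maxfev=20000)
                except (RuntimeError, ValueError):
                    continue
                rss = float(np.sum((self._response(t[sel], *popt)
                                    - y[sel]) ** 2))
                if best is None or rss < best[2]:
                    best = (popt, pcov, rss)
        if best is None:
            raise FitError("Kelvin-Voigt fit did not converge on any start")
        popt, pcov, rss = best
        rmse = float(np.sqrt(rss / sel.sum()))

        pre = self.series.t < self.t_on
        noise = float(np.std(y[pre])) if pre.sum() > 1 else 0.0
        flat = bool(abs(popt[0]) <= _FLAT_SNR * noise)
        if flat:
            warnings.warn("flat series: Kelvin-Voigt amplitude ~ 0",
                          stacklevel=2)
        return KelvinVoigtResults(self, popt, pcov, rmse, flat)


class KelvinVoigtResults:
    """Estimates, uncertainties and diagnostics of a Kelvin-Voigt fit."""

    def __init__(self, model, popt, pcov, rmse, flat):
        self.model = model
        self.creep_amplitude, self.tau_c, self.tau_r = map(float, popt)
        self.relax_amplitude = float(kv_creep(
            model.t_off - model.t_on, self.creep_amplitude, self.tau_c))
        self._pcov = pcov
        self.fit_rmse = float(rmse)
        self.flat = bool(flat)
        self.E = 1.0 / self.creep_amplitude if self.creep_amplitude != 0 \
            else np.inf
        self.eta = self.E * self.tau_c

    @property
    def bse(self) -> dict:
        """Approximate standard errors from the curvature of the fit."""
        out = {}
        for i, name in enumerate(("creep_amplitude", "tau_c", "tau_r")):
            var = self._pcov[i, i] if np.all(np.isfinite(self._pcov)) \
                else np.nan
            out[name] = float(np.sqrt(var)) if var >= 0 else np.nan
        return out

    @property
    def params(self) -> KelvinVoigtParams:
        return KelvinVoigtParams(
            E=self.E, tau_c=self.tau_c, tau_r=self.tau_r, eta=self.eta,
            fit_rmse=self.fit_rmse, baseline=self.model.baseline,
            creep_amplitude=self.creep_amplitude,
            relax_amplitude=self.relax_amplitude, flat=self.flat)

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Fitted response (baseline added back) at arbitrary times."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        creep = (t >= self.model.t_on) & (t <= self.model.t_off)
        out[creep] = kv_creep(t[creep] - self.model.t_on,
                              self.creep_amplitude, self.tau_c)
        relax = t > self.model.t_off
        out[relax] = kv_relaxation(t[relax] - self.model.t_off,
                                   self.relax_amplitude, self.tau_r)
        return out + self.model.baseline

    def plot(self, ax=None):
        """Data and fitted creep/recovery curve on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.plot(s.t, s.value, ".", ms=3, alpha=0.6, label="data")
        tt = np.linspace(s.t[0], s.t[-1], 500)
        ax.plot(tt, self.predict(tt), "-", label="Kelvin-Voigt fit")
        ax.axvspan(self.model.t_on, self.model.t_off, alpha=0.1,
                   label="stimulus")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(s.label or "response")
        ax.legend()
        return ax

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Kelvin-Voigt fit",
            "================",
            f"creep:  amplitude (1/E) = {self.creep_amplitude:.6g}"
            f" +/- {se['creep_amplitude']:.2g}",
            f"        tau_c           = {self.tau_c:.6g} s"
            f" +/- {se['tau_c']:.2g}",
            f"relax:  amplitude       = {self.relax_amplitude:.6g}"
            " (creep endpoint)",
            f"        tau_r           = {self.tau_r:.6g} s"
            f" +/- {se['tau_r']:.2g}",
            f"derived: E = {self.E:.6g}, eta = E*tau_c = {self.eta:.6g}",
            f"baseline = {self.model.baseline:.6g}, "
            f"fit RMSE = {self.fit_rmse:.3g}",
        ]
        if self.flat:
            lines.append("WARNING: flat series, amplitude ~ 0")
        return "\n".join(lines)


def fit_kelvin_voigt(series: TimeSeries) -> KelvinVoigtParams:
    """Convenience wrapper: fit and return the parameter record."""
    return KelvinVoigtModel(series).fit().params


# ---------------------------------------------------------------------------
# feature tracking
# ---------------------------------------------------------------------------

@dataclass
class FeatureTrack:
    """Centroid/shape trace of one nuclear feature across frames."""

    feature_id: int
    polarity: str  # "dark" (chromatin void) or "bright" (CHC)
    t: list = field(default_factory=list)
    centroid_um: list = field(default_factory=list)  # (x, y) per frame
    area_um2: list = field(default_factory=list)
    major_um: list = field(default_factory=list)
    minor_um: list = field(default_factory=list)

    def displacement_um(self, from_index: int = 0) -> np.ndarray:
        c = np.asarray(self.centroid_um, dtype=float)
        return np.linalg.norm(c - c[from_index], axis=1)


def _detect(frame, mask, polarity, quantile, min_area_px):
    inside = frame[mask]
    if polarity == "dark":
        thr = np.quantile(inside, quantile)
        cand = (frame < thr) & mask
    else:
        thr = np.quantile(inside, 1.0 - quantile)
        cand = (frame > thr) & mask
    labels = measure.label(cand)
    out = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area <= min_area_px:
            continue
        cy, cx = region.centroid_weighted if polarity == "bright" \
            else region.centroid
        out.append((cx, cy, region.area, region.axis_major_length,
                    region.axis_minor_length))
    return out


def track_features(stack: ImageStack, polarity: str = "bright",
                   mask: Optional[np.ndarray] = None,
                   quantile: float = 0.15, min_area_px: int = 4,
                   max_step_um: float = 1.0) -> list[FeatureTrack]:
    """Detect and link nuclear features across frames.

    Per frame, features are thresholded (dark: below the low quantile;
    bright: above the high quantile), labelled, and characterized by
    centroid, area and ellipse axes; frame-to-frame linking is nearest
    neighbor with a ``max_step_um`` gate.  Ambiguous links (two candidates
    within the gate) end the track with a warning.
    """
    if mask is None:
        mask = np.ones(stack.shape, dtype=bool)
    px = stack.pixel_size
    tracks: list[FeatureTrack] = []
    next_id = 0
    active: list[FeatureTrack] = []
    for i in range(stack.n_frames):
        dets = _detect(stack.frames[i], mask, polarity, quantile, min_area_px)
        used = set()
        still_active = []
        for tr in active:
            lx, ly = tr.centroid_um[-1]
            cands = [(j, np.hypot(d[0] * px - lx, d[1] * px - ly))
                     for j, d in enumerate(dets) if j not in used]
            cands = [(j, dist) for j, dist in cands if dist <= max_step_um]
            if not cands:
                continue
            if len(cands) > 1:
                cands.sort(key=lambda c: c[1])
                if cands[1][1] <= max_step_um:
                    warnings.warn(
                        f"ambiguous link for track {tr.feature_id}: "
                        "nearest candidate taken", stacklevel=2)
            j = min(cands, key=lambda c: c[1])[0]
            used.add(j)
            cx, cy, area, maj, mino = dets[j]
            tr.t.append(stack.timestamps[i])
            tr.centroid_um.append((cx * px, cy * px))
            tr.area_um2.append(area * px ** 2)
            tr.major_um.append(maj * px)
            tr.minor_um.append(mino * px)
            still_active.append(tr)
        for j, (cx, cy, area, maj, mino) in enumerate(dets):
            if j in used:
                continue
            tr = FeatureTrack(feature_id=next_id, polarity=polarity)
            next_id += 1
            tr.t.append(stack.timestamps[i])
            tr.centroid_um.append((cx * px, cy * px))
            tr.area_um2.append(area * px ** 2)
            tr.major_um.append(maj * px)
            tr.minor_um.append(mino * px)
            tracks.append(tr)
            still_active.append(tr)
        active = still_active
    return tracks


# ---------------------------------------------------------------------------
# kymographs and border profiles
# ---------------------------------------------------------------------------

def kymograph(stack: ImageStack, line: tuple[tuple[float, float],
                                             tuple[float, float]],
              n_samples: Optional[int] = None) -> np.ndarray:
    """Intensity along a line per frame, stacked as (position, time)."""
    (x0, y0), (x1, y1) = line
    length = np.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("zero-length kymograph line")
    if n_samples is None:
        n_samples = int(np.ceil(length)) + 1
    xs = np.linspace(x0, x1, n_samples)
    ys = np.linspace(y0, y1, n_samples)
    cols = [ndimage.map_coordinates(f, [ys, xs], order=1, mode="nearest")
            for f in stack.frames]
    return np.stack(cols, axis=1)


@dataclass
class BorderProfile:
    """Radial border distance r(theta, t) from a fixed reference centroid."""

    angles_deg: np.ndarray
    r_um: np.ndarray  # (n_frames, n_angles); NaN where no crossing
    t: np.ndarray

    def max_deviation_um(self) -> float:
        """max over time and angle of |r(theta, t) - r(theta, 0)|."""
        dev = np.abs(self.r_um - self.r_um[0])
        return float(np.nanmax(dev))


def border_profile(masks: Sequence[np.ndarray],
                   centroid_ref: Optional[tuple[float, float]] = None,
                   n_angles: int = 360, pixel_size: float = 1.0,
                   timestamps: Optional[np.ndarray] = None,
                   dr: float = 0.25) -> BorderProfile:
    """Angular border-distance profiles relative to the t=0 centroid.

    For each angle a ray is cast from the reference centroid and the
    outermost mask crossing located with sub-pixel linear interpolation.
    Angles without a crossing are NaN-flagged.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks or not masks[0].any():
        raise SegmentationError("empty mask")
    if centroid_ref is None:
        cy, cx = ndimage.center_of_mass(masks[0])
    else:
        cx, cy = centroid_ref
    h, w = masks[0].shape
    rmax = float(np.hypot(h, w))
    radii = np.arange(0.0, rmax, dr)
    angles = np.linspace(0.0, 360.0, n_angles, endpoint=False)
    th = np.deg2rad(angles)
    xs = cx + np.outer(radii, np.cos(th))
    ys = cy + np.outer(radii, np.sin(th))
    r = np.full((len(masks), n_angles), np.nan)
    for i, m in enumerate(masks):
        vals = ndimage.map_coordinates(m.astype(float), [ys, xs], order=1,
                                       mode="constant", cval=0.0)
        inside = vals >= 0.5
        for j in range(n_angles):
            idx = np.nonzero(inside[:, j])[0]
            if idx.size == 0:
                continue
            k = idx[-1]  # outermost crossing
            if k + 1 < radii.size:
                v0, v1 = vals[k, j], vals[k + 1, j]
                frac = (v0 - 0.5) / (v0 - v1) if v0 != v1 else 0.0
                r[i, j] = (radii[k] + frac * dr) * pixel_size
            else:
                r[i, j] = radii[k] * pixel_size
    t = np.arange(len(masks), dtype=float) if timestamps is None \
        else np.asarray(timestamps, dtype=float)
    return BorderProfile(angles_deg=angles, r_um=r, t=t)


# ---------------------------------------------------------------------------
# fiber strain
# ---------------------------------------------------------------------------

@dataclass
class FiberStrainEstimate:
    """Chromatin-fiber strain from rigid-cluster centroid displacement.

    strain(t) = |centroid(t) - centroid(t_on)| / L0, with L0 the rest
    length of the radial fibers (~3 µm).
    """

    t: np.ndarray
    delta_L_um: np.ndarray
    L0_um: float

    @property
    def strain(self) -> np.ndarray:
        return self.delta_L_um / self.L0_um


def fiber_strain(track: FeatureTrack, L0_um: float = 3.0,
                 t_on: float = DEFAULT_T_ON_S) -> FiberStrainEstimate:
    """Fiber strain series from a (CHC) feature track, referenced to the
    centroid at stimulus onset."""
    if L0_um <= 0:
        raise ValueError("L0 must be positive")
    t = np.asarray(track.t, dtype=float)
    ref_idx = int(np.argmin(np.abs(t - t_on)))
    dL = track.displacement_um(from_index=ref_idx)
    return FiberStrainEstimate(t=t, delta_L_um=dL, L0_um=L0_um)
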