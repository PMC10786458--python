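"""Synthetic nucleus phantoms with analytic displacement ground truth.

A phantom is a chromatin-like random texture masked to a disc nucleus,
deformed over time by an analytic displacement field: the magnitude decays
exponentially with distance from a stimulus line and follows Kelvin-Voigt
creep/recovery dynamics in time.  Optional structures — an immobile or
mobile nucleolus (dark, chromatin-void) and a rigid bright heterochromatin
cluster (CHC) — modify the field locally.  Because the field and its
spatial derivatives are known in closed form, every downstream stage
(PIV, strain, tracking, viscoelastic fitting) can be validated against
exact ground truth.

Coordinates are physical (µm), origin at the top-left pixel centre,
x = column, y = row (y increases downward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage

from .core import (
    DEFAULT_FRAME_RATE_HZ,
    DEFAULT_PIXEL_SIZE_UM,
    DEFAULT_T_OFF_S,
    DEFAULT_T_ON_S,
    ImageStack,
)
from .errors import InvalidSpecError

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class NucleolusSpec:
    """A disc nucleolus: dark in the chromatin channel, optionally immobile.

    When ``mobile`` is False the displacement field vanishes inside the disc
    and ramps linearly back to the far-field value over ``ramp_um`` outside
    its border — the 'network effect' coupling length.
    """

    center_px: tuple[float, float]  # (x, y) in pixels
    radius_um: float = 2.0
    mobile: bool = False
    ramp_um: float = 1.5


@dataclass
class CHCSpec:
    """A rigid bright central heterochromatin cluster translating as a body.

    Outside the disc the rigid translation blends linearly into the
    far-field displacement over ``ramp_um`` — the chromatin fibers that
    couple the cluster to its surroundings.  A continuous field keeps the
    forward map injective, so the rendered cluster actually translates.
    """

    center_px: tuple[float, float]
    radius_um: float = 2.5
    translation_um: float = 0.8
    ramp_um: float = 1.5


@dataclass
class KelvinVoigtTiming:
    """Temporal creep/recovery parameters of the phantom deformation."""

    tau_c: float = 0.74
    tau_r: float = 0.92
    t_on: float = DEFAULT_T_ON_S
    t_off: float = DEFAULT_T_OFF_S


@dataclass
class PhantomSpec:
    """Full description of a synthetic nucleus sequence.

    Defaults reproduce the acquisition protocol the analysis targets:
    240 frames at 4 fps (20 s baseline, 10 s stimulation, 30 s recovery),
    0.1233 µm pixels, peak displacement 2 µm at the stimulus line.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = 1.0 / DEFAULT_FRAME_RATE_HZ
    n_frames: int = 240
    nucleus_radius_um: float = 10.0
    nucleus_center_px: Optional[tuple[float, float]] = None
    texture_grain_um: float = 0.5
    amplitude_um: float = 2.0
    decay_length_um: float = 5.0
    #: point on the stimulus line, (x, y) pixels
    line_point_px: tuple[float, float] = (16.0, 0.0)
    #: orientation of the line in degrees (90 = vertical line)
    line_angle_deg: float = 90.0
    timing: KelvinVoigtTiming = field(default_factory=KelvinVoigtTiming)
    nucleolus: Optional[NucleolusSpec] = None
    chc: Optional[CHCSpec] = None
    #: if set, damp the field linearly to zero over this distance inside the
    #: nuclear border, emulating the static lamina (low displacements at the
    #: border are what the 6 px analysis cutoff excludes)
    border_ramp_um: Optional[float] = None
    noise_sigma: float = 0.0
    poisson_scale: Optional[float] = None
    texture_mean: float = 100.0
    texture_contrast: float = 30.0
    background: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise InvalidSpecError("amplitude_um must be >= 0")
        if self.decay_length_um <= 0:
            raise InvalidSpecError("decay_length_um must be > 0")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        h, w = self.image_shape
        r_px = self.nucleus_radius_um / self.pixel_size
        cx, cy = self.nucleus_center()
        if r_px > min(cx, cy, w - 1 - cx, h - 1 - cy) + 0.5 and r_px > 0:
            raise InvalidSpecError("nucleus does not fit inside the frame")
        for disc, name in ((self.nucleolus, "nucleolus"), (self.chc, "chc")):
            if disc is None:
                continue
            dx = (disc.center_px[0] - cx) * self.pixel_size
            dy = (disc.center_px[1] - cy) * self.pixel_size
            if np.hypot(dx, dy) + disc.radius_um > self.nucleus_radius_um:
                raise InvalidSpecError(f"{name} disc must lie inside the nucleus")

    def nucleus_center(self) -> tuple[float, float]:
        if self.nucleus_center_px is not None:
            return self.nucleus_center_px
        h, w = self.image_shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def line_normal(self) -> tuple[float, float]:
        th = np.deg2rad(self.line_angle_deg)
        return (-np.sin(th), np.cos(th))


@dataclass
class GroundTruth:
    """Analytic displacement and strain of a rendered phantom.

    ``displacement_fn(x, y, t) -> (u, v)`` in µm; ``strain_fn(x, y, t) ->
    (eps_hydro, eps_shear)`` are the exact spatial derivatives of the
    displacement field (dimensionless).
    """

    displacement_fn: Callable
    strain_fn: Callable
    spec: PhantomSpec


def kelvin_voigt_g(t, timing: KelvinVoigtTiming):
    """Normalized Kelvin-Voigt creep/recovery time course g(t) in [0, 1].

    g = 0 before stimulation; 1 - exp(-(t-t_on)/tau_c) while the stimulus is
    on; exponential recovery with tau_r afterwards, continuous at t_off.
    """
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t)
    creep = (t >= timing.t_on) & (t <= timing.t_off)
    # exponents clipped at 0: out-of-branch values are discarded by where()
    # but would otherwise overflow
    g = np.where(creep,
                 1.0 - np.exp(np.minimum(-(t - timing.t_on) / timing.tau_c,
                                         0.0)), g)
    g_off = 1.0 - np.exp(-(timing.t_off - timing.t_on) / timing.tau_c)
    relax = t > timing.t_off
    g = np.where(relax,
                 g_off * np.exp(np.minimum(-(t - timing.t_off) / timing.tau_r,
                                           0.0)), g)
    return g if g.ndim else float(g)


def nucleus_mask(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth boolean nucleus mask (disc)."""
    h, w = spec.image_shape
    cx, cy = spec.nucleus_center()
    yy, xx = np.mgrid[0:h, 0:w]
    r_px = spec.nucleus_radius_um / spec.pixel_size
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2


def make_texture(spec: PhantomSpec) -> ImageStack:
    """Render the undeformed t=0 frame: band-limited chromatin-like texture.

    White noise is Gaussian-filtered so that the autocorrelation FWHM of the
    texture equals ``texture_grain_um``, normalized to the requested mean and
    contrast inside the nucleus disc, with a dark nucleolus pocket and a
    bright CHC disc if specified.  Deterministic per seed.
    """
    h, w = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    grain_px = spec.texture_grain_um / spec.pixel_size
    # smoothing with sigma_f gives a Gaussian autocorrelation with
    # sigma = sigma_f * sqrt(2); match its FWHM to the grain size
    sigma_f = grain_px / (_FWHM_PER_SIGMA * np.sqrt(2.0))
    noise = rng.standard_normal((h, w))
    texture = ndimage.gaussian_filter(noise, sigma_f, mode="wrap")
    sd = texture.std()
    if sd > 0:
        texture = texture / sd
    frame = spec.texture_mean + spec.texture_contrast * texture
    mask = nucleus_mask(spec)
    frame = np.where(mask, frame, spec.background)

    yy, xx = np.mgrid[0:h, 0:w]
    if spec.nucleolus is not None:
        nx, ny = spec.nucleolus.center_px
        r = spec.nucleolus.radius_um / spec.pixel_size
        inside = (xx - nx) ** 2 + (yy - ny) ** 2 <= r ** 2
        frame = np.where(inside & mask, spec.background
                         + 0.15 * (frame - spec.background), frame)
    if spec.chc is not None:
        cx_, cy_ = spec.chc.center_px
        r = spec.chc.radius_um / spec.pixel_size
        rr = np.hypot(xx - cx_, yy - cy_)
        # condensed cluster: coherently bright with damped internal texture
        # (still textured enough for correlation tracking); the edge is
        # anti-aliased over one pixel so it warps without aliasing
        chc_frame = (spec.texture_mean + 2.0 * spec.texture_contrast
                     + 0.3 * (frame - spec.texture_mean))
        w_edge = np.clip(r - rr + 0.5, 0.0, 1.0) * mask
        frame = w_edge * chc_frame + (1.0 - w_edge) * frame
    frame = np.clip(frame, 0.0, None)
    return ImageStack(frames=frame[None], timestamps=np.zeros(1),
                      pixel_size=spec.pixel_size, channel="phantom")


def _base_field(x, y, spec: PhantomSpec):
    """Signed distance s to the stimulus line and the unit normal."""
    nx, ny = spec.line_normal()
    px, py = spec.line_point_px
    s = (x - px * spec.pixel_size) * nx + (y - py * spec.pixel_size) * ny
    return s, nx, ny


def _ramp_weights(x, y, spec: PhantomSpec):
    """Combined multiplicative weight field W(x, y) and its gradient.

    W is the product of the immobile-nucleolus ramp (0 inside the disc,
    rising linearly to 1 over the coupling length) and the optional static
    nuclear-border ramp (1 in the interior, falling linearly to 0 at the
    border).  Returns (W, dW/dx, dW/dy).
    """
    w = np.ones_like(x)
    wx = np.zeros_like(x)
    wy = np.zeros_like(x)

    nll = spec.nucleolus
    if nll is not None and not nll.mobile:
        cx = nll.center_px[0] * spec.pixel_size
        cy = nll.center_px[1] * spec.pixel_size
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        w1 = np.clip((r - nll.radius_um) / nll.ramp_um, 0.0, 1.0)
        band = (r > nll.radius_um) & (r < nll.radius_um + nll.ramp_um)
        with np.errstate(invalid="ignore", divide="ignore"):
            w1x = np.where(band, dx / (r * nll.ramp_um), 0.0)
            w1y = np.where(band, dy / (r * nll.ramp_um), 0.0)
        wx = w * w1x + w1 * wx
        wy = w * w1y + w1 * wy
        w = w * w1

    if spec.border_ramp_um is not None:
        cx, cy = spec.nucleus_center()
        cx, cy = cx * spec.pixel_size, cy * spec.pixel_size
        R = spec.nucleus_radius_um
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        w2 = np.clip((R - r) / spec.border_ramp_um, 0.0, 1.0)
        band = (r > R - spec.border_ramp_um) & (r < R)
        with np.errstate(invalid="ignore", divide="ignore"):
            w2x = np.where(band, -dx / (r * spec.border_ramp_um), 0.0)
            w2y = np.where(band, -dy / (r * spec.border_ramp_um), 0.0)
        wx = w * w2x + w2 * wx
        wy = w * w2y + w2 * wy
        w = w * w2

    return w, wx, wy


def displacement_model(x, y, t, spec: PhantomSpec):
    """Analytic displacement (u, v) in µm at positions (x, y) µm, time t s.

    The field points away from the stimulus line with magnitude
    ``A * exp(-d / lambda) * g(t)`` where d is the distance to the line and
    g the Kelvin-Voigt time course.  It vanishes inside an immobile
    nucleolus (linear ramp back to the far field over the coupling length),
    optionally damps to zero at the static nuclear border, and is spatially
    constant (rigid translation) inside a CHC disc.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = kelvin_voigt_g(t, spec.timing)
    s, nx, ny = _base_field(x, y, spec)
    mag = spec.amplitude_um * np.sign(s) * np.exp(-np.abs(s) / spec.decay_length_um)
    w, _, _ = _ramp_weights(x, y, spec)
    u = mag * nx * g * w
    v = mag * ny * g * w

    chc = spec.chc
    if chc is not None:
        cx = chc.center_px[0] * spec.pixel_size
        cy = chc.center_px[1] * spec.pixel_size
        r = np.hypot(x - cx, y - cy)
        wc = np.clip((r - chc.radius_um) / chc.ramp_um, 0.0, 1.0)
        s_c, _, _ = _base_field(np.asarray(cx), np.asarray(cy), spec)
        u_rigid = chc.translation_um * np.sign(s_c) * nx * g
        v_rigid = chc.translation_um * np.sign(s_c) * ny * g
        u = wc * u + (1.0 - wc) * u_rigid
        v = wc * v + (1.0 - wc) * v_rigid
    return u, v


def strain_model(x, y, t, spec: PhantomSpec):
    """Exact hydrostatic and shear strain of :func:`displacement_model`.

    eps_hydro = (du/dx + dv/dy) / 2, eps_shear = du/dy + dv/dx, from the
    closed-form derivatives of the field (piecewise-analytic; the measure-zero
    kinks at the stimulus line and ramp edges are evaluated one-sidedly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = kelvin_voigt_g(t, spec.timing)
    s, nx, ny = _base_field(x, y, spec)
    lam = spec.decay_length_um
    f = spec.amplitude_um * np.sign(s) * np.exp(-np.abs(s) / lam)
    fp = -(spec.amplitude_um / lam) * np.exp(-np.abs(s) / lam)

    # unweighted field and derivatives: u_b = g * f(s) * nx, grad s = (nx, ny)
    ub = g * f * nx
    vb = g * f * ny
    ubx = g * fp * nx * nx
    uby = g * fp * nx * ny
    vbx = g * fp * ny * nx
    vby = g * fp * ny * ny

    w, wx, wy = _ramp_weights(x, y, spec)
    ux = w * ubx + wx * ub
    uy = w * uby + wy * ub
    vx = w * vbx + wx * vb
    vy = w * vby + wy * vb

    chc = spec.chc
    if chc is not None:
        cx = chc.center_px[0] * spec.pixel_size
        cy = chc.center_px[1] * spec.pixel_size
        dx, dy = x - cx, y - cy
        r = np.hypot(dx, dy)
        wc = np.clip((r - chc.radius_um) / chc.ramp_um, 0.0, 1.0)
        band = (r > chc.radius_um) & (r < chc.radius_um + chc.ramp_um)
        with np.errstate(invalid="ignore", divide="ignore"):
            wcx = np.where(band, dx / (r * chc.ramp_um), 0.0)
            wcy = np.where(band, dy / (r * chc.ramp_um), 0.0)
        s_c, _, _ = _base_field(np.asarray(cx), np.asarray(cy), spec)
        u_rigid = chc.translation_um * np.sign(s_c) * nx * g
        v_rigid = chc.translation_um * np.sign(s_c) * ny * g
        u_w = w * ub  # weighted field the blend interpolates toward
        v_w = w * vb
        ux = wc * ux + wcx * (u_w - u_rigid)
        uy = wc * uy + wcy * (u_w - u_rigid)
        vx = wc * vx + wcx * (v_w - v_rigid)
        vy = wc * vy + wcy * (v_w - v_rigid)

    eps_hydro = 0.5 * (ux + vy)
    eps_shear = uy + vx
    return eps_hydro, eps_shear


def warp_frame(frame: np.ndarray, disp_fn: Callable, pixel_size: float,
               order: int = 3, n_iter: int = 10) -> np.ndarray:
    """Warp a frame by a displacement field via backward mapping.

    ``disp_fn(x_um, y_um) -> (u, v)`` is the forward displacement: texture at
    source position p appears at p + u(p).  The source of each output pixel is
    found by fixed-point iteration of ``src = x - u(src)`` (converges for
    displacement gradients < 1), then sampled with spline interpolation,
    edge-clamped.  Sources falling outside the frame raise a warning.
    """
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    x_um = xx * pixel_size
    y_um = yy * pixel_size
    sx, sy = x_um.copy(), y_um.copy()
    for _ in range(n_iter):
        u, v = disp_fn(sx, sy)
        sx = x_um - u
        sy = y_um - v
    col = sx / pixel_size
    row = sy / pixel_size
    if col.min() < -0.5 or row.min() < -0.5 or col.max() > w - 0.5 \
            or row.max() > h - 0.5:
        warnings.warn("displacement exceeds image bounds; sampling edge-clamped",
                      stacklevel=2)
    return ndimage.map_coordinates(frame, [row, col], order=order,
                                   mode="nearest")


def add_noise(stack: ImageStack, spec: PhantomSpec) -> ImageStack:
    """Add seeded camera noise: optional Poisson shot noise, then Gaussian
    read noise of standard deviation ``noise_sigma``, clipped at zero."""
    if spec.noise_sigma < 0:
        raise InvalidSpecError("noise_sigma must be >= 0")
    if spec.noise_sigma == 0 and spec.poisson_scale is None:
        return stack
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    frames = stack.frames
    if spec.poisson_scale is not None:
        if spec.poisson_scale <= 0:
            raise InvalidSpecError("poisson_scale must be > 0")
        frames = rng.poisson(np.clip(frames, 0, None)
                             * spec.poisson_scale) / spec.poisson_scale
    frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    frames = np.clip(frames, 0.0, None)
    return ImageStack(frames=frames, timestamps=stack.timestamps,
                      pixel_size=stack.pixel_size, channel=stack.channel)


def render_sequence(spec: PhantomSpec,
                    frame_indices: Optional[np.ndarray] = None
                    ) -> tuple[ImageStack, GroundTruth]:
    """Render the full phantom sequence plus its analytic ground truth.

    Each frame is the t=0 texture backward-warped by the analytic
    displacement field at that frame's time, then noised.  Passing
    ``frame_indices`` renders a subset of the protocol (timestamps keep
    their protocol values) — useful for fast validation runs.
    """
    texture = make_texture(spec).frames[0]
    times = spec.timestamps()
    if frame_indices is not None:
        times = times[np.asarray(frame_indices)]
    frames = np.empty((len(times),) + spec.image_shape)
    null_field = spec.amplitude_um == 0 and (
        spec.chc is None or spec.chc.translation_um == 0)
    for i, t in enumerate(times):
        if null_field or kelvin_voigt_g(t, spec.timing) == 0.0:
            frames[i] = texture
        else:
            frames[i] = warp_frame(
                texture, lambda x, y, _t=t: displacement_model(x, y, _t, spec),
                spec.pixel_size)
    stack = ImageStack(frames=frames, timestamps=times,
                       pixel_size=spec.pixel_size, channel="phantom")
    stack = add_noise(stack, spec)
    truth = GroundTruth(
        displacement_fn=lambda x, y, t: displacement_model(x, y, t, spec),
        strain_fn=lambda x, y, t: strain_model(x, y, t, spec),
        spec=spec)
    return stack, truth
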