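"""Multi-pass particle image velocimetry against the undeformed t=0 frame.

Dense intra-nuclear displacement fields are computed by windowed
cross-correlation between the reference frame (t=0) and every later frame:
a coarse 32 px pass seeds window offsets for a refining 16 px pass, both at
75 % overlap, so the final vector grid has 4 px spacing.  Integer
correlation peaks are refined by a 3-point Gaussian fit; vectors are
validated by a signal-to-noise ratio, a global mean±k·std filter and a
local normalized-median filter, with invalid vectors replaced by the
neighborhood median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .core import ImageStack
from .errors import PIVConfigError, SegmentationError

# floor on the local median-absolute-deviation in the normalized median
# test, in px; prevents division blow-up in smooth regions
_MAD_FLOOR_PX = 0.1


@dataclass
class PIVConfig:
    """Interrogation and validation parameters.

    The default pass schedule [32, 16] px at 75 % overlap yields a final
    vector spacing of 16 × (1 − 0.75) = 4 px.
    """

    pass_windows: tuple[int, ...] = (32, 16)
    overlap: float = 0.75
    subpixel: str = "gaussian"
    global_k: float = 3.0
    local_threshold: float = 2.5
    min_snr: float = 1.3

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise PIVConfigError("overlap must be in [0, 1)")
        ws = self.pass_windows
        if any(w & (w - 1) or w <= 0 for w in ws):
            raise PIVConfigError("window sizes must be powers of two")
        if any(a <= b for a, b in zip(ws, ws[1:])):
            raise PIVConfigError("window sizes must be strictly decreasing")

    def spacing(self, window: Optional[int] = None) -> int:
        """Node spacing in px for a pass (default: final pass)."""
        w = self.pass_windows[-1] if window is None else window
        return max(1, int(round(w * (1.0 - self.overlap))))


@dataclass
class DisplacementField:
    """Gridded displacement vectors of one frame relative to frame 0.

    ``grid_x``/``grid_y`` are 1-D window-centre coordinates in px;
    ``u``/``v`` are displacement components in px on the (ny, nx) grid
    (u along x/columns, v along y/rows, y increasing downward);
    ``valid`` flags vectors that passed all filters.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    snr: np.ndarray
    reference: int = 0
    target: int = 1
    pixel_size: float = 1.0

    @property
    def spacing(self) -> float:
        return float(self.grid_x[1] - self.grid_x[0]) if self.grid_x.size > 1 \
            else float("nan")

    def magnitude_um(self) -> np.ndarray:
        return np.hypot(self.u, self.v) * self.pixel_size

    def to_dataframe(self):
        import pandas as pd

        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame({
            "grid_x_px": gx.ravel(), "grid_y_px": gy.ravel(),
            "u_px": self.u.ravel(), "v_px": self.v.ravel(),
            "valid": self.valid.ravel().astype(int),
        })


def _subpixel_offset(c: np.ndarray, peak: tuple[int, int],
                     method: str) -> tuple[float, float]:
    """3-point Gaussian (parabolic fallback) refinement along each axis."""
    offs = []
    for ax in (0, 1):
        idx = list(peak)
        vals = []
        for d in (-1, 0, 1):
            idx[ax] = peak[ax] + d
            vals.append(c[tuple(idx)])
        cm, c0, cp = vals
        if method == "gaussian" and cm > 0 and c0 > 0 and cp > 0:
            denom = 2.0 * (np.log(cm) + np.log(cp) - 2.0 * np.log(c0))
            off = (np.log(cm) - np.log(cp)) / denom if denom != 0 else 0.0
        else:  # parabolic fallback when a neighbor is non-positive
            denom = 2.0 * (cm + cp - 2.0 * c0)
            off = (cm - cp) / denom if denom != 0 else 0.0
        offs.append(off if np.isfinite(off) and abs(off) < 1 else 0.0)
    return offs[0], offs[1]


def correlate_window(ref_patch: np.ndarray, tgt_patch: np.ndarray,
                     subpixel: str = "gaussian"
                     ) -> tuple[float, float, float]:
    """Cross-correlate one interrogation window pair.

    Returns ``(du, dv, snr)``: the sub-pixel displacement of the target
    patch relative to the reference (px, x = columns / y = rows) and the
    ratio of the highest to the second-highest non-adjacent correlation
    peak.  A constant reference patch has no correlation signal and raises
    ``ValueError`` (callers mark the vector invalid).
    """
    ref = np.asarray(ref_patch, dtype=float)
    tgt = np.asarray(tgt_patch, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError("patches must have equal shape")
    if ref.shape[0] % 2 or ref.shape[1] % 2:
        raise ValueError("patch sizes must be even")
    if np.ptp(ref) == 0:
        raise ValueError("constant reference patch: correlation undefined")
    ref = ref - ref.mean()
    tgt = tgt - tgt.mean()
    norm = np.linalg.norm(ref) * np.linalg.norm(tgt)
    if norm == 0:
        raise ValueError("zero-variance patch: correlation undefined")
    c = signal.fftconvolve(tgt, ref[::-1, ::-1], mode="full") / norm
    n2, n1 = ref.shape
    # restrict the search to shifts within half a window
    half_y, half_x = n2 // 2, n1 // 2
    cy, cx = n2 - 1, n1 - 1
    sub = c[cy - half_y:cy + half_y + 1, cx - half_x:cx + half_x + 1]
    py, px = np.unravel_index(np.argmax(sub), sub.shape)
    peak_val = sub[py, px]
    # SNR: exclude the 3x3 neighborhood of the main peak
    masked = sub.copy()
    masked[max(py - 1, 0):py + 2, max(px - 1, 0):px + 2] = -np.inf
    second = masked.max()
    snr = peak_val / second if second > 0 else np.inf
    if 0 < py < sub.shape[0] - 1 and 0 < px < sub.shape[1] - 1:
        # sub-pixel fit on overlap-normalized values: the linear taper of
        # the full correlation (smaller patch overlap at larger lags) would
        # otherwise bias the 3-point fit toward integer shifts
        ov_y = np.minimum(np.arange(1, 2 * n2), np.arange(2 * n2 - 1, 0, -1))
        ov_x = np.minimum(np.arange(1, 2 * n1), np.arange(2 * n1 - 1, 0, -1))
        cn = c * norm / np.outer(np.clip(ov_y, 1, n2), np.clip(ov_x, 1, n1))
        subn = cn[cy - half_y:cy + half_y + 1, cx - half_x:cx + half_x + 1]
        oy, ox = _subpixel_offset(subn, (py, px), subpixel)
    else:
        oy = ox = 0.0
    dv = (py - half_y) + oy
    du = (px - half_x) + ox
    return float(du), float(dv), float(snr)


def _grid_1d(size: int, window: int, spacing: int) -> np.ndarray:
    """Window-centre coordinates along one axis."""
    half = window // 2
    return np.arange(half, size - half + 1, spacing, dtype=float)


def _extract(frame: np.ndarray, cy: float, cx: float, window: int
             ) -> np.ndarray:
    """Window around (cy, cx) with edge-clamped padding."""
    half = window // 2
    y0, x0 = int(round(cy)) - half, int(round(cx)) - half
    h, w = frame.shape
    ys = np.clip(np.arange(y0, y0 + window), 0, h - 1)
    xs = np.clip(np.arange(x0, x0 + window), 0, w - 1)
    return frame[np.ix_(ys, xs)]


def filter_outliers(field: DisplacementField, config: PIVConfig
                    ) -> DisplacementField:
    """Validate vectors and replace rejected ones by the neighbor median.

    Three tests, applied to currently valid vectors: (1) global — a
    component deviating from the field mean by more than ``global_k``
    standard deviations; (2) local — deviation from the 3×3 neighborhood
    median exceeding ``local_threshold`` times the neighborhood median
    absolute deviation (with a small floor); (3) ``snr < min_snr``.
    Rejected vectors keep ``valid=False`` and are filled with the median of
    valid neighbors, iterated until the interior is complete.
    """
    u = field.u.copy()
    v = field.v.copy()
    valid = field.valid.copy()

    # SNR test
    valid &= field.snr >= config.min_snr

    # global filter, componentwise
    for comp in (u, v):
        vals = comp[valid]
        if vals.size:
            mean, std = vals.mean(), vals.std()
            # sub-micropixel spread is numerical noise, not flow
            if std > 1e-9:
                valid &= ~(np.abs(comp - mean) > config.global_k * std)

    # local normalized median filter
    def _neigh_stats(comp):
        padded = np.pad(np.where(valid, comp, np.nan), 1,
                        constant_values=np.nan)
        stacks = [padded[1 + dy:padded.shape[0] - 1 + dy,
                         1 + dx:padded.shape[1] - 1 + dx]
                  for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                  if (dy, dx) != (0, 0)]
        neigh = np.stack(stacks)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(neigh, axis=0)
            mad = np.nanmedian(np.abs(neigh - med), axis=0)
        return med, mad

    for comp in (u, v):
        med, mad = _neigh_stats(comp)
        with np.errstate(invalid="ignore"):
            bad = np.abs(comp - med) > config.local_threshold * (mad + _MAD_FLOOR_PX)
        valid &= ~(bad & np.isfinite(med))

    # replacement: iterated valid-neighbor median (replaced vectors stay
    # flagged invalid)
    filled = valid.copy()
    for comp in (u, v):
        comp[~filled] = np.nan
    for _ in range(max(u.shape) * 2):
        todo = ~filled & ~np.isnan(field.u)
        if not todo.any():
            break
        changed = False
        for comp in (u, v):
            padded = np.pad(comp, 1, constant_values=np.nan)
            neigh = np.stack([
                padded[1 + dy:padded.shape[0] - 1 + dy,
                       1 + dx:padded.shape[1] - 1 + dx]
                for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(neigh, axis=0)
            fill = todo & np.isfinite(med)
            comp[fill] = med[fill]
            changed = changed or bool(fill.any())
        if changed:
            filled |= todo & np.isfinite(u) & np.isfinite(v)
        else:
            break
    return DisplacementField(grid_x=field.grid_x, grid_y=field.grid_y,
                             u=u, v=v, valid=valid, snr=field.snr,
                             reference=field.reference, target=field.target,
                             pixel_size=field.pixel_size)


def multipass_piv(frame0: np.ndarray, frame_t: np.ndarray,
                  config: Optional[PIVConfig] = None,
                  mask: Optional[np.ndarray] = None,
                  pixel_size: float = 1.0,
                  target_index: int = 1) -> DisplacementField:
    """Multi-pass windowed cross-correlation between two frames.

    Each pass interrogates windows centred on a grid of spacing
    ``window × (1 − overlap)``; later passes offset the target window by the
    (filtered, interpolated) estimate of the previous pass and correlate
    only the residual.  With the default config the final grid spacing is
    4 px.  Vectors whose window falls outside ``mask`` are marked invalid.
    """
    config = config or PIVConfig()
    frame0 = np.asarray(frame0, dtype=float)
    frame_t = np.asarray(frame_t, dtype=float)
    if frame0.shape != frame_t.shape:
        raise PIVConfigError("frames must have the same shape")
    if min(frame0.shape) < config.pass_windows[-1]:
        raise PIVConfigError("frame smaller than the final window")
    if min(frame0.shape) < config.pass_windows[0]:
        raise PIVConfigError("frame smaller than the first window")

    h, w = frame0.shape
    prev: Optional[DisplacementField] = None
    for window in config.pass_windows:
        spacing = config.spacing(window)
        gx = _grid_1d(w, window, spacing)
        gy = _grid_1d(h, window, spacing)
        u = np.zeros((gy.size, gx.size))
        v = np.zeros_like(u)
        snr = np.zeros_like(u)
        valid = np.ones(u.shape, dtype=bool)

        if prev is not None:
            from scipy.interpolate import RegularGridInterpolator

            pts = np.stack(np.meshgrid(gy, gx, indexing="ij"), axis=-1)
            pred_u = RegularGridInterpolator(
                (prev.grid_y, prev.grid_x), prev.u, bounds_error=False,
                fill_value=None)(pts)
            pred_v = RegularGridInterpolator(
                (prev.grid_y, prev.grid_x), prev.v, bounds_error=False,
                fill_value=None)(pts)
        else:
            pred_u = np.zeros_like(u)
            pred_v = np.zeros_like(u)

        for iy, cy in enumerate(gy):
            for ix, cx in enumerate(gx):
                su = int(round(pred_u[iy, ix]))
                sv = int(round(pred_v[iy, ix]))
                ref = _extract(frame0, cy, cx, window)
                tgt = _extract(frame_t, cy + sv, cx + su, window)
                try:
                    du, dv, s = correlate_window(ref, tgt, config.subpixel)
                except ValueError:
                    valid[iy, ix] = False
                    snr[iy, ix] = 0.0
                    u[iy, ix] = su
                    v[iy, ix] = sv
                    continue
                u[iy, ix] = su + du
                v[iy, ix] = sv + dv
                snr[iy, ix] = s

        fld = DisplacementField(grid_x=gx, grid_y=gy, u=u, v=v, valid=valid,
                                snr=snr, reference=0, target=target_index,
                                pixel_size=pixel_size)
        prev = filter_outliers(fld, config)

    if mask is not None:
        prev = _apply_mask(prev, mask, config.pass_windows[-1])
    return prev


def _apply_mask(field: DisplacementField, mask: np.ndarray, window: int
                ) -> DisplacementField:
    """Invalidate vectors whose interrogation window leaves the mask."""
    mask = np.asarray(mask, dtype=bool)
    cover = ndimage.uniform_filter(mask.astype(float), size=window)
    gx = field.grid_x.astype(int)
    gy = field.grid_y.astype(int)
    gx = np.clip(gx, 0, mask.shape[1] - 1)
    gy = np.clip(gy, 0, mask.shape[0] - 1)
    inside = cover[np.ix_(gy, gx)] >= 0.5
    inside &= mask[np.ix_(gy, gx)]
    u = np.where(inside, field.u, np.nan)
    v = np.where(inside, field.v, np.nan)
    return DisplacementField(grid_x=field.grid_x, grid_y=field.grid_y,
                             u=u, v=v, valid=field.valid & inside,
                             snr=field.snr, reference=field.reference,
                             target=field.target,
                             pixel_size=field.pixel_size)


def displacement_sequence(stack: ImageStack,
                          config: Optional[PIVConfig] = None,
                          mask: Optional[np.ndarray] = None
                          ) -> list[DisplacementField]:
    """One displacement field per frame t >= 1, each against frame 0.

    Cumulative referencing to the undeformed frame (not frame-to-frame
    chaining) avoids drift accumulation.
    """
    if stack.n_frames < 2:
        raise PIVConfigError("need at least two frames")
    if mask is not None and not np.asarray(mask, dtype=bool).any():
        raise SegmentationError("empty mask")
    frame0 = stack.frames[0]
    return [multipass_piv(frame0, stack.frames[t], config=config, mask=mask,
                          pixel_size=stack.pixel_size, target_index=t)
            for t in range(1, stack.n_frames)]
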