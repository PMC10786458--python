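"""Hydrostatic and shear strain maps from gridded displacement fields.

Strains are computed from node-to-node displacement differences normalized
by the characteristic initial length L_char (the grid spacing, in the same
units as u and v), which makes them the standard dimensionless
infinitesimal strains:

    eps_hydro = (du/dx + dv/dy) / 2      (mean normal strain)
    eps_shear =  du/dy + dv/dx           (engineering shear)

Relative units throughout: 1 = 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy import ndimage

from .piv import DisplacementField


@dataclass
class StrainField:
    """Per-node hydrostatic and shear strain on the displacement grid."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    hydro: np.ndarray
    shear: np.ndarray
    L_char: float
    valid: np.ndarray


def strain_from_displacement(field: DisplacementField) -> StrainField:
    """Differentiate a displacement field into a strain field.

    Central differences across adjacent grid nodes (one-sided at the
    edges), each normalized by the node spacing L_char.  Requires a regular
    grid with at least 2x2 nodes and >= 50 % valid vectors.
    """
    gx, gy = field.grid_x, field.grid_y
    if gx.size < 2 or gy.size < 2:
        raise ValueError("strain needs at least a 2x2 vector grid")
    sx = np.diff(gx)
    sy = np.diff(gy)
    if not (np.allclose(sx, sx[0]) and np.allclose(sy, sy[0])):
        raise ValueError("displacement grid must be regular")
    finite = np.isfinite(field.u) & np.isfinite(field.v)
    if finite.mean() < 0.5:
        raise ValueError("less than 50% valid vector coverage")

    u = np.where(finite, field.u, np.nan)
    v = np.where(finite, field.v, np.nan)
    # np.gradient with physical spacing == difference / L_char
    du_dy, du_dx = np.gradient(u, sy[0], sx[0])
    dv_dy, dv_dx = np.gradient(v, sy[0], sx[0])
    hydro = 0.5 * (du_dx + dv_dy)
    shear = du_dy + dv_dx
    valid = np.isfinite(hydro) & np.isfinite(shear)
    return StrainField(grid_x=gx, grid_y=gy, hydro=hydro, shear=shear,
                       L_char=float(sx[0]), valid=valid)


def upsample_to_image(strain: StrainField, image_shape: tuple[int, int],
                      component: str = "hydro",
                      mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Interpolate a strain component to per-pixel resolution.

    Bilinear interpolation inside the grid hull; outside it (but inside the
    optional nucleus mask) the nearest finite node value is used.  Pixels
    outside the mask are NaN.
    """
    comp = getattr(strain, component)
    if comp.size == 0 or not np.isfinite(comp).any():
        raise ValueError("empty strain field")
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]

    filled = comp.copy()
    bad = ~np.isfinite(filled)
    if bad.any():  # nearest-node fill so bilinear interpolation is defined
        idx = ndimage.distance_transform_edt(bad, return_distances=False,
                                             return_indices=True)
        filled = filled[tuple(idx)]
    interp = RegularGridInterpolator((strain.grid_y, strain.grid_x), filled,
                                     method="linear", bounds_error=False,
                                     fill_value=np.nan)
    pts = np.stack([yy.ravel(), xx.ravel()], axis=-1).astype(float)
    out = interp(pts).reshape(h, w)

    outside = ~np.isfinite(out)
    if outside.any():  # nearest-value extrapolation beyond the hull
        cy = np.clip(yy, strain.grid_y[0], strain.grid_y[-1])
        cx = np.clip(xx, strain.grid_x[0], strain.grid_x[-1])
        near = interp(np.stack([cy.ravel(), cx.ravel()], axis=-1).astype(float))
        out[outside] = near.reshape(h, w)[outside]
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out


def displacement_magnitude_map(field: DisplacementField,
                               image_shape: tuple[int, int],
                               mask: Optional[np.ndarray] = None,
                               in_um: bool = True) -> np.ndarray:
    """Upsample |displacement| to pixel resolution (µm by default)."""
    mag = np.hypot(field.u, field.v)
    if in_um:
        mag = mag * field.pixel_size
    carrier = StrainField(grid_x=field.grid_x, grid_y=field.grid_y,
                          hydro=mag, shear=mag,
                          L_char=field.spacing,
                          valid=np.isfinite(mag))
    return upsample_to_image(carrier, image_shape, "hydro", mask=mask)
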