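"""Independent direct-space evaluation of the Boussinesq surface convolution.

Used as an oracle against the FFT-based forward model: the displacement is
computed by real-space quadrature of the half-space surface Green's tensor

    G(r) = (1 + nu) / (pi E r^3) * [[(1-nu) r^2 + nu x^2, nu x y],
                                    [nu x y, (1-nu) r^2 + nu y^2]]

with the traction piecewise constant per grid cell, midpoint sub-cell
quadrature away from the singularity, and the singular self-cell integrated
analytically (the integral of 1/r over a square of side h is
4 h ln(1 + sqrt(2)); the x^2/r^3 term integrates to half of that by
symmetry).  This path shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def direct_displacement(traction, youngs_modulus_pa: float,
                        poisson_ratio: float, sub: int = 3,
                        points: np.ndarray | None = None) -> np.ndarray:
    """Displacement (um) by direct-space quadrature.

    ``points``: optional (N, 2) array of (y_um, x_um) evaluation points;
    defaults to all grid nodes (returned as two (ny, nx) arrays).  The
    analytic self-cell term only applies to on-grid evaluation.
    """
    sp = traction.grid_spacing_um
    ny, nx = traction.shape
    e = youngs_modulus_pa
    nu = poisson_ratio
    coords = np.arange(max(ny, nx)) * sp
    gy, gx = np.meshgrid(coords[:ny], coords[:nx], indexing="ij")
    tx = traction.t_x.ravel()
    ty = traction.t_y.ravel()
    mag = np.abs(tx) + np.abs(ty)
    nzi = np.nonzero(mag > 1e-6 * mag.max())[0]
    src_y = gy.ravel()[nzi]
    src_x = gx.ravel()[nzi]

    on_grid = points is None
    if on_grid:
        py = gy.ravel()
        px = gx.ravel()
    else:
        py = np.asarray(points)[:, 0]
        px = np.asarray(points)[:, 1]

    offsets = (np.arange(sub) + 0.5) / sub - 0.5
    ux = np.zeros(py.shape)
    uy = np.zeros(py.shape)
    for oy in offsets:
        for ox in offsets:
            dy = py[:, None] - (src_y + oy * sp)[None, :]
            dx = px[:, None] - (src_x + ox * sp)[None, :]
            r = np.hypot(dx, dy)
            # the self-cell (target inside the source cell) is handled
            # analytically below for on-grid targets
            same_cell = (np.abs(py[:, None] - src_y[None, :]) < sp / 2) & \
                        (np.abs(px[:, None] - src_x[None, :]) < sp / 2)
            tiny = r < 1e-12
            r = np.where(tiny, 1.0, r)
            pref = (1 + nu) / (math.pi * e * r ** 3)
            pref = np.where(tiny | (same_cell & on_grid), 0.0, pref)
            gxx = pref * ((1 - nu) * r ** 2 + nu * dx ** 2)
            gyy = pref * ((1 - nu) * r ** 2 + nu * dy ** 2)
            gxy = pref * nu * dx * dy
            ux += gxx @ tx[nzi] + gxy @ ty[nzi]
            uy += gxy @ tx[nzi] + gyy @ ty[nzi]
    ux *= sp * sp / sub ** 2
    uy *= sp * sp / sub ** 2
    if on_grid:
        # analytic self-cell: int 1/r over the square cell; the anisotropic
        # x^2/r^3 part contributes half of it by symmetry
        i1 = 4.0 * sp * math.log(1.0 + math.sqrt(2.0))
        g_self = (1 + nu) / (math.pi * e) * ((1 - nu) * i1 + nu * i1 / 2.0)
        ux += g_self * tx
        uy += g_self * ty
        return np.stack([ux.reshape(ny, nx), uy.reshape(ny, nx)])
    return np.stack([ux, uy], axis=1)
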