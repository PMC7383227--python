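"""Traction force microscopy on elastic half-space substrates.

Pipeline: rigid drift correction of a stressed/relaxed bead-image pair,
window-based PIV to sample substrate displacements, linear interpolation onto
a regular grid (default 2.6 um spacing), unconstrained Fourier-transform
traction cytometry (FTTC) to invert the Boussinesq problem, strain energy and
strain-energy-density readout, and force-balance/size filtering of cell
islands.

The substrate is modeled as a linear elastic half-space with Young's modulus
``E`` and Poisson ratio ``nu``; surface displacement and surface traction are
related mode-by-mode in Fourier space by the Boussinesq Green's tensor

    G(k) = 2 (1 + nu) / (E k^3) * [[(1-nu) k^2 + nu ky^2, -nu kx ky],
                                   [-nu kx ky, (1-nu) k^2 + nu kx^2]]

with u(k) = G(k) T(k).  "Unconstrained" FTTC inverts G per mode without
regularization; an optional Tikhonov parameter is exposed for noisy data.

Units: displacements in micrometres and tractions in pascals at field level;
strain energy is returned in joules (U = 1/2 * sum(T . u) dA in SI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator
from scipy.signal.windows import tukey

from .errors import DataError, ConfigError, NormalizationError, RegistrationError

__all__ = [
    "GelProperties",
    "DisplacementField",
    "TractionField",
    "MatchedPair",
    "IslandRecord",
    "correct_drift",
    "piv_displacements",
    "track_beads",
    "interpolate_to_grid",
    "forward_boussinesq",
    "fttc_inverse",
    "strain_energy",
    "equilibrium_ratio",
    "filter_islands",
    "summarize_by_gel",
    "analyze_island",
]

DEFAULT_GRID_SPACING_UM = 2.6
DEFAULT_POISSON_RATIO = 0.5


@dataclass(frozen=True)
class GelProperties:
    """Elastic constants of the polyacrylamide substrate.

    Defaults follow common practice for TFM on PAA gels: near-incompressible
    (nu = 0.5).  Typical stiffnesses in this workflow are 1 kPa and 40 kPa
    coatings and TFM gels around 16.4 kPa.
    """

    youngs_modulus_pa: float
    poisson_ratio: float = DEFAULT_POISSON_RATIO

    def __post_init__(self) -> None:
        if not self.youngs_modulus_pa > 0:
            raise ConfigError("youngs_modulus_pa must be > 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ConfigError("poisson_ratio must be in [0, 0.5]")


@dataclass
class DisplacementField:
    """Substrate displacement field on a regular grid (um)."""

    u_x: np.ndarray
    u_y: np.ndarray
    grid_spacing_um: float = DEFAULT_GRID_SPACING_UM
    valid_mask: np.ndarray | None = None
    origin_offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.u_y.shape:
            raise DataError("u_x and u_y must have identical shapes")
        if not self.grid_spacing_um > 0:
            raise ConfigError("grid_spacing_um must be > 0")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.u_x.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.u_x.shape:
                raise DataError("valid_mask shape mismatch")
        if not np.all(np.isfinite(self.u_x[self.valid_mask])):
            raise DataError("non-finite displacements inside valid_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_x.shape


@dataclass
class TractionField:
    """Surface traction field (Pa) on the same grid as the displacements."""

    t_x: np.ndarray
    t_y: np.ndarray
    grid_spacing_um: float = DEFAULT_GRID_SPACING_UM
    gel: GelProperties | None = None

    def __post_init__(self) -> None:
        self.t_x = np.asarray(self.t_x, dtype=float)
        self.t_y = np.asarray(self.t_y, dtype=float)
        if self.t_x.shape != self.t_y.shape:
            raise DataError("t_x and t_y must have identical shapes")
        if not self.grid_spacing_um > 0:
            raise ConfigError("grid_spacing_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.t_x.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.t_x, self.t_y)


@dataclass
class MatchedPair:
    """Drift-corrected stressed/relaxed image pair.

    ``applied_shift_px`` is the (row, col) translation of the stressed image
    relative to the relaxed one; the stored relaxed image has been resampled
    by that shift so the pair is aligned.
    """

    stressed: np.ndarray
    relaxed: np.ndarray
    applied_shift_px: tuple[float, float]
    correlation_peak: float


@dataclass
class IslandRecord:
    """Per-island TFM readout with filter outcome."""

    island_id: str
    island_mask: np.ndarray | None
    area_um2: float
    strain_energy_j: float
    energy_density_j_per_m2: float
    equilibrium_ratio: float
    gel_id: str = ""
    condition_id: str = ""
    retained: bool = False
    discard_reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------

def _subpixel_offset(cm: float, c0: float, cp: float) -> float:
    """Three-point Gaussian peak refinement, parabolic fallback."""
    if cm > 0 and c0 > 0 and cp > 0 and c0 >= cm and c0 >= cp:
        lm, l0, lp = math.log(cm), math.log(c0), math.log(cp)
        denom = 2.0 * l0 - lm - lp
        if denom > 0:
            return (lp - lm) / (2.0 * denom)
    denom = 2.0 * c0 - cm - cp
    if denom > 0:
        return (cp - cm) / (2.0 * denom)
    return 0.0


def _upsampled_refine(cross: np.ndarray, row0: float, col0: float,
                      usf: int = 32, radius: float = 1.0
                      ) -> tuple[float, float]:
    """Locate the correlation maximum on an upsampled local grid.

    Matrix-DFT evaluation of the cross-correlation on a fine grid around the
    integer peak (Guizar-Sicairos style); a final 3-point fit on the fine
    grid brings the residual bias well below the grid step.  Avoids the
    peak-locking bias of 3-point fits applied directly at pixel pitch.
    """
    ny, nx = cross.shape
    n_fine = 2 * int(round(usf * radius)) + 1
    ys = row0 + (np.arange(n_fine) - n_fine // 2) / usf
    xs = col0 + (np.arange(n_fine) - n_fine // 2) / usf
    fy = np.fft.fftfreq(ny)
    fx = np.fft.fftfreq(nx)
    ey = np.exp(2j * np.pi * np.outer(ys, fy))
    ex = np.exp(2j * np.pi * np.outer(fx, xs))
    cc = (ey @ cross @ ex).real
    iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
    dy = dx = 0.0
    if 0 < iy < n_fine - 1:
        dy = _subpixel_offset(cc[iy - 1, ix], cc[iy, ix], cc[iy + 1, ix])
    if 0 < ix < n_fine - 1:
        dx = _subpixel_offset(cc[iy, ix - 1], cc[iy, ix], cc[iy, ix + 1])
    return ys[iy] + dy / usf, xs[ix] + dx / usf


def _xcorr_peak(a: np.ndarray, b: np.ndarray, max_shift: int | None = None
                ) -> tuple[float, float, float]:
    """Circular cross-correlation peak of ``a`` against ``b``.

    Returns (row_shift, col_shift, quality) where the shift moves ``b`` onto
    ``a`` and quality is the normalized correlation coefficient in [0, 1].
    The peak is refined to sub-pixel precision on a 32x-upsampled local DFT
    grid.
    """
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0, 0.0, 0.0
    cross = np.fft.fft2(a) * np.conj(np.fft.fft2(b))
    cc = np.fft.ifft2(cross).real
    ny, nx = cc.shape
    if max_shift is not None:
        allowed = np.zeros_like(cc, dtype=bool)
        allowed[:max_shift + 1, :max_shift + 1] = True
        allowed[:max_shift + 1, -max_shift:] = True
        allowed[-max_shift:, :max_shift + 1] = True
        allowed[-max_shift:, -max_shift:] = True
        cc_search = np.where(allowed, cc, -np.inf)
    else:
        cc_search = cc
    iy, ix = np.unravel_index(np.argmax(cc_search), cc.shape)
    quality = float(cc[iy, ix] / (na * nb))
    row = iy if iy <= ny // 2 else iy - ny
    col = ix if ix <= nx // 2 else ix - nx
    row, col = _upsampled_refine(cross / (na * nb), float(row), float(col))
    return row, col, quality


def _xcorr_peak_linear(a: np.ndarray, b: np.ndarray, max_shift: int
                       ) -> tuple[float, float, float]:
    """Linear (zero-padded) NCC peak with triangular-overlap normalization.

    Unlike the circular variant, the finite-window overlap loss is divided
    out, which removes the systematic bias of the peak toward zero lag
    (loss-of-pairs bias) in window PIV.
    """
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0, 0.0, 0.0
    n = a.shape[0]
    ap = np.zeros((2 * n, 2 * n))
    bp = np.zeros((2 * n, 2 * n))
    ap[:n, :n] = a
    bp[:n, :n] = b
    cross = np.fft.fft2(ap) * np.conj(np.fft.fft2(bp))
    cc_raw = np.fft.ifft2(cross).real
    tau = np.minimum(np.arange(2 * n), 2 * n - np.arange(2 * n))
    lam = np.maximum(1.0 - tau / n, 1e-6)
    cc = cc_raw / np.outer(lam, lam)
    m = max_shift
    allowed = np.zeros_like(cc, dtype=bool)
    allowed[:m + 1, :m + 1] = True
    allowed[:m + 1, -m:] = True
    allowed[-m:, :m + 1] = True
    allowed[-m:, -m:] = True
    iy, ix = np.unravel_index(np.argmax(np.where(allowed, cc, -np.inf)),
                              cc.shape)
    quality = float(cc_raw[iy, ix] / (na * nb))
    row = iy if iy <= n else iy - 2 * n
    col = ix if ix <= n else ix - 2 * n
    row, col = _upsampled_refine(np.fft.fft2(cc), float(row), float(col))
    return row, col, quality


def correct_drift(stressed: np.ndarray, relaxed: np.ndarray,
                  margin_frac: float = 0.2,
                  min_quality: float = 0.2) -> MatchedPair:
    """Estimate and remove rigid drift between a stressed/relaxed pair.

    The cell-free border frame (outer ``margin_frac`` of the image) is used
    as the registration region, so real bead displacements under the island
    do not bias the estimate.  The relaxed image is resampled by the
    estimated shift; subsequent PIV then measures pure deformation.
    """
    stressed = np.asarray(stressed, dtype=float)
    relaxed = np.asarray(relaxed, dtype=float)
    if stressed.shape != relaxed.shape:
        raise DataError("stressed and relaxed images must have the same shape")
    ny, nx = stressed.shape
    m = max(8, int(round(margin_frac * min(ny, nx))))
    frame = np.zeros((ny, nx), dtype=bool)
    frame[:m, :] = frame[-m:, :] = True
    frame[:, :m] = frame[:, -m:] = True

    a = np.where(frame, stressed, 0.0)
    b = np.where(frame, relaxed, 0.0)
    a = np.where(frame, a - a[frame].mean(), 0.0)
    b = np.where(frame, b - b[frame].mean(), 0.0)
    row, col, quality = _xcorr_peak(a, b, max_shift=m - 2)
    if quality < min_quality:
        raise RegistrationError(
            f"correlation peak {quality:.3f} below {min_quality}; "
            "cannot establish rigid drift")
    aligned_relaxed = ndimage.shift(relaxed, (row, col), order=3,
                                    mode="nearest")
    return MatchedPair(stressed=stressed, relaxed=aligned_relaxed,
                       applied_shift_px=(float(row), float(col)),
                       correlation_peak=quality)


# ---------------------------------------------------------------------------
# PIV
# ---------------------------------------------------------------------------

def piv_displacements(pair: MatchedPair, window_px: int = 32,
                      overlap: float = 0.5,
                      min_quality: float = 0.3) -> np.ndarray:
    """Window-wise displacement samples between relaxed and stressed images.

    Returns an (N, 5) array with columns (x_px, y_px, u_x_px, u_y_px,
    quality): window-centre position, bead displacement relaxed->stressed in
    pixels, and the normalized correlation peak.  Windows below
    ``min_quality`` or with no texture are dropped.
    """
    if window_px < 16:
        raise ConfigError("window_px must be >= 16")
    if not 0.0 <= overlap < 1.0:
        raise ConfigError("overlap must be in [0, 1)")
    stressed = pair.stressed
    relaxed = pair.relaxed
    ny, nx = stressed.shape
    if window_px > min(ny, nx):
        raise DataError("PIV window larger than image")
    step = max(1, int(round(window_px * (1.0 - overlap))))
    max_shift = window_px // 3
    samples = []
    for y0 in range(0, ny - window_px + 1, step):
        for x0 in range(0, nx - window_px + 1, step):
            wa = stressed[y0:y0 + window_px, x0:x0 + window_px]
            wb = relaxed[y0:y0 + window_px, x0:x0 + window_px]
            if wa.std() == 0 or wb.std() == 0:
                continue
            dy, dx, q = _xcorr_peak_linear(wa, wb, max_shift=max_shift)
            if q < min_quality:
                continue
            samples.append((x0 + window_px / 2.0, y0 + window_px / 2.0,
                            dx, dy, q))
    return np.asarray(samples, dtype=float).reshape(-1, 5)


def track_beads(pair: MatchedPair, predictor_samples: np.ndarray | None = None,
                detect_sigma_px: float = 1.0, min_distance_px: int = 3,
                threshold_rel: float = 0.2, patch_half_px: int = 5,
                min_quality: float = 0.3, n_iter: int = 3) -> np.ndarray:
    """Per-bead displacement refinement (PIV-guided particle tracking).

    Beads are detected as local maxima in the relaxed image; around every
    bead an 11x11 patch is cross-correlated against the stressed image
    starting at the position predicted by the coarse PIV field
    (``predictor_samples``, optional).  The stressed patch is re-extracted at
    the running estimate (iterative window offset, ``n_iter`` passes) so the
    loss-of-pairs bias of a single correlation pass cancels as the residual
    shift goes to zero.  Tracking resolves displacement structure below the
    PIV window scale, which window correlation alone smooths out.  Returns
    samples in the PIV schema (x_px, y_px, u_x_px, u_y_px, quality).
    """
    from scipy.ndimage import gaussian_filter, map_coordinates, spline_filter
    from skimage.feature import peak_local_max

    relaxed = pair.relaxed
    stressed = pair.stressed
    stressed_coeffs = spline_filter(stressed, order=3)
    ny, nx = relaxed.shape
    bg = float(np.median(relaxed))
    smoothed = gaussian_filter(relaxed, detect_sigma_px)
    peaks = peak_local_max(
        smoothed, min_distance=min_distance_px,
        threshold_abs=bg + threshold_rel * (smoothed.max() - bg))
    if len(peaks) == 0:
        raise DataError("no beads detected in the relaxed image")
    if predictor_samples is not None and len(predictor_samples) >= 3:
        pred = LinearNDInterpolator(predictor_samples[:, :2],
                                    predictor_samples[:, 2:4], fill_value=0.0)
        u0 = pred(peaks[:, 1], peaks[:, 0])  # (u_x, u_y) at bead positions
        u0 = np.nan_to_num(u0)
    else:
        u0 = np.zeros((len(peaks), 2))
    half = patch_half_px
    offs = np.arange(-half, half + 1, dtype=float)
    out = []
    for (y, x), (ux0, uy0) in zip(peaks, u0):
        iy, ix = int(round(y)), int(round(x))
        if not (half <= iy < ny - half and half <= ix < nx - half):
            continue
        pa = relaxed[iy - half:iy + half + 1, ix - half:ix + half + 1]
        uy_est, ux_est = float(uy0), float(ux0)
        quality = 0.0
        ok = True
        for _ in range(n_iter):
            cy, cx = iy + uy_est, ix + ux_est
            if not (half <= cy < ny - half - 1 and half <= cx < nx - half - 1):
                ok = False
                break
            gy = cy + offs[:, None] + np.zeros_like(offs)[None, :]
            gx = cx + np.zeros_like(offs)[:, None] + offs[None, :]
            pb = map_coordinates(stressed_coeffs, [gy, gx], order=3,
                                 prefilter=False)
            dy, dx, quality = _xcorr_peak(pb, pa, max_shift=half - 2)
            uy_est += dy
            ux_est += dx
            if abs(dy) < 0.005 and abs(dx) < 0.005:
                break
        if not ok or quality < min_quality:
            continue
        out.append((x, y, ux_est, uy_est, quality))
    return np.asarray(out, dtype=float).reshape(-1, 5)


def interpolate_to_grid(samples: np.ndarray, pixel_size_um: float,
                        spacing_um: float = DEFAULT_GRID_SPACING_UM,
                        image_shape_px: tuple[int, int] | None = None
                        ) -> DisplacementField:
    """Linearly interpolate PIV samples onto a regular grid.

    ``samples`` are PIV rows (x_px, y_px, u_x_px, u_y_px[, quality]).
    Piecewise-linear (Delaunay) interpolation; grid nodes outside the convex
    hull of the samples are masked invalid and set to zero so the field can
    be fed to the FFT-based inversion directly.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 3:
        raise DataError("need at least 3 displacement samples")
    pts = samples[:, :2] * pixel_size_um
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise DataError("displacement samples are collinear")
    u_um = samples[:, 2:4] * pixel_size_um
    if image_shape_px is not None:
        extent_x = image_shape_px[1] * pixel_size_um
        extent_y = image_shape_px[0] * pixel_size_um
    else:
        extent_x = pts[:, 0].max()
        extent_y = pts[:, 1].max()
    xs = np.arange(0.0, extent_x + spacing_um / 2, spacing_um)
    ys = np.arange(0.0, extent_y + spacing_um / 2, spacing_um)
    gx, gy = np.meshgrid(xs, ys)
    interp = LinearNDInterpolator(pts, u_um, fill_value=np.nan)
    vals = interp(np.column_stack([gx.ravel(), gy.ravel()]))
    ux = vals[:, 0].reshape(gx.shape)
    uy = vals[:, 1].reshape(gx.shape)
    valid = np.isfinite(ux) & np.isfinite(uy)
    ux = np.where(valid, ux, 0.0)
    uy = np.where(valid, uy, 0.0)
    return DisplacementField(u_x=ux, u_y=uy, grid_spacing_um=spacing_um,
                             valid_mask=valid)


# ---------------------------------------------------------------------------
# Boussinesq forward / inverse (FTTC)
# ---------------------------------------------------------------------------

def _pad_size(n: int, factor: int = 4) -> int:
    """Next power of two >= factor * n (wraparound suppression)."""
    return 1 << int(math.ceil(math.log2(factor * n)))


def _pixel_box_factor(shape: tuple[int, int], spacing_um: float) -> np.ndarray:
    """Fourier transform of the grid-cell box (tractions are piecewise
    constant per cell, not point sources)."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    return np.sinc(fx) * np.sinc(fy)


def _fourier_greens(shape: tuple[int, int], spacing_um: float,
                    gel: GelProperties
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boussinesq surface Green's tensor per Fourier mode (um/Pa)."""
    ny, nx = shape
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing_um)[:, None]
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing_um)[None, :]
    k = np.hypot(kx, ky)
    nu = gel.poisson_ratio
    e = gel.youngs_modulus_pa
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (e * k ** 3)
        gxx = pref * ((1.0 - nu) * k ** 2 + nu * ky ** 2)
        gyy = pref * ((1.0 - nu) * k ** 2 + nu * kx ** 2)
        gxy = pref * (-nu * kx * ky)
    gxx[0, 0] = gyy[0, 0] = gxy[0, 0] = 0.0  # DC mode undetermined
    return gxx, gxy, gyy


def forward_boussinesq(traction: TractionField, gel: GelProperties
                       ) -> DisplacementField:
    """Surface displacement generated by a traction field (forward model).

    The traction field is zero-padded to the next power of two >= twice its
    extent before the FFT so the periodic convolution approximates the open
    half-space; the DC mode is set to zero (displacements are defined up to a
    rigid translation, which TFM cannot observe anyway).
    """
    ny, nx = traction.shape
    py, px = _pad_size(ny), _pad_size(nx)
    tx = np.zeros((py, px))
    ty = np.zeros((py, px))
    tx[:ny, :nx] = traction.t_x
    ty[:ny, :nx] = traction.t_y
    gxx, gxy, gyy = _fourier_greens((py, px), traction.grid_spacing_um, gel)
    box = _pixel_box_factor((py, px), traction.grid_spacing_um)
    ftx = np.fft.fft2(tx)
    fty = np.fft.fft2(ty)
    ux = np.fft.ifft2(box * (gxx * ftx + gxy * fty)).real[:ny, :nx]
    uy = np.fft.ifft2(box * (gxy * ftx + gyy * fty)).real[:ny, :nx]
    return DisplacementField(u_x=ux, u_y=uy,
                             grid_spacing_um=traction.grid_spacing_um)


def fttc_inverse(disp: DisplacementField, gel: GelProperties,
                 regularization: float = 0.0,
                 taper_alpha: float = 0.2) -> TractionField:
    """Unconstrained Fourier-transform traction cytometry.

    Inverts u(k) = G(k) T(k) per mode.  ``regularization`` adds an optional
    Tikhonov term (0 = unconstrained).  Invalid nodes are zeroed, the field
    is apodized with a 2-D Tukey window (cosine taper over the outer
    ``taper_alpha`` fraction, where the cell-free margin carries little
    signal) and zero-padded to suppress wraparound of the slowly decaying
    displacement tails.
    """
    ny, nx = disp.shape
    if min(ny, nx) < 16:
        raise DataError("displacement grid too small for FTTC (< 16 x 16)")
    win = np.outer(tukey(ny, taper_alpha), tukey(nx, taper_alpha))
    ux0 = np.where(disp.valid_mask, disp.u_x, 0.0) * win
    uy0 = np.where(disp.valid_mask, disp.u_y, 0.0) * win
    py, px = _pad_size(ny), _pad_size(nx)
    ux = np.zeros((py, px))
    uy = np.zeros((py, px))
    ux[:ny, :nx] = ux0
    uy[:ny, :nx] = uy0
    gxx, gxy, gyy = _fourier_greens((py, px), disp.grid_spacing_um, gel)
    box = _pixel_box_factor((py, px), disp.grid_spacing_um)
    gxx, gxy, gyy = gxx * box, gxy * box, gyy * box
    fux = np.fft.fft2(ux)
    fuy = np.fft.fft2(uy)
    det = gxx * gyy - gxy ** 2
    if regularization > 0.0:
        # Tikhonov: T = (G'G + l^2 I)^-1 G' u for each (symmetric real) mode
        lam2 = regularization ** 2
        a11 = gxx ** 2 + gxy ** 2 + lam2
        a12 = gxy * (gxx + gyy)
        a22 = gyy ** 2 + gxy ** 2 + lam2
        b1 = gxx * fux + gxy * fuy
        b2 = gxy * fux + gyy * fuy
        deta = a11 * a22 - a12 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            ftx = (a22 * b1 - a12 * b2) / deta
            fty = (a11 * b2 - a12 * b1) / deta
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ftx = (gyy * fux - gxy * fuy) / det
            fty = (gxx * fuy - gxy * fux) / det
    ftx[0, 0] = fty[0, 0] = 0.0
    ftx[~np.isfinite(ftx)] = 0.0
    fty[~np.isfinite(fty)] = 0.0
    tx = np.fft.ifft2(ftx).real[:ny, :nx]
    ty = np.fft.ifft2(fty).real[:ny, :nx]
    return TractionField(t_x=tx, t_y=ty, grid_spacing_um=disp.grid_spacing_um,
                         gel=gel)


# ---------------------------------------------------------------------------
# Energy, balance, filtering and per-gel summaries
# ---------------------------------------------------------------------------

def strain_energy(traction: TractionField, disp: DisplacementField) -> float:
    """Total strain energy U = 1/2 sum(T . u) dA in joules."""
    if traction.shape != disp.shape:
        raise DataError("traction and displacement grids differ")
    if traction.grid_spacing_um != disp.grid_spacing_um:
        raise DataError("traction and displacement grid spacings differ")
    da_m2 = (traction.grid_spacing_um * 1e-6) ** 2
    mask = disp.valid_mask
    dot = (traction.t_x * disp.u_x + traction.t_y * disp.u_y)[mask]
    return float(0.5 * dot.sum() * 1e-6 * da_m2)  # u in um -> m


def equilibrium_ratio(traction: TractionField,
                      mask: np.ndarray | None = None) -> float:
    """Out-of-equilibrium force ratio |sum F| / sum |F| over masked nodes.

    Zero for a perfectly balanced island, one when all force vectors point
    the same way.  All-zero tractions give 0 by convention.
    """
    if mask is None:
        mask = np.ones(traction.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != traction.shape:
        raise DataError("mask shape mismatch")
    if not mask.any():
        raise DataError("island mask is empty")
    fx = traction.t_x[mask]
    fy = traction.t_y[mask]
    amp = np.hypot(fx, fy).sum()
    if amp == 0.0:
        return 0.0
    return float(np.hypot(fx.sum(), fy.sum()) / amp)


def filter_islands(records: Iterable[IslandRecord],
                   ratio_threshold: float = 0.10,
                   size_range_um2: tuple[float, float] | None = None
                   ) -> list[IslandRecord]:
    """Apply the force-balance and island-size filters.

    An island is discarded when its out-of-equilibrium ratio exceeds the
    threshold (strictly greater than, so ratio == threshold is retained) or
    its area falls outside ``size_range_um2``.  All records are annotated;
    the retained subset is returned.
    """
    if not 0.0 < ratio_threshold < 1.0:
        raise ConfigError("ratio_threshold must be in (0, 1)")
    retained = []
    for rec in records:
        rec.discard_reasons = []
        if rec.equilibrium_ratio > ratio_threshold:
            rec.discard_reasons.append(
                f"out-of-equilibrium force {rec.equilibrium_ratio:.3f} > "
                f"{ratio_threshold:.2f}")
        if size_range_um2 is not None:
            lo, hi = size_range_um2
            if not lo <= rec.area_um2 <= hi:
                rec.discard_reasons.append(
                    f"island area {rec.area_um2:.1f} um^2 outside "
                    f"[{lo:.1f}, {hi:.1f}]")
        rec.retained = not rec.discard_reasons
        if rec.retained:
            retained.append(rec)
    return retained


@dataclass
class GelSummary:
    """Per-gel means and fold-of-control normalization."""

    per_gel: pd.DataFrame
    per_island: pd.DataFrame


def summarize_by_gel(records: Sequence[IslandRecord],
                     control_condition: str) -> GelSummary:
    """Average retained island energy densities per gel; fold of control.

    Per gel and condition, the mean strain energy density across retained
    islands is computed; each condition mean is divided by the control mean
    of the same gel (fold of control).  Per-island folds (island density /
    same-gel control mean) are also reported so distribution tests can be
    run on individual islands.
    """
    rows = [
        dict(island_id=r.island_id, gel_id=r.gel_id,
             condition_id=r.condition_id,
             energy_density=r.energy_density_j_per_m2,
             strain_energy_j=r.strain_energy_j, area_um2=r.area_um2)
        for r in records if r.retained
    ]
    if not rows:
        raise DataError("no retained islands to summarize")
    per_island = pd.DataFrame(rows)
    per_gel = (per_island
               .groupby(["gel_id", "condition_id"], as_index=False)
               .agg(n_islands=("island_id", "size"),
                    mean_density=("energy_density", "mean")))
    controls = (per_gel[per_gel.condition_id == control_condition]
                .set_index("gel_id")["mean_density"])
    missing = sorted(set(per_gel.gel_id) - set(controls.index))
    if missing:
        raise NormalizationError(
            f"no retained {control_condition!r} island in gel(s): {missing}")
    per_gel["fold_of_control"] = (
        per_gel["mean_density"] / per_gel["gel_id"].map(controls).values)
    per_island["fold_of_control"] = (
        per_island["energy_density"]
        / per_island["gel_id"].map(controls).values)
    return GelSummary(per_gel=per_gel, per_island=per_island)


def analyze_island(stressed: np.ndarray, relaxed: np.ndarray,
                   island_mask_px: np.ndarray, gel: GelProperties,
                   pixel_size_um: float,
                   spacing_um: float = DEFAULT_GRID_SPACING_UM,
                   window_px: int = 32, overlap: float = 0.5,
                   regularization: float = 0.0,
                   island_id: str = "island", gel_id: str = "",
                   condition_id: str = "",
                   correct_drift_first: bool = True,
                   refine_tracking: bool = True
                   ) -> tuple[IslandRecord, DisplacementField, TractionField]:
    """Full single-island TFM analysis from a bead-image pair.

    Drift correction -> PIV -> per-bead tracking refinement -> grid
    interpolation -> FTTC inversion -> strain energy / density / balance
    ratio.  The island area comes from the user-supplied island mask
    (pixels); energy density is U divided by that area in SI units.
    """
    if correct_drift_first:
        pair = correct_drift(stressed, relaxed)
    else:
        pair = MatchedPair(np.asarray(stressed, float),
                           np.asarray(relaxed, float), (0.0, 0.0), 1.0)
    samples = piv_displacements(pair, window_px=window_px, overlap=overlap)
    if refine_tracking:
        tracked = track_beads(pair, predictor_samples=samples)
        if len(tracked) >= max(20, len(samples) // 2):
            samples = tracked
    disp = interpolate_to_grid(samples, pixel_size_um, spacing_um,
                               image_shape_px=stressed.shape)
    traction = fttc_inverse(disp, gel, regularization=regularization)
    u_total = strain_energy(traction, disp)
    island_mask_px = np.asarray(island_mask_px, dtype=bool)
    area_um2 = float(island_mask_px.sum()) * pixel_size_um ** 2
    # island mask resampled to the analysis grid for the balance ratio
    zoom = pixel_size_um / spacing_um
    grid_mask = ndimage.zoom(island_mask_px.astype(float), zoom, order=0)
    gy, gx = traction.shape
    grid_mask = grid_mask[:gy, :gx]
    pad_y, pad_x = gy - grid_mask.shape[0], gx - grid_mask.shape[1]
    if pad_y or pad_x:
        grid_mask = np.pad(grid_mask, ((0, pad_y), (0, pad_x)))
    grid_mask = grid_mask > 0.5
    if not grid_mask.any():
        raise DataError("island mask empty after resampling to grid")
    ratio = equilibrium_ratio(traction, grid_mask)
    density = u_total / (area_um2 * 1e-12) if area_um2 > 0 else math.nan
    rec = IslandRecord(island_id=island_id, island_mask=island_mask_px,
                       area_um2=area_um2, strain_energy_j=u_total,
                       energy_density_j_per_m2=density,
                       equilibrium_ratio=ratio, gel_id=gel_id,
                       condition_id=condition_id)
    return rec, disp, traction
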