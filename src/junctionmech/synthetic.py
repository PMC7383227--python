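"""Synthetic microscopy scenes with known ground truth.

Every downstream stage of the package (TFM, FRET, morphometry) is exercised
on data produced here: bead-image pairs displaced by a known, force-balanced
traction field on a cell-island footprint; three-cube and acceptor-bleach
FRET channel sets with known true efficiency, crossover and bleach depth; and
polygonal cell mosaics with junctional ridges and seeded junction gaps.

All generators are deterministic given identical scene parameters (the RNG is
seeded from ``SceneParams.rng_seed``), emit a :class:`SyntheticTruth` record,
and can be written to disk as 16-bit TIFF images plus a JSON truth sidecar
(arrays stored as float TIFFs referenced from the JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .errors import ConfigError, DataError
from .tfm import (DisplacementField, GelProperties, TractionField,
                  forward_boussinesq)

__all__ = [
    "NoiseModel",
    "SceneParams",
    "SyntheticTruth",
    "make_island_traction",
    "render_bead_pair",
    "make_fret_threecube",
    "make_bleach_pair",
    "make_cell_mosaic",
    "write_image",
    "save_truth",
    "load_truth",
]


@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise: additive Gaussian (sd as a fraction of the dynamic
    range) plus optional Poisson shot noise (0 disables it)."""

    gaussian_sd: float = 0.02
    poisson_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ConfigError("noise parameters must be >= 0")

    def apply(self, image: np.ndarray, rng: np.random.Generator,
              dynamic_range: float) -> np.ndarray:
        out = image.astype(float)
        if self.poisson_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.poisson_scale
                              ) / self.poisson_scale
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd * dynamic_range,
                                   size=out.shape)
        return out


@dataclass(frozen=True)
class SceneParams:
    """Common imaging-scene parameters shared by all generators."""

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.325
    rng_seed: int = 0
    noise_model: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if min(self.image_size_px) < 64:
            raise ConfigError("image dimensions must be >= 64 px")
        if not self.pixel_size_um > 0:
            raise ConfigError("pixel_size_um must be > 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream])

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.image_size_px[0] * self.pixel_size_um,
                self.image_size_px[1] * self.pixel_size_um)


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted by every generator."""

    kind: str  # tfm | fret_bleach | fret_threecube | mosaic
    parameters: dict
    ground_truth: dict
    rng_seed: int


# ---------------------------------------------------------------------------
# TFM scenes
# ---------------------------------------------------------------------------

_PATTERNS = ("contractile_dipole", "ring", "random_balanced")


def make_island_traction(scene: SceneParams, footprint_radius_um: float,
                         magnitude_pa: float,
                         pattern: str = "contractile_dipole"
                         ) -> TractionField:
    """Force-balanced traction field on a circular cell-island footprint.

    The footprint must leave a cell-free margin of at least 25% of the image
    width on all sides (the no-displacement region required for drift
    registration).  The field is zero outside the footprint and exactly
    balanced: the mean traction over the footprint is subtracted before a
    final rescale to the requested peak magnitude, so |sum F| / sum |F| is at
    machine-precision level.
    """
    if pattern not in _PATTERNS:
        raise ConfigError(f"unknown pattern {pattern!r}; one of {_PATTERNS}")
    if magnitude_pa < 0:
        raise ConfigError("magnitude_pa must be >= 0")
    h_um, w_um = scene.extent_um
    margin = 0.25 * w_um
    if footprint_radius_um <= 0 or footprint_radius_um + margin > min(h_um, w_um) / 2:
        raise ConfigError(
            f"footprint radius {footprint_radius_um} um does not fit with a "
            f"margin of 25% of the image width ({margin:.1f} um)")

    ny, nx = scene.image_size_px
    y = (np.arange(ny) - (ny - 1) / 2) * scene.pixel_size_um
    x = (np.arange(nx) - (nx - 1) / 2) * scene.pixel_size_um
    gy, gx = np.meshgrid(y, x, indexing="ij")
    r = np.hypot(gx, gy)
    footprint = r <= footprint_radius_um

    rr = footprint_radius_um
    if pattern == "contractile_dipole":
        # two inward-pointing Gaussian force lobes on the x axis
        s = rr / 4.0
        d = rr / 2.0
        lobe_r = np.exp(-((gx - d) ** 2 + gy ** 2) / (2 * s ** 2))
        lobe_l = np.exp(-((gx + d) ** 2 + gy ** 2) / (2 * s ** 2))
        tx = -lobe_r + lobe_l
        ty = np.zeros_like(tx)
    elif pattern == "ring":
        band = np.exp(-((r - 0.8 * rr) ** 2) / (2 * (rr / 6.0) ** 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            tx = np.where(r > 0, -gx / np.maximum(r, 1e-9) * band, 0.0)
            ty = np.where(r > 0, -gy / np.maximum(r, 1e-9) * band, 0.0)
    else:  # random_balanced
        rng = scene.rng(stream=1)
        sigma_px = rr / 5.0 / scene.pixel_size_um
        tx = ndimage.gaussian_filter(rng.normal(size=(ny, nx)), sigma_px)
        ty = ndimage.gaussian_filter(rng.normal(size=(ny, nx)), sigma_px)

    tx = np.where(footprint, tx, 0.0)
    ty = np.where(footprint, ty, 0.0)
    if magnitude_pa == 0:
        return TractionField(np.zeros((ny, nx)), np.zeros((ny, nx)),
                             grid_spacing_um=scene.pixel_size_um)
    n_fp = footprint.sum()
    tx[footprint] -= tx[footprint].mean()
    ty[footprint] -= ty[footprint].mean()
    peak = np.hypot(tx, ty).max()
    if peak == 0:
        raise DataError("degenerate traction pattern")
    tx *= magnitude_pa / peak
    ty *= magnitude_pa / peak
    # re-center once more: the rescale preserves balance, this mops up
    # floating-point residue from the first pass
    tx[footprint] -= tx[footprint].sum() / n_fp
    ty[footprint] -= ty[footprint].sum() / n_fp
    return TractionField(t_x=tx, t_y=ty, grid_spacing_um=scene.pixel_size_um)


def island_footprint_mask(scene: SceneParams,
                          footprint_radius_um: float) -> np.ndarray:
    """Boolean island mask on the pixel grid (centre disk)."""
    ny, nx = scene.image_size_px
    y = (np.arange(ny) - (ny - 1) / 2) * scene.pixel_size_um
    x = (np.arange(nx) - (nx - 1) / 2) * scene.pixel_size_um
    gy, gx = np.meshgrid(y, x, indexing="ij")
    return np.hypot(gx, gy) <= footprint_radius_um


def _render_beads(shape: tuple[int, int], positions_px: np.ndarray,
                  sigma_px: float, amplitude: float,
                  baseline: float) -> np.ndarray:
    """Render isotropic Gaussian spots at sub-pixel positions."""
    img = np.full(shape, baseline, dtype=float)
    ny, nx = shape
    half = max(2, int(np.ceil(4 * sigma_px)))
    for py, px in positions_px:
        iy, ix = int(round(py)), int(round(px))
        y0, y1 = max(0, iy - half), min(ny, iy + half + 1)
        x0, x1 = max(0, ix - half), min(nx, ix + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None] - py
        xx = np.arange(x0, x1)[None, :] - px
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -(yy ** 2 + xx ** 2) / (2 * sigma_px ** 2))
    return img


def render_bead_pair(traction: TractionField, gel: GelProperties,
                     scene: SceneParams, n_beads: int = 2000,
                     bead_sigma_um: float | None = None,
                     drift_px: tuple[float, float] = (0.0, 0.0),
                     bead_amplitude: float = 1000.0,
                     baseline: float = 100.0
                     ) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Stressed/relaxed fluorescent-bead image pair for a traction scene.

    Beads are placed uniformly at random and rendered as isotropic Gaussian
    spots (default sigma 1 px, the diffraction-limited image of a 0.20 um
    bead).  The relaxed image shows the beads at rest; the stressed image
    shows the same beads displaced by the forward Boussinesq displacement of
    ``traction`` plus a rigid drift (row, col pixels).  Imaging noise follows
    the scene's noise model.  The truth record keeps the pixel-grid
    displacement field, traction and drift.
    """
    if n_beads < 50:
        raise ConfigError("n_beads must be >= 50")
    sigma_px = (1.0 if bead_sigma_um is None
                else bead_sigma_um / scene.pixel_size_um)
    if sigma_px <= 0:
        raise ConfigError("bead_sigma_um must be > 0")
    if traction.shape != tuple(scene.image_size_px):
        raise DataError("traction grid must match the scene pixel grid")
    disp = forward_boussinesq(traction, gel)
    u_px = np.stack([disp.u_y, disp.u_x]) / scene.pixel_size_um  # (row, col)
    max_u = float(np.abs(u_px).max())
    if max_u > 0.25 * min(scene.image_size_px):
        raise DataError(
            f"peak displacement {max_u:.1f} px exceeds 25% of the image; "
            "unphysical scene")

    rng = scene.rng(stream=2)
    ny, nx = scene.image_size_px
    pos = np.column_stack([rng.uniform(0, ny - 1, n_beads),
                           rng.uniform(0, nx - 1, n_beads)])
    u_at_beads = np.column_stack([
        ndimage.map_coordinates(u_px[0], pos.T, order=1, mode="nearest"),
        ndimage.map_coordinates(u_px[1], pos.T, order=1, mode="nearest"),
    ])
    relaxed = _render_beads((ny, nx), pos, sigma_px, bead_amplitude, baseline)
    stressed = _render_beads((ny, nx), pos + u_at_beads + np.asarray(drift_px),
                             sigma_px, bead_amplitude, baseline)
    noise_rng = scene.rng(stream=3)
    relaxed = scene.noise_model.apply(relaxed, noise_rng, bead_amplitude)
    stressed = scene.noise_model.apply(stressed, noise_rng, bead_amplitude)
    truth = SyntheticTruth(
        kind="tfm",
        parameters=dict(n_beads=n_beads, bead_sigma_px=sigma_px,
                        drift_px=list(map(float, drift_px)),
                        pixel_size_um=scene.pixel_size_um,
                        youngs_modulus_pa=gel.youngs_modulus_pa,
                        poisson_ratio=gel.poisson_ratio),
        ground_truth=dict(u_x_um=disp.u_x, u_y_um=disp.u_y,
                          t_x_pa=traction.t_x, t_y_pa=traction.t_y,
                          drift_px=list(map(float, drift_px))),
        rng_seed=scene.rng_seed)
    return stressed, relaxed, truth


# ---------------------------------------------------------------------------
# FRET scenes
# ---------------------------------------------------------------------------

def make_fret_threecube(scene: SceneParams, true_efficiency_map: np.ndarray,
                        donor_conc: np.ndarray, acceptor_conc: np.ndarray,
                        crossover_d: float, crossover_a: float,
                        background: float = 100.0
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                   SyntheticTruth]:
    """Three-cube (donor / FRET / acceptor filter) image set.

    Generative model: donor emission is quenched by transfer,
    I_DD = bg + D (1-E); the FRET channel carries the sensitized emission
    D*E plus donor bleed-through d and acceptor cross-excitation a,
    I_DA = bg + D E + d (I_DD - bg) + a (I_AA - bg); the acceptor channel is
    direct excitation, I_AA = bg + A.  Noise per the scene model.
    """
    e = np.asarray(true_efficiency_map, dtype=float)
    d_conc = np.asarray(donor_conc, dtype=float)
    a_conc = np.asarray(acceptor_conc, dtype=float)
    if e.min() < 0 or e.max() > 1:
        raise DataError("true efficiency map must lie in [0, 1]")
    if not (0 <= crossover_d < 1 and 0 <= crossover_a < 1):
        raise ConfigError("crossover coefficients must be in [0, 1)")
    donor_em = d_conc * (1.0 - e)
    sensitized = d_conc * e
    i_dd = background + donor_em
    i_aa = background + a_conc
    i_da = background + sensitized + crossover_d * donor_em + crossover_a * a_conc
    rng = scene.rng(stream=4)
    rng2 = scene.rng(stream=5)
    rng3 = scene.rng(stream=6)
    dyn = max(float(d_conc.max(initial=0.0)), float(a_conc.max(initial=0.0)),
              1.0)
    i_dd = scene.noise_model.apply(i_dd, rng, dyn)
    i_da = scene.noise_model.apply(i_da, rng2, dyn)
    i_aa = scene.noise_model.apply(i_aa, rng3, dyn)
    truth = SyntheticTruth(
        kind="fret_threecube",
        parameters=dict(crossover_d=crossover_d, crossover_a=crossover_a,
                        background=background),
        ground_truth=dict(true_efficiency=e, donor_conc=d_conc,
                          acceptor_conc=a_conc),
        rng_seed=scene.rng_seed)
    return i_dd, i_da, i_aa, truth


def make_bleach_pair(scene: SceneParams, true_efficiency: float,
                     bleach_fraction: float, donor_level: float = 1000.0,
                     acceptor_level: float = 1000.0, background: float = 0.0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                np.ndarray, SyntheticTruth]:
    """Donor/acceptor image quadruple for acceptor-photobleaching FRET.

    Donor dequenching is strictly proportional to the fraction ``b`` of
    acceptor destroyed: (D_post - D_pre) / D_post = b * E, i.e.
    D_post = D_pre / (1 - b E); a full bleach gives D_post = D_pre / (1 - E).
    Acceptor images encode the bleach depth, A_post = A_pre (1 - b).
    """
    if not 0.0 <= true_efficiency <= 1.0:
        raise ConfigError("true_efficiency must be in [0, 1]")
    if not 0.0 < bleach_fraction <= 1.0:
        raise ConfigError("bleach_fraction must be in (0, 1]")
    shape = tuple(scene.image_size_px)
    d_pre_level = donor_level * (1.0 - true_efficiency)
    d_post_level = d_pre_level / (1.0 - bleach_fraction * true_efficiency)
    d_pre = np.full(shape, background + d_pre_level)
    d_post = np.full(shape, background + d_post_level)
    a_pre = np.full(shape, background + acceptor_level)
    a_post = np.full(shape, background + acceptor_level * (1.0 - bleach_fraction))
    rngs = [scene.rng(stream=7 + i) for i in range(4)]
    dyn = max(donor_level, acceptor_level)
    d_pre = scene.noise_model.apply(d_pre, rngs[0], dyn)
    d_post = scene.noise_model.apply(d_post, rngs[1], dyn)
    a_pre = scene.noise_model.apply(a_pre, rngs[2], dyn)
    a_post = scene.noise_model.apply(a_post, rngs[3], dyn)
    truth = SyntheticTruth(
        kind="fret_bleach",
        parameters=dict(donor_level=donor_level, acceptor_level=acceptor_level,
                        background=background),
        ground_truth=dict(true_efficiency=true_efficiency,
                          bleach_fraction=bleach_fraction),
        rng_seed=scene.rng_seed)
    return d_pre, d_post, a_pre, a_post, truth


# ---------------------------------------------------------------------------
# Cell mosaics
# ---------------------------------------------------------------------------

def _order_edge_path(pixels: np.ndarray) -> np.ndarray:
    """Order border pixels into a path by greedy nearest-neighbour chaining."""
    pts = [tuple(p) for p in pixels]
    remaining = set(pts)
    # start from an extremal pixel (likely an endpoint of the border arc)
    start = min(remaining)
    path = [start]
    remaining.discard(start)
    while remaining:
        cur = path[-1]
        nxt = min(remaining,
                  key=lambda p: (p[0] - cur[0]) ** 2 + (p[1] - cur[1]) ** 2)
        path.append(nxt)
        remaining.discard(nxt)
    return np.asarray(path)


def _label_boundaries(labels: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Map each pair of adjacent labels to its shared-border pixel array.

    A pixel belongs to the border of (i, j) when its 4-neighbourhood contains
    both labels.  Border pixels are assigned to the lower-label side.
    """
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for axis in (0, 1):
        a = labels
        b = np.roll(labels, -1, axis=axis)
        diff = a != b
        if axis == 0:
            diff[-1, :] = False
        else:
            diff[:, -1] = False
        ys, xs = np.nonzero(diff)
        for y, x in zip(ys.tolist(), xs.tolist()):
            la = int(a[y, x])
            lb = int(b[y, x] if axis == 1 else b[y, x])
            key = (min(la, lb), max(la, lb))
            edges.setdefault(key, []).append((y, x))
    return {k: np.unique(np.asarray(v), axis=0) for k, v in edges.items()}


def make_cell_mosaic(scene: SceneParams, n_cells: int,
                     junction_width_px: float = 3.0,
                     n_disruptions: int = 0,
                     disruption_len_px: float = 15.0,
                     layout: str = "random",
                     edge_intensity: float = 1000.0,
                     interior_intensity: float = 100.0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                SyntheticTruth]:
    """Polygonal cell mosaic with junctional ridges and seeded gaps.

    Cells are a nearest-seed (Voronoi) tessellation of jittered-grid seed
    points (``layout='grid'`` uses the exact regular grid, requires square
    ``n_cells``).  The ZO-1 channel carries bright ridges on every shared
    border; the occludin channel carries the same ridges with
    ``n_disruptions`` contiguous gaps of ``disruption_len_px`` on distinct
    interior borders; the nuclei channel has one Gaussian blob per cell.
    Truth stores the label map and the disrupted-edge list.
    """
    if n_cells < 4:
        raise ConfigError("n_cells must be >= 4")
    ny, nx = scene.image_size_px
    side = int(round(np.sqrt(n_cells)))
    rng = scene.rng(stream=10)
    if layout == "grid":
        if side * side != n_cells:
            raise ConfigError("grid layout requires a square n_cells")
        jitter = 0.0
        rows = cols = side
    elif layout == "random":
        rows = cols = int(np.ceil(np.sqrt(n_cells)))
        jitter = 0.30
    else:
        raise ConfigError("layout must be 'random' or 'grid'")
    pitch_y, pitch_x = ny / rows, nx / cols
    seeds = []
    for i in range(rows):
        for j in range(cols):
            cy = (i + 0.5) * pitch_y
            cx = (j + 0.5) * pitch_x
            if jitter:
                cy += rng.uniform(-jitter, jitter) * pitch_y
                cx += rng.uniform(-jitter, jitter) * pitch_x
            seeds.append((cy, cx))
    seeds = np.asarray(seeds[:n_cells])

    marker = np.zeros((ny, nx), dtype=np.int32)
    for lbl, (cy, cx) in enumerate(seeds, start=1):
        marker[int(np.clip(round(cy), 0, ny - 1)),
               int(np.clip(round(cx), 0, nx - 1))] = lbl
    _, (iy, ix) = ndimage.distance_transform_edt(marker == 0,
                                                 return_indices=True)
    labels = marker[iy, ix]

    edges = _label_boundaries(labels)
    min_len = int(disruption_len_px) + 4
    eligible = [k for k, px in edges.items() if len(px) >= min_len]
    if n_disruptions > len(edges):
        raise ConfigError(
            f"{n_disruptions} disruptions requested but only {len(edges)} "
            "interior shared borders exist")
    if n_disruptions > len(eligible):
        raise ConfigError(
            f"only {len(eligible)} borders are long enough for "
            f"{disruption_len_px}-px gaps")

    boundary = np.zeros((ny, nx), dtype=bool)
    for px in edges.values():
        boundary[px[:, 0], px[:, 1]] = True

    disrupted = []
    occ_boundary = boundary.copy()
    if n_disruptions:
        chosen = rng.choice(len(eligible), size=n_disruptions, replace=False)
        for idx in sorted(chosen.tolist()):
            key = eligible[idx]
            path = _order_edge_path(edges[key])
            n_gap = int(disruption_len_px)
            start = (len(path) - n_gap) // 2
            gap = path[start:start + n_gap]
            occ_boundary[gap[:, 0], gap[:, 1]] = False
            disrupted.append(key)

    sigma = max(junction_width_px / 2.355, 0.5)  # FWHM ~ junction width

    def ridge_channel(mask: np.ndarray) -> np.ndarray:
        ridge = ndimage.gaussian_filter(mask.astype(float), sigma)
        peak = ridge.max() if ridge.max() > 0 else 1.0
        return interior_intensity + ridge / peak * (edge_intensity
                                                    - interior_intensity)

    zo1 = ridge_channel(boundary)
    occludin = ridge_channel(occ_boundary)
    nuclei = np.zeros((ny, nx))
    nuc_sigma = min(pitch_y, pitch_x) / 6.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    for cy, cx in seeds:
        nuclei += edge_intensity * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * nuc_sigma ** 2))
    rngs = [scene.rng(stream=11 + i) for i in range(3)]
    zo1 = scene.noise_model.apply(zo1, rngs[0], edge_intensity)
    occludin = scene.noise_model.apply(occludin, rngs[1], edge_intensity)
    nuclei = scene.noise_model.apply(nuclei, rngs[2], edge_intensity)
    truth = SyntheticTruth(
        kind="mosaic",
        parameters=dict(n_cells=n_cells, junction_width_px=junction_width_px,
                        n_disruptions=n_disruptions,
                        disruption_len_px=disruption_len_px, layout=layout),
        ground_truth=dict(label_map=labels,
                          disrupted_edges=[list(k) for k in disrupted],
                          seeds=seeds),
        rng_seed=scene.rng_seed)
    return zo1, occludin, nuclei, truth


# ---------------------------------------------------------------------------
# I/O: 16-bit TIFF images, JSON truth with float-TIFF array sidecars
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: np.ndarray,
                dynamic_max: float | None = None) -> None:
    """Write an image as 16-bit single-channel TIFF (values clipped/scaled)."""
    img = np.asarray(image, dtype=float)
    if dynamic_max is None:
        dynamic_max = max(float(img.max()), 1.0)
    scaled = np.clip(img / dynamic_max, 0.0, 1.0) * 65535.0
    tifffile.imwrite(str(path), scaled.astype(np.uint16))


def save_truth(truth: SyntheticTruth, directory: str | Path,
               name: str = "truth") -> Path:
    """Serialize a truth record: JSON scalars + float TIFF array sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = dict(kind=truth.kind, parameters=truth.parameters,
                   rng_seed=truth.rng_seed, ground_truth={}, arrays={})
    for key, val in truth.ground_truth.items():
        arr = np.asarray(val)
        if arr.dtype.kind in "fiub" and arr.ndim >= 2:
            fname = f"{name}_{key}.tif"
            tifffile.imwrite(str(directory / fname), arr.astype(np.float64))
            payload["arrays"][key] = fname
        else:
            payload["ground_truth"][key] = (
                arr.tolist() if isinstance(val, np.ndarray) else val)
    out = directory / f"{name}.json"
    out.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return out


def load_truth(json_path: str | Path) -> SyntheticTruth:
    json_path = Path(json_path)
    payload = json.loads(json_path.read_text())
    ground_truth = dict(payload["ground_truth"])
    for key, fname in payload["arrays"].items():
        ground_truth[key] = tifffile.imread(str(json_path.parent / fname))
    return SyntheticTruth(kind=payload["kind"],
                          parameters=payload["parameters"],
                          ground_truth=ground_truth,
                          rng_seed=payload["rng_seed"])
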