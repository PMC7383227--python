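"""Tight-junction-based cell segmentation and morphometry.

From a junction-marker channel (e.g. ZO-1), a binary ridge mask of the
cell-cell junction network is detected (Hessian/tubeness response with
hysteresis thresholds, Steger-style), cells are segmented as the enclosed
regions of the mask complement, per-cell apical areas are measured, junctional
protein recruitment is quantified from two opposing line-profile peaks per
cell, and junction disruptions (local absence of occludin between adjacent
cells) are counted and normalized per 100 cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold, sato
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import skeletonize

from .errors import ConfigError, DataError, SegmentationError

__all__ = [
    "JunctionMask",
    "CellSegmentation",
    "RecruitmentMeasurement",
    "DisruptionReport",
    "ridge_mask",
    "segment_cells",
    "recruitment_index",
    "detect_disruptions",
]


@dataclass
class JunctionMask:
    """Binary junctional ridge network plus the parameters that produced it."""

    mask: np.ndarray
    skeleton: np.ndarray
    source_channel: str = ""
    ridge_params: dict = field(default_factory=dict)


@dataclass
class CellSegmentation:
    """Labelled cells (0 = junction/background) with adjacency graph.

    ``filled_labels`` extends each cell label across the junction band
    (nearest-cell assignment) so that shared borders are well defined;
    ``adjacency`` maps each unordered cell pair to its shared-border pixels.
    Cells touching the image border are flagged and excluded from area
    statistics.
    """

    labels: np.ndarray
    filled_labels: np.ndarray
    areas_um2: dict[int, float]
    adjacency: dict[tuple[int, int], np.ndarray]
    border_cells: set[int]
    pixel_size_um: float

    @property
    def n_cells(self) -> int:
        return len(self.areas_um2)

    def interior_areas_um2(self) -> dict[int, float]:
        return {k: v for k, v in self.areas_um2.items()
                if k not in self.border_cells}


@dataclass
class RecruitmentMeasurement:
    """Per-cell junctional recruitment from two opposing profile peaks."""

    cell_id: int
    peaks: tuple[float, float]
    mean_peak: float
    image_mean: float

    @property
    def index(self) -> float:
        return self.mean_peak / self.image_mean


@dataclass
class DisruptionReport:
    """Junction disruptions normalized per 100 cells."""

    n_disruptions: int
    n_cells: int
    disrupted_edges: list[tuple[int, int]]

    @property
    def per_100_cells(self) -> float:
        return self.n_disruptions / self.n_cells * 100.0


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy ** 2 + xx ** 2) <= radius ** 2


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    lab = cc_label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[lab]


def ridge_mask(junction_channel: np.ndarray, sigma: float = 1.5,
               low_thr: float | None = None, high_thr: float | None = None,
               min_object_px: int = 50,
               source_channel: str = "") -> JunctionMask:
    """Binary mask of curvilinear junctional ridges.

    The ridge response is the Hessian-based tubeness (Sato) filter at scale
    ``sigma``; hysteresis thresholds default to the 99th/95th percentiles of
    the response.  Connected components smaller than ``min_object_px``
    (cytosolic specks) are removed.
    """
    img = np.asarray(junction_channel, dtype=float)
    if img.ndim != 2:
        raise DataError("junction channel must be a single-channel 2D image")
    if img.max() == img.min():
        raise SegmentationError("featureless (constant) junction channel")
    response = sato(img, sigmas=[sigma], black_ridges=False, mode="reflect")
    if high_thr is None:
        high_thr = float(np.percentile(response, 99.0))
    if low_thr is None:
        low_thr = float(np.percentile(response, 95.0))
    mask = apply_hysteresis_threshold(response, low_thr, high_thr)
    mask = _remove_small(mask, min_object_px)
    if not mask.any():
        raise SegmentationError("empty junction mask after thresholding")
    return JunctionMask(mask=mask, skeleton=skeletonize(mask),
                        source_channel=source_channel,
                        ridge_params=dict(sigma=sigma, low_thr=low_thr,
                                          high_thr=high_thr,
                                          min_object_px=min_object_px))


def segment_cells(mask: JunctionMask | np.ndarray, pixel_size_um: float = 1.0,
                  gap_close_px: int = 3,
                  min_cell_area_px: int = 64) -> CellSegmentation:
    """Single-step cell segmentation from a junction mask.

    Gaps up to ``gap_close_px`` in the junction network are bridged by
    morphological closing; the connected components of the mask complement
    become cells.  Adjacency is derived by extending each label across the
    junction band (nearest-cell assignment) and collecting shared-border
    pixels.  Cells touching the image border are flagged.
    """
    binary = mask.mask if isinstance(mask, JunctionMask) else np.asarray(mask)
    binary = binary.astype(bool)
    if gap_close_px > 0:
        s = _disk(gap_close_px)
        # erosion treats outside the image as junction so ridges that run
        # along the frame are not opened up
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(binary, structure=s), structure=s,
            border_value=1)
    else:
        closed = binary
    # one-pixel junction midline so cell areas extend to the ridge centre;
    # edge-padding keeps skeleton endpoints from retracting off the frame
    pad = gap_close_px + 4
    skeleton = skeletonize(np.pad(closed, pad, mode="edge"))[pad:-pad,
                                                            pad:-pad]
    cells = cc_label(~skeleton, connectivity=1)
    # drop sliver regions, relabel contiguously
    counts = np.bincount(cells.ravel())
    keep = np.nonzero(counts >= min_cell_area_px)[0]
    keep = keep[keep != 0]
    if keep.size == 0:
        raise SegmentationError("no enclosed cell regions found")
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    labels = remap[cells]

    # extend labels across the junction band to define shared borders
    _, (iy, ix) = ndimage.distance_transform_edt(labels == 0,
                                                 return_indices=True)
    filled = labels[iy, ix]

    adjacency: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for axis in (0, 1):
        b = np.roll(filled, -1, axis=axis)
        diff = filled != b
        if axis == 0:
            diff[-1, :] = False
        else:
            diff[:, -1] = False
        ys, xs = np.nonzero(diff)
        for y, x in zip(ys.tolist(), xs.tolist()):
            la, lb = int(filled[y, x]), int(b[y, x])
            if la == 0 or lb == 0:
                continue
            key = (min(la, lb), max(la, lb))
            adjacency.setdefault(key, []).append((y, x))
    adjacency_np = {k: np.unique(np.asarray(v), axis=0)
                    for k, v in adjacency.items()}

    areas = {int(lbl): float(n) * pixel_size_um ** 2
             for lbl, n in zip(*np.unique(labels, return_counts=True))
             if lbl != 0}
    border = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])).tolist())
    border.discard(0)
    return CellSegmentation(labels=labels, filled_labels=filled,
                            areas_um2=areas, adjacency=adjacency_np,
                            border_cells=border, pixel_size_um=pixel_size_um)


def _profile_peak(channel: np.ndarray, cells: CellSegmentation, cell_id: int,
                  centroid: tuple[float, float], direction: np.ndarray,
                  profile_length_px: int) -> float | None:
    """Peak intensity around the boundary crossing along one direction."""
    ny, nx = channel.shape
    max_steps = int(np.hypot(ny, nx))
    pos = np.asarray(centroid, dtype=float)
    crossing = None
    for step in range(1, max_steps):
        p = pos + step * direction
        iy, ix = int(round(p[0])), int(round(p[1]))
        if not (0 <= iy < ny and 0 <= ix < nx):
            return None  # profile exits the image before leaving the cell
        if cells.filled_labels[iy, ix] != cell_id:
            crossing = step
            break
    if crossing is None:
        return None
    half = profile_length_px / 2.0
    ts = np.linspace(crossing - half, crossing + half,
                     2 * profile_length_px + 1)
    pts = pos[None, :] + ts[:, None] * direction[None, :]
    inside = ((pts[:, 0] >= 0) & (pts[:, 0] <= ny - 1)
              & (pts[:, 1] >= 0) & (pts[:, 1] <= nx - 1))
    if not inside.any():
        return None
    vals = ndimage.map_coordinates(channel, pts[inside].T, order=1)
    return float(vals.max())


def recruitment_index(intensity_channel: np.ndarray,
                      cells: CellSegmentation,
                      profile_length_px: int = 20,
                      include_border_cells: bool = False
                      ) -> list[RecruitmentMeasurement]:
    """Junctional recruitment per cell, normalized to the image mean.

    For each cell two line profiles are cast from the centroid along the
    cell's minor axis in opposite directions; the maximum intensity within
    +-profile_length/2 of the boundary crossing is the junction peak.  The
    two peaks are averaged and divided by the mean integrated density of the
    entire image.  Cells whose profiles exit the image are skipped.
    """
    channel = np.asarray(intensity_channel, dtype=float)
    image_mean = float(channel.mean())
    if image_mean == 0:
        raise DataError("image mean integrated density is zero")
    results = []
    for prop in regionprops(cells.filled_labels):
        cid = int(prop.label)
        if not include_border_cells and cid in cells.border_cells:
            continue
        theta = prop.orientation  # major-axis angle vs row axis
        # minor axis is perpendicular to the major axis
        direction = np.array([np.sin(theta), np.cos(theta)])
        peaks = []
        for sign in (1.0, -1.0):
            peak = _profile_peak(channel, cells, cid, prop.centroid,
                                 sign * direction, profile_length_px)
            if peak is None:
                break
            peaks.append(peak)
        if len(peaks) != 2:
            warnings.warn(f"cell {cid}: profile exits image; skipped")
            continue
        results.append(RecruitmentMeasurement(
            cell_id=cid, peaks=(peaks[0], peaks[1]),
            mean_peak=float(np.mean(peaks)), image_mean=image_mean))
    return results


def detect_disruptions(occludin_channel: np.ndarray,
                       cells: CellSegmentation,
                       gap_fraction_thr: float = 0.5,
                       intensity_thr: float = 0.3,
                       window_px: int = 12) -> DisruptionReport:
    """Automated proxy for 'staining clearly absent between adjacent cells'.

    For every shared border, a window of ``window_px`` ordered border pixels
    slides along the border; the border is flagged disrupted when in some
    window at least ``gap_fraction_thr`` of the pixels fall below
    ``intensity_thr`` x (median junctional intensity).  The total count is
    normalized per 100 cells.
    """
    channel = np.asarray(occludin_channel, dtype=float)
    if not cells.adjacency:
        return DisruptionReport(0, cells.n_cells, [])
    all_border = np.concatenate(list(cells.adjacency.values()), axis=0)
    median_junction = float(np.median(channel[all_border[:, 0],
                                              all_border[:, 1]]))
    cutoff = intensity_thr * median_junction
    disrupted = []
    for key, px in cells.adjacency.items():
        order = np.lexsort((px[:, 1], px[:, 0]))
        # order along the border path for a meaningful sliding window
        path = _order_path(px[order])
        vals = channel[path[:, 0], path[:, 1]]
        low = vals < cutoff
        n = len(low)
        w = min(window_px, n)
        if w == 0:
            continue
        frac = np.convolve(low.astype(float), np.ones(w) / w, mode="valid")
        if frac.max() >= gap_fraction_thr:
            disrupted.append(key)
    return DisruptionReport(n_disruptions=len(disrupted),
                            n_cells=cells.n_cells,
                            disrupted_edges=disrupted)


def _order_path(pixels: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour chaining of border pixels into a path."""
    pts = [tuple(p) for p in pixels.tolist()]
    remaining = set(pts)
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
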