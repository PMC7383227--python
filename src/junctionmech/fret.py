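"""FRET efficiency quantification for tension-sensor imaging.

Two acquisition modes are supported:

* **Acceptor photobleaching** (confocal): the acceptor is destroyed and the
  donor dequenching quantifies transfer, E = (D_post - D_pre) / D_post * 100,
  optionally corrected for an incomplete bleach by dividing by the measured
  bleach depth b = (A_pre - A_post) / A_pre.

* **Three-cube sensitized emission** (filter-based epifluorescence): the
  FRET-filter image is corrected for donor bleed-through ``d`` and acceptor
  cross-excitation ``a`` calibrated from single-fluorophore samples,
  Fc = (I_DA - bg) - d (I_DD - bg) - a (I_AA - bg), and apparent per-pixel
  efficiency is E = Fc / (Fc + (I_DD - bg)) * 100.

Junctional FRET is summarized per junction segment, and efficiency changes
can be mapped to force (pN) through an externally supplied tension-sensor
calibration table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationError, ConfigError, DataError

__all__ = [
    "FRETCalibration",
    "BleachMeasurement",
    "FRETEfficiencyMap",
    "ForceCalibrationTable",
    "acceptor_bleach_efficiency",
    "calibrate_crossover",
    "sensitized_emission_map",
    "junctional_fret",
    "efficiency_to_force",
    "estimate_background",
]


@dataclass(frozen=True)
class FRETCalibration:
    """Crossover coefficients of the filter set.

    ``donor_bleedthrough_d``: fraction of donor-channel signal appearing in
    the FRET channel; ``acceptor_crossexcitation_a``: fraction of
    acceptor-channel signal appearing in the FRET channel.  Both are measured
    from cells expressing a single fluorophore.
    """

    donor_bleedthrough_d: float
    acceptor_crossexcitation_a: float
    source_images: dict | None = None

    def __post_init__(self) -> None:
        for name, v in (("d", self.donor_bleedthrough_d),
                        ("a", self.acceptor_crossexcitation_a)):
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"crossover coefficient {name} must be in [0, 1)")


@dataclass(frozen=True)
class BleachMeasurement:
    """Scalar ROI intensities for one acceptor-photobleaching measurement."""

    d_pre: float
    d_post: float
    a_pre: float = float("nan")
    a_post: float = float("nan")

    @property
    def bleach_depth(self) -> float:
        return (self.a_pre - self.a_post) / self.a_pre


@dataclass
class FRETEfficiencyMap:
    """Per-pixel apparent FRET efficiency in percent.

    Small negative values from noise are retained (not clipped) but flagged
    via ``negative_fraction``; pixels where the correction denominator is not
    positive are masked invalid (set to 0, excluded from statistics).
    """

    efficiency_pct: np.ndarray
    valid_mask: np.ndarray
    background_pct: float
    method: str  # acceptor_bleach | three_cube

    def median(self) -> float:
        return float(np.median(self.efficiency_pct[self.valid_mask]))

    @property
    def negative_fraction(self) -> float:
        vals = self.efficiency_pct[self.valid_mask]
        return float((vals < 0).mean()) if vals.size else 0.0


def acceptor_bleach_efficiency(m: BleachMeasurement,
                               correct_for_bleach_depth: bool = True
                               ) -> float:
    """FRET efficiency (%) from donor recovery after acceptor bleaching.

    E_raw = (D_post - D_pre) / D_post * 100; when correcting for an
    incomplete bleach, E = E_raw / b with b = (A_pre - A_post) / A_pre.
    """
    if not m.d_post > 0:
        raise DataError("D_post must be > 0")
    e_raw = (m.d_post - m.d_pre) / m.d_post * 100.0
    if not correct_for_bleach_depth:
        return float(e_raw)
    if not m.a_pre > 0:
        raise DataError("A_pre must be > 0 to measure the bleach depth")
    b = m.bleach_depth
    if not 0.0 < b <= 1.0:
        raise DataError(f"bleach depth {b:.3f} outside (0, 1]; no bleach?")
    return float(e_raw / b)


def estimate_background(image: np.ndarray, decile: float = 0.1) -> float:
    """Automatic background: mean of the lowest-intensity decile."""
    img = np.asarray(image, dtype=float).ravel()
    cutoff = np.quantile(img, decile)
    return float(img[img <= cutoff].mean())


def _crossover_coefficient(numerator: np.ndarray, denominator: np.ndarray,
                           bg_num: float, bg_den: float,
                           min_signal_frac: float = 0.1) -> float:
    num = np.asarray(numerator, dtype=float) - bg_num
    den = np.asarray(denominator, dtype=float) - bg_den
    peak = den.max()
    if peak <= 0:
        raise CalibrationError("foreground below background in the "
                               "calibration channel")
    fg = den > min_signal_frac * peak
    if not fg.any():
        raise CalibrationError("no usable foreground pixels for calibration")
    return float(np.median(num[fg] / den[fg]))


def calibrate_crossover(donor_only: Sequence[np.ndarray],
                        acceptor_only: Sequence[np.ndarray],
                        background: Sequence[float] = (0.0, 0.0, 0.0)
                        ) -> FRETCalibration:
    """Crossover coefficients from single-fluorophore three-cube sets.

    ``donor_only`` and ``acceptor_only`` are (I_DD, I_DA, I_AA) triples from
    samples expressing only the donor and only the acceptor, respectively;
    ``background`` gives per-channel background levels.  d is the median of
    (I_DA - bg) / (I_DD - bg) over donor foreground, a the median of
    (I_DA - bg) / (I_AA - bg) over acceptor foreground.
    """
    bg_dd, bg_da, bg_aa = background
    d_dd, d_da, _ = donor_only
    _, a_da, a_aa = acceptor_only
    d = _crossover_coefficient(d_da, d_dd, bg_da, bg_dd)
    a = _crossover_coefficient(a_da, a_aa, bg_da, bg_aa)
    return FRETCalibration(donor_bleedthrough_d=d,
                           acceptor_crossexcitation_a=a)


def sensitized_emission_map(i_dd: np.ndarray, i_da: np.ndarray,
                            i_aa: np.ndarray, cal: FRETCalibration,
                            background: Sequence[float] = (0.0, 0.0, 0.0)
                            ) -> FRETEfficiencyMap:
    """Apparent per-pixel FRET efficiency from a three-cube image set.

    Fc = (I_DA - bg) - d (I_DD - bg) - a (I_AA - bg);
    E = Fc / (Fc + (I_DD - bg)) * 100, masked wherever the denominator or the
    background-corrected donor signal is not positive.
    """
    i_dd = np.asarray(i_dd, dtype=float)
    i_da = np.asarray(i_da, dtype=float)
    i_aa = np.asarray(i_aa, dtype=float)
    if not (i_dd.shape == i_da.shape == i_aa.shape):
        raise DataError("three-cube images must share one shape")
    bg_dd, bg_da, bg_aa = background
    dd = i_dd - bg_dd
    fc = (i_da - bg_da) - cal.donor_bleedthrough_d * dd \
        - cal.acceptor_crossexcitation_a * (i_aa - bg_aa)
    denom = fc + dd
    valid = (denom > 0) & (dd > 0) & np.isfinite(denom)
    eff = np.zeros_like(fc)
    np.divide(fc, denom, out=eff, where=valid)
    eff *= 100.0
    return FRETEfficiencyMap(efficiency_pct=eff, valid_mask=valid,
                             background_pct=0.0, method="three_cube")


def junctional_fret(efficiency: FRETEfficiencyMap,
                    junction_segments: Sequence[np.ndarray],
                    image_background: float = 0.0
                    ) -> list[tuple[int, float]]:
    """Mean background-subtracted efficiency per junction segment.

    Each segment is a boolean mask (or pixel-index pair array); empty
    segments are skipped with a warning.  Returns (segment_id, value) pairs.
    """
    results = []
    for seg_id, seg in enumerate(junction_segments):
        seg = np.asarray(seg)
        if seg.dtype == bool:
            sel = seg & efficiency.valid_mask
            vals = efficiency.efficiency_pct[sel]
        else:  # (N, 2) pixel coordinates
            ys, xs = seg[:, 0], seg[:, 1]
            keep = efficiency.valid_mask[ys, xs]
            vals = efficiency.efficiency_pct[ys[keep], xs[keep]]
        if vals.size == 0:
            warnings.warn(f"junction segment {seg_id} is empty; skipped")
            continue
        results.append((seg_id, float(vals.mean() - image_background)))
    return results


@dataclass(frozen=True)
class ForceCalibrationTable:
    """Tension-sensor calibration: (efficiency_pct, force_pN) pairs.

    The module's force-extension calibration comes from the sensor
    literature and is consumed as external input; it must be strictly
    monotone so the interpolation is single-valued.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ConfigError("calibration table needs >= 2 points")
        eff = np.array([p[0] for p in self.points], dtype=float)
        force = np.array([p[1] for p in self.points], dtype=float)
        order = np.argsort(eff)
        eff, force = eff[order], force[order]
        if np.any(np.diff(eff) <= 0) or (
                not (np.all(np.diff(force) > 0) or np.all(np.diff(force) < 0))):
            raise ConfigError("calibration table must be strictly monotone")
        object.__setattr__(self, "_eff", eff)
        object.__setattr__(self, "_force", force)


def efficiency_to_force(delta_e_pct: float, table: ForceCalibrationTable
                        ) -> tuple[float, bool]:
    """Piecewise-linear force lookup for an efficiency change.

    Returns (force_pN, in_range).  Values beyond the table are clamped to the
    end point and flagged out-of-range rather than extrapolated.
    """
    eff = table._eff
    force = table._force
    in_range = bool(eff[0] <= delta_e_pct <= eff[-1])
    value = float(np.interp(delta_e_pct, eff, force))
    return value, in_range
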