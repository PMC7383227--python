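# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Elastic substrate model and FTTC

The hydrogel substrate is modeled as a linear-elastic, homogeneous,
isotropic half-space with Young's modulus `E` and Poisson ratio `ν`.
Surface displacement `u` and surface traction `T` are related in Fourier
space by the Boussinesq Green's tensor

    Ĝ(k) = 2(1+ν)/(E k³) · [[(1−ν)k² + ν k_y²,  −ν k_x k_y],
                             [−ν k_x k_y,  (1−ν)k² + ν k_x²]],

equivalently in real space G(r) = (1+ν)/(πE r³) · [[(1−ν)r² + ν x², ν x y],
[ν x y, (1−ν)r² + ν y²]]. The forward model (`forward_boussinesq`) and the
inverse (`fttc_inverse`, "unconstrained" = zero regularization; an optional
Tikhonov parameter is exposed for noisy data) invert this relation per
Fourier mode with the DC mode set to zero — rigid translations are
unobservable, and balanced tractions carry no DC component.

Numerical choices:

* **Padding.** Fields are zero-padded to the next power of two ≥ 4× their
  extent before the FFT. The Green's function decays like 1/r, so periodic
  images contaminate a 2×-padded solve at the percent level; 4× reduces the
  discrepancy against a direct-space quadrature oracle to ≲ 0.4% (the test
  suite checks ≤ 1% with a sharper field).
* **Pixel-box factor.** Tractions are treated as piecewise constant per grid
  cell, so the spectral kernel carries one `sinc(k_x h/2)·sinc(k_y h/2)`
  factor (the Fourier transform of the cell box). The same factor is used in
  forward and inverse directions, keeping the round trip self-consistent.
* **Apodization.** Before inversion the displacement field is multiplied by
  a 2-D Tukey window (cosine taper over the outer 20%). Island scenes keep a
  cell-free margin of ≥ 25% of the image width, so the taper only attenuates
  the low-signal margin while suppressing wraparound of the slowly decaying
  displacement tails.
* **Defaults.** `ν = 0.5` (near-incompressible polyacrylamide), grid spacing
  2.6 µm, `E` per gel (the TFM gels this workflow targets average ~16.4 kPa;
  1 and 40 kPa are typical coating stiffnesses for the culture experiments).

Strain energy is `U = ½ Σ (T·u) ΔA` over valid grid nodes, computed in SI
(tractions Pa, displacements converted µm → m, `ΔA = spacing²` in m²) and
reported in joules (pJ in CSV reports). Strain-energy density divides `U` by
the island area taken from the user-supplied island mask. The
out-of-equilibrium ratio is `|Σ F_i| / Σ |F_i|` over masked nodes; islands
with ratio **strictly greater** than 0.10 are discarded (a ratio of exactly
0.10 is retained), followed by an optional island-size filter.

## Displacement measurement

1. **Drift correction** (`correct_drift`): rigid drift between the stressed
   and relaxed bead images is estimated by FFT cross-correlation restricted
   to the cell-free border frame (outer 20% of the image), so real
   deformation under the island cannot bias the estimate. The correlation
   peak is refined on a 32×-upsampled local DFT grid (matrix-DFT evaluation)
   with a final three-point fit; a normalized peak correlation below 0.2
   raises a registration error. The relaxed image is resampled by the
   estimated shift (cubic spline).
2. **Window PIV** (`piv_displacements`): 32-px windows with 50% overlap
   (defaults), zero-padded *linear* normalized cross-correlation per window
   with triangular-overlap normalization — dividing out the finite-window
   overlap removes the systematic loss-of-pairs bias toward zero lag —
   followed by the same upsampled-DFT sub-pixel refinement. Samples with
   peak correlation below 0.3 are dropped.
3. **Bead tracking** (`track_beads`): beads are detected as local maxima in
   the relaxed image and each is tracked by correlating an 11×11 patch
   against the stressed image, starting from the PIV prediction and
   iterating the patch offset (3 passes, re-extracting the stressed patch at
   the running estimate by spline interpolation) so the residual shift — and
   with it the correlation bias — goes to zero. Window PIV alone attenuates
   displacement structure at or below the window scale, which biases strain
   energy low by tens of percent on island-scale fields; tracking restores
   per-bead resolution at ~0.02–0.05 px noise. `analyze_island` therefore
   uses PIV as the coarse predictor and tracking for the final samples.
4. **Gridding** (`interpolate_to_grid`): piecewise-linear (Delaunay)
   interpolation of the samples onto the regular analysis grid; nodes
   outside the convex hull are masked invalid and set to zero for the FFT.

## FRET quantification

*Acceptor photobleaching*: `E_raw = (D_post − D_pre)/D_post · 100`; when
correcting for an incomplete bleach, `E = E_raw / b` with
`b = (A_pre − A_post)/A_pre` measured from the acceptor images. The
synthetic generator assumes donor dequenching strictly proportional to the
fraction of acceptor destroyed (`(D_post − D_pre)/D_post = b·E`), which
makes the correction exactly invertible on noiseless data; the tests verify
that recovered efficiency is independent of bleach depth over b ∈ {0.4, 0.6,
1.0}.

*Three-cube sensitized emission*: crossover coefficients are calibrated from
single-fluorophore samples as medians of `(I_DA − bg)/(I_DD − bg)` (donor
bleed-through `d`) and `(I_DA − bg)/(I_AA − bg)` (acceptor cross-excitation
`a`) over foreground pixels. The corrected FRET signal is
`Fc = (I_DA − bg) − d(I_DD − bg) − a(I_AA − bg)` and the apparent per-pixel
efficiency `E = Fc/(Fc + (I_DD − bg)) · 100`. Vendor software implements
proprietary variants of this correction; the package uses the
literature-standard form, which reduces to the correct limits (no transfer →
0, no crossover → pure sensitized emission) — all downstream comparisons are
across conditions, for which the common scale cancels. Pixels with
non-positive denominator are masked invalid rather than propagated as NaN;
negative efficiencies from noise are kept (flagged via the negative-pixel
fraction) to preserve unbiased statistics near zero.

Background defaults to the mean of the lowest intensity decile
(`estimate_background`); an explicit ROI value can be supplied instead.

Efficiency changes map to force through an externally supplied, strictly
monotone tension-sensor calibration table (piecewise-linear interpolation;
out-of-range queries are clamped and flagged, not extrapolated). The table
itself comes from published sensor calibrations and is consumed as input —
this package does not re-derive it.

## Junction morphometry

Ridges of the junctional network are detected with a Hessian-based tubeness
(Sato) response at scale `sigma` (default 1.5 px ≈ junction width / (2√3)),
binarized by hysteresis thresholds defaulting to the 99th/95th percentiles
of the response, and cleaned of connected components below `min_object_px`.
Cells are the connected components of the complement after morphological gap
closing (≤ 3 px) and skeletonization of the closed mask to a one-pixel
junction midline — cell areas therefore extend to the ridge centerline,
matching the truth tessellation to within ~2–3% on noiseless mosaics.
Skeletonization is performed on an edge-padded copy so skeleton endpoints do
not retract from the image frame (which would merge border cells). Cells
touching the image border are flagged and excluded from area statistics.
Adjacency (shared borders with pixel lists) is derived by nearest-cell
extension of the labels across the junction band.

Junctional recruitment per cell casts two opposite line profiles from the
centroid along the cell's minor axis, takes each profile's maximum within
± half a profile length of the boundary crossing, averages the two peaks and
divides by the image mean intensity. The minor-axis choice is a geometric
convention; the index is invariant to global intensity scaling.

Disruption detection is an automated proxy for manual scoring of "staining
clearly absent between two adjacent cells": a 12-px window slides along each
ordered shared border, and the border counts as disrupted when ≥ 50% of some
window's pixels fall below 0.3× the median junctional intensity. Totals are
normalized per 100 cells. The thresholds are validated against synthetic
truth only; they are not calibrated to any manual count.

## Statistics

Group comparisons use rank-based tests via scipy: Kruskal–Wallis H (tie
corrected, χ² reference), Wilcoxon rank-sum (exact null for combined
n ≤ 25 and untied data, otherwise normal approximation with continuity
correction), and the Wilcoxon signed-rank test against a standard (zero
differences dropped; exact for n ≤ 25). P-values are two-sided; the
two-sided exact convention is the doubled one-sided tail capped at 1, which
the test suite verifies against exhaustive enumeration for all n ≤ 8.
Quantiles use linear interpolation (type 7). No multiple-testing correction
is applied. Box-plot summaries report median and quartiles with individual
data points overlaid.

## Synthetic data: what it emulates, and what it does not

The generators emulate the measurement geometry and noise of the study
designs the analysis targets: cell islands (radius ~30–45 µm ≈ 10–20
epithelial cells) on ~16 kPa gels exerting peak tractions of a few hundred
Pa (contractile dipole, inward ring, or smoothed random balanced fields; all
exactly force-balanced by mean subtraction over the footprint and zero
outside it, with a cell-free margin ≥ 25% of the image width); ~0.2 µm
fiducial beads rendered as 1-px Gaussian spots at uniform random positions,
displaced by the forward model plus rigid drift; Gaussian read noise at 2%
of dynamic range by default (Poisson shot noise optional, off by default);
uniform-efficiency FRET fields with known crossover and bleach depth; and
Voronoi cell mosaics (jittered-grid seeds) with Gaussian-profile junctional
ridges and seeded contiguous occludin gaps.

They deliberately do **not** model: 3-D image stacks or focus selection
(single best-focus planes only), full optical PSFs, photobleaching kinetics
over time, spatially varying FRET within a junction, gel thickness effects
(the half-space assumption), cell-shaped island outlines (disks), or
biological variability beyond the explicit magnitude/size jitter. Passing
tests therefore demonstrate correctness of the *computational* chain under
controlled imaging physics, not robustness to every property of real
micrographs.

The two-condition study (`studies.two_condition_tfm_study`) imposes a known
density effect by scaling treated traction magnitude by √ratio, draws island
radii from a narrow pool (35–41 µm; the analysis filters islands to
comparable sizes) with ±5% magnitude jitter, and analyzes ~10 islands per
condition over 3 gels at the 128² grid / 2.6 µm scale — sizes chosen so the
full validation chain runs in seconds while each stage operates in its
realistic regime. The fold-of-control signed-rank test is applied to
per-island folds (island density ÷ same-gel control mean); per-gel means and
folds are reported alongside.

## Degenerate inputs and error behaviour

Constant images fail ridge detection explicitly; all-zero tractions define
an equilibrium ratio of 0; identical data give p = 1 with a degeneracy
warning rather than an error; empty junction segments are skipped with a
warning; registration with a correlation peak < 0.2 and calibration without
usable foreground raise typed errors that the CLI maps to exit codes
(2 configuration, 3 data, 4 numerical).

## Known limitations

* Unconstrained inversion amplifies high-frequency displacement noise; the
  tracking-based measurement keeps this tolerable at ~2000 beads, but very
  sparse bead fields would need the optional Tikhonov term, at the price of
  underestimated tractions.
* Energy recovery from bead images is biased low by a few percent
  (finite sampling of the displacement field); the round-trip tests bound
  this at the study conditions.
* The disruption thresholds are synthetic-truth validated stand-ins for a
  manual criterion; on real data they would need a sensitivity check.
* The bleach-pair model treats dequenching as strictly proportional to
  bleach depth; for very high efficiencies and shallow bleaches, real
  photophysics deviates from this first-order picture.
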