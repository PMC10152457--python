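"""Spectral preprocessing chain for FTIR tissue cubes.

The chain, applied in this fixed order:

1. **Quality gate** — pixels whose Amide I absorbance (channel nearest
   1650 cm⁻¹) is strictly below 0.1 or strictly above 2 AU are masked out
   (sub-optimal section thickness); boundary values are kept.
2. **Truncation and paraffin omission** — the grid is truncated to the
   fingerprint region 900–1800 cm⁻¹, and the paraffin-dominated interval
   1350–1500 cm⁻¹ (inclusive) is masked from analysis while remaining in
   storage for display (e.g. ratio images).
3. **Rubber-band baseline correction** — per pixel, the greatest convex
   minorant of the spectrum (the lower boundary of the convex hull of the
   (ν, A) points) is subtracted.  The baseline is computed on the full
   retained range including the masked paraffin channels: the hull is more
   stable on a contiguous range, and the paraffin region is excluded from
   analysis, not from correction.
4. **Vector normalisation** — each spectrum is scaled to unit Euclidean
   norm, the norm being taken over *analysis* (unmasked) channels only so
   that paraffin intensity cannot influence the tissue-spectrum scale;
   masked channels are scaled by the same factor for display consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import SpectralCube, Spectrum

__all__ = [
    "PreprocessParams",
    "quality_filter",
    "truncate_and_mask",
    "rubberband_baseline",
    "rubberband_baseline_matrix",
    "vector_normalise",
    "preprocess_cube",
]

AMIDE_I_CM1 = 1650.0


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable parameters of the preprocessing chain (defaults as above)."""

    amide_low: float = 0.1
    amide_high: float = 2.0
    keep: tuple = (900.0, 1800.0)
    omit: tuple = (1350.0, 1500.0)


def quality_filter(cube: SpectralCube, low: float = 0.1, high: float = 2.0) -> SpectralCube:
    """Mask pixels with out-of-range Amide I absorbance.

    A pixel is removed iff its absorbance ``a`` at the channel nearest
    1650 cm⁻¹ satisfies ``a < low`` or ``a > high`` — strict inequalities,
    so boundary values are kept.  Absorbance values are never altered.
    """
    w = cube.wavenumbers
    if not (w[0] <= AMIDE_I_CM1 <= w[-1]):
        raise ValueError(
            f"Amide I ({AMIDE_I_CM1:g} cm⁻¹) lies outside the wavenumber range "
            f"[{w[0]:g}, {w[-1]:g}]"
        )
    out = cube.copy()
    amide = cube.absorbance[:, :, cube.nearest_channel(AMIDE_I_CM1)]
    bad = (amide < low) | (amide > high)
    out.pixel_mask &= ~bad
    out.provenance.append(f"quality_filter(low={low}, high={high})")
    return out


def truncate_and_mask(cube: SpectralCube, keep: tuple = (900.0, 1800.0),
                      omit: tuple = (1350.0, 1500.0)) -> SpectralCube:
    """Truncate the grid to ``keep`` and mask ``omit`` from analysis.

    Channels outside ``keep`` are dropped from storage; channels inside
    ``omit`` (inclusive endpoints) stay stored but have ``channel_mask``
    False so downstream analysis ignores them.
    """
    w = cube.wavenumbers
    keep_sel = (w >= keep[0]) & (w <= keep[1])
    if not keep_sel.any():
        raise ValueError(f"keep range {keep} does not intersect the grid")
    new_w = w[keep_sel]
    new_mask = cube.channel_mask[keep_sel].copy()
    if omit is not None:
        new_mask &= ~((new_w >= omit[0]) & (new_w <= omit[1]))
    if not new_mask.any():
        raise ValueError("no analysis channels remain after truncation and omission")
    out = SpectralCube(
        absorbance=cube.absorbance[:, :, keep_sel].copy(),
        wavenumbers=new_w.copy(),
        pixel_mask=cube.pixel_mask.copy(),
        channel_mask=new_mask,
        provenance=list(cube.provenance) + [f"truncate_and_mask(keep={keep}, omit={omit})"],
    )
    return out


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Greatest convex minorant of the points (x, y), evaluated at x.

    Andrew's monotone-chain lower hull; x must be strictly increasing.
    Interior points on a hull edge are popped (cross == 0), which leaves
    the interpolated baseline unchanged.
    """
    n = x.size
    hull = [0]
    for i in range(1, n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # cross product of (P_k - P_j) × (P_i - P_j); <= 0 means P_k is
            # on or above the chord P_j–P_i, so it is not a lower-hull vertex
            if (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def rubberband_baseline(spectrum: Spectrum) -> Spectrum:
    """Rubber-band baseline correction of a single spectrum.

    Subtracts the lower convex hull boundary (linear interpolation between
    hull vertices).  The result is non-negative to numerical precision and
    exactly zero at the first and last channel and at every hull vertex;
    residuals within double-precision noise of the baseline (|v| < 1e-12)
    are clamped to exactly zero so that meaningless sub-numerical orderings
    cannot masquerade as signal downstream.
    """
    v = spectrum.values
    if v.size < 3:
        raise ValueError("rubber-band correction needs at least 3 channels")
    if not np.all(np.isfinite(v)):
        raise ValueError("spectrum contains non-finite values")
    out = v - _lower_hull_baseline(spectrum.wavenumbers, v)
    out[np.abs(out) < 1e-12] = 0.0
    return Spectrum(out, spectrum.wavenumbers)


def rubberband_baseline_matrix(values: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """Row-wise rubber-band correction of an (n, channels) matrix."""
    if values.shape[1] < 3:
        raise ValueError("rubber-band correction needs at least 3 channels")
    if not np.all(np.isfinite(values)):
        raise ValueError("spectra contain non-finite values")
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        out[i] = values[i] - _lower_hull_baseline(wavenumbers, values[i])
    out[np.abs(out) < 1e-12] = 0.0
    return out


def vector_normalise(spectrum: Spectrum, channel_mask: np.ndarray = None) -> Spectrum:
    """Scale a spectrum to unit Euclidean norm over unmasked channels.

    Masked channels are divided by the same factor so ratios and displays
    remain consistent.  A zero norm signals a dead pixel that escaped the
    quality gate and raises.
    """
    v = spectrum.values
    if channel_mask is None:
        channel_mask = np.ones(v.size, dtype=bool)
    channel_mask = np.asarray(channel_mask, dtype=bool)
    norm = float(np.linalg.norm(v[channel_mask]))
    if norm == 0.0:
        raise ValueError("zero norm over unmasked channels (empty/dead pixel)")
    return Spectrum(v / norm, spectrum.wavenumbers)


def preprocess_cube(cube: SpectralCube, params: PreprocessParams = PreprocessParams()) -> SpectralCube:
    """Apply the full chain: gate → truncate/mask → rubber band → normalise.

    Only unmasked pixels are baseline-corrected and normalised (masked
    pixels keep their raw truncated spectra); provenance lists all four
    steps in order.
    """
    out = quality_filter(cube, params.amide_low, params.amide_high)
    out = truncate_and_mask(out, params.keep, params.omit)
    live = out.pixel_mask
    flat = out.absorbance[live]
    flat = rubberband_baseline_matrix(flat, out.wavenumbers)
    norms = np.linalg.norm(flat[:, out.channel_mask], axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm pixel after baseline correction escaped the quality gate")
    out.absorbance[live] = flat / norms[:, None]
    out.provenance.append("rubberband_baseline")
    out.provenance.append("vector_normalise")
    return out
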