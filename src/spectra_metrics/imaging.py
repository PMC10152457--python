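"""Rendering: single-metric ratio images and confidence-saturated
pseudo-colour tissue maps.

In a pseudo-colour map each pixel's hue encodes the predicted tissue class
and its saturation encodes the prediction confidence: a confidently
labelled pixel shows the pure class colour, an uncertain one fades towards
grey of the same brightness.  Saturation is linear in confidence by
default (``gamma`` reshapes the mapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

from .cube import SpectralCube
from .labelmap import EXCLUDED_LABEL, LabelMap
from .metrics import DEFAULT_EPS

__all__ = [
    "Palette",
    "default_palette",
    "ratio_image",
    "render_pseudocolour",
    "save_png",
]


@dataclass(frozen=True)
class Palette:
    """Class name → base sRGB colour (floats in [0, 1]); excluded pixels
    get their own colour (default black)."""

    colors: dict
    excluded: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        seen = set()
        for c, rgb in self.colors.items():
            if tuple(rgb) in seen:
                raise ValueError(f"palette colour for {c!r} duplicates another class")
            seen.add(tuple(rgb))


def default_palette(classes) -> Palette:
    """Maximally hue-spaced palette (full saturation and value).

    With up to ~12 classes the hue spacing stays ≥ 20°, so the class is
    recoverable from the rendered hue wherever saturation is non-zero.
    """
    classes = list(classes)
    hues = np.linspace(0.0, 1.0, len(classes), endpoint=False)
    colors = {c: tuple(hsv_to_rgb([h, 1.0, 1.0])) for c, h in zip(classes, hues)}
    return Palette(colors=colors)


def ratio_image(cube: SpectralCube, num_wn: float = 1252.0, den_wn: float = 1285.0,
                eps: float = DEFAULT_EPS) -> tuple:
    """Per-pixel absorbance ratio A(ν_num)/A(ν_den) over the stored grid.

    Returns ``(image, vmin, vmax)`` where masked pixels and undefined
    ratios are NaN and (vmin, vmax) span the finite values for colour
    scaling.  Wavenumbers must sit on the stored grid (within half a grid
    step of a channel).
    """
    w = cube.wavenumbers
    step = float(np.min(np.diff(w))) if w.size > 1 else 0.0
    idx = []
    for target in (num_wn, den_wn):
        i = cube.nearest_channel(target)
        if abs(w[i] - target) > step / 2 + 1e-9:
            raise ValueError(f"wavenumber {target:g} cm⁻¹ is not on the stored grid")
        idx.append(i)
    if idx[0] == idx[1]:
        raise ValueError("numerator and denominator wavenumbers coincide")
    num = cube.absorbance[:, :, idx[0]]
    den = cube.absorbance[:, :, idx[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        img = num / den
    img[np.abs(den) < eps] = np.nan
    img[~cube.pixel_mask] = np.nan
    finite = img[np.isfinite(img)]
    vmin = float(finite.min()) if finite.size else float("nan")
    vmax = float(finite.max()) if finite.size else float("nan")
    return img, vmin, vmax


def render_pseudocolour(labels: LabelMap, palette: Palette,
                        gamma: float = 1.0) -> np.ndarray:
    """Render a LabelMap as an 8-bit RGB raster.

    Pixel colour = the class base colour with its HSV saturation scaled by
    ``confidence ** gamma`` (value/brightness preserved); excluded pixels
    take the palette's excluded colour.
    """
    present = {l for l in labels.labels.ravel() if l != EXCLUDED_LABEL}
    missing = present - set(palette.colors)
    if missing:
        raise ValueError(f"palette lacks entries for classes {sorted(missing)}")
    rows, cols = labels.shape
    rgb = np.zeros((rows, cols, 3))
    hsv_base = {c: rgb_to_hsv(np.asarray(col, dtype=float))
                for c, col in palette.colors.items()}
    for c in present:
        sel = labels.labels == c
        h, s, v = hsv_base[c]
        conf = labels.confidence[sel] ** gamma
        hsv = np.empty((conf.size, 3))
        hsv[:, 0] = h
        hsv[:, 1] = s * conf
        hsv[:, 2] = v
        rgb[sel] = hsv_to_rgb(hsv)
    rgb[labels.labels == EXCLUDED_LABEL] = palette.excluded
    return np.round(rgb * 255).astype(np.uint8)


def save_png(raster: np.ndarray, path) -> None:
    Image.fromarray(raster, mode="RGB").save(path)
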