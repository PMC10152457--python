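"""Synthetic hyperspectral tissue phantoms with known ground truth.

The generator emulates the statistical structure that the metric-based
analysis assumes of mid-IR tissue images: every tissue class is a fixed
additive mixture of Gaussian absorbance bands (always including the protein
Amide I band at 1650 cm⁻¹ and Amide II near 1540 cm⁻¹, plus a small set of
class-discriminating bands), sitting on a smooth polynomial baseline drift,
contaminated by paraffin CH-deformation bands inside 1350–1500 cm⁻¹, and
degraded by independent additive Gaussian channel noise.  A configurable
number of "outlier" pixels are planted with Amide I absorbance outside the
(0.1, 2) quality window so the downstream quality gate can be verified
exactly.

Nothing here attempts physical optics (no Mie scattering, no dispersion);
the phantoms exist to make every downstream stage testable without real
tissue data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cube import SpectralCube, nearest_channel

__all__ = [
    "TissueProfile",
    "PhantomSpec",
    "generate_phantom",
    "default_seven_class_spec",
    "strip_layout",
    "AMIDE_I_CM1",
    "SEVEN_CLASSES",
]

AMIDE_I_CM1 = 1650.0
#: Tissue roster: carcinoma, inflamed tumour stroma, progenitor and
#: maturation epithelial layers, pre-existing normal stroma, submucosal
#: components (e.g. skeletal muscle) and lymphoid node tissue.
SEVEN_CLASSES = ("OSCC", "CS", "BL", "ML", "NS", "SM", "LYM")

# Paraffin CH2/CH3 deformation contamination: (centre cm⁻¹, relative amp, sigma)
_PARAFFIN_BANDS = ((1378.0, 0.6, 9.0), (1462.0, 1.0, 11.0))

# Amide I window (AU) outside which a pixel is a quality-gate violator.
_GATE_LOW, _GATE_HIGH = 0.1, 2.0


@dataclass(frozen=True)
class TissueProfile:
    """Spectral recipe for one tissue class.

    ``bands`` are Gaussian absorbance bands ``(centre cm⁻¹, amplitude AU,
    sigma cm⁻¹)``.  ``baseline_coeffs`` are polynomial coefficients
    ``(c0, c1, ...)`` applied to the normalised grid coordinate
    ``t = (ν − ν_min)/(ν_max − ν_min) ∈ [0, 1]``, lowest order first.
    """

    class_name: str
    bands: tuple
    baseline_coeffs: tuple = (0.0,)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        for centre, amp, width in self.bands:
            if amp < 0:
                raise ValueError(f"TissueProfile.bands: amplitude {amp} < 0 (class {self.class_name})")
            if width <= 0:
                raise ValueError(f"TissueProfile.bands: width {width} <= 0 (class {self.class_name})")
        if self.noise_sigma < 0:
            raise ValueError(f"TissueProfile.noise_sigma: {self.noise_sigma} < 0")
        if not any(abs(c - AMIDE_I_CM1) < 1e-9 for c, _, _ in self.bands):
            raise ValueError(
                f"TissueProfile.bands: class {self.class_name} lacks the required "
                f"Amide I band at {AMIDE_I_CM1:g} cm⁻¹"
            )

    def clean_spectrum(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Noise-free spectrum (bands + baseline) on ``wavenumbers``."""
        w = np.asarray(wavenumbers, dtype=float)
        out = np.zeros_like(w)
        for centre, amp, sigma in self.bands:
            out += amp * np.exp(-0.5 * ((w - centre) / sigma) ** 2)
        if any(c != 0 for c in self.baseline_coeffs):
            t = (w - w[0]) / (w[-1] - w[0]) if w[-1] > w[0] else np.zeros_like(w)
            out += np.polynomial.polynomial.polyval(t, np.asarray(self.baseline_coeffs, float))
        return out


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic image.

    ``region_layout`` assigns every pixel a class name (rows × cols array);
    if ``None``, :func:`strip_layout` splits the raster into equal
    contiguous blocks, one per class, in profile order.
    """

    class_profiles: tuple
    image_shape: tuple = (21, 21)
    region_layout: np.ndarray = None
    n_outlier_pixels: int = 0
    paraffin_band: float = 0.5
    wavenumber_grid: tuple = (900.0, 1800.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_profiles) == 0:
            raise ValueError("PhantomSpec.class_profiles: at least one profile required")
        names = [p.class_name for p in self.class_profiles]
        if len(set(names)) != len(names):
            raise ValueError("PhantomSpec.class_profiles: duplicate class names")
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"PhantomSpec.image_shape: non-positive {self.image_shape}")
        if self.n_outlier_pixels < 0 or self.n_outlier_pixels > rows * cols:
            raise ValueError(
                f"PhantomSpec.n_outlier_pixels: {self.n_outlier_pixels} outside [0, {rows * cols}]"
            )
        if self.paraffin_band < 0:
            raise ValueError(f"PhantomSpec.paraffin_band: {self.paraffin_band} < 0")
        lo, hi, step = self.wavenumber_grid
        if not (lo < hi and step > 0):
            raise ValueError(f"PhantomSpec.wavenumber_grid: invalid range {self.wavenumber_grid}")
        layout = self.region_layout
        if layout is None:
            layout = strip_layout(self.image_shape, names)
            object.__setattr__(self, "region_layout", layout)
        else:
            layout = np.asarray(layout)
            if layout.shape != tuple(self.image_shape):
                raise ValueError("PhantomSpec.region_layout: shape mismatch with image_shape")
            unknown = set(layout.ravel().tolist()) - set(names)
            if unknown:
                raise ValueError(f"PhantomSpec.region_layout: unknown class names {sorted(unknown)}")
            object.__setattr__(self, "region_layout", layout)

    @property
    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.wavenumber_grid
        return np.arange(lo, hi + step / 2, step)

    def profile(self, class_name: str) -> TissueProfile:
        for p in self.class_profiles:
            if p.class_name == class_name:
                return p
        raise KeyError(class_name)

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=int(seed))


def strip_layout(shape, class_names) -> np.ndarray:
    """Partition the raster (in row-major order) into near-equal contiguous
    blocks, one per class.  Covers every pixel exactly once by construction."""
    rows, cols = shape
    flat = np.empty(rows * cols, dtype=object)
    for block, name in zip(np.array_split(np.arange(rows * cols), len(class_names)),
                           class_names):
        flat[block] = name
    return flat.reshape(rows, cols)


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Generate one phantom image.

    Returns ``(cube, ground_truth)`` where ``ground_truth`` is the
    rows × cols array of true class names (a copy of the region layout).
    Exactly ``spec.n_outlier_pixels`` pixels are rescaled so their Amide I
    absorbance falls strictly outside (0.1, 2); every other pixel is
    guaranteed inside the window, so the quality gate removes exactly the
    planted set.  Bit-identical for identical specs (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.wavenumbers
    rows, cols = spec.image_shape
    n_ch = w.size
    layout = spec.region_layout

    clean = {p.class_name: p.clean_spectrum(w) for p in spec.class_profiles}
    paraffin = np.zeros(n_ch)
    if spec.paraffin_band > 0:
        for centre, rel, sigma in _PARAFFIN_BANDS:
            paraffin += spec.paraffin_band * rel * np.exp(-0.5 * ((w - centre) / sigma) ** 2)

    cube = np.empty((rows, cols, n_ch))
    for name, base in clean.items():
        mask = layout == name
        n_px = int(mask.sum())
        if n_px == 0:
            continue
        sigma = spec.profile(name).noise_sigma
        noise = rng.normal(0.0, sigma, size=(n_px, n_ch)) if sigma > 0 else 0.0
        cube[mask] = base + paraffin + noise

    amide_idx = nearest_channel(w, AMIDE_I_CM1)

    # Plant outliers: half scaled below the low gate bound, half above the
    # high bound, by direct amplitude scaling of the whole pixel spectrum.
    n_out = spec.n_outlier_pixels
    flat = cube.reshape(-1, n_ch)
    outlier_flat_idx = np.array([], dtype=int)
    if n_out > 0:
        outlier_flat_idx = rng.choice(rows * cols, size=n_out, replace=False)
        n_low = n_out // 2 + n_out % 2
        targets = np.concatenate([
            rng.uniform(0.02, 0.08, size=n_low),
            rng.uniform(2.2, 3.0, size=n_out - n_low),
        ])
        for i, target in zip(outlier_flat_idx, targets):
            current = flat[i, amide_idx]
            flat[i] *= target / current

    # Guarantee non-planted pixels pass the gate even under heavy noise, so
    # the planted count is exact for any spec.
    amide_vals = flat[:, amide_idx]
    inliers = np.ones(rows * cols, dtype=bool)
    inliers[outlier_flat_idx] = False
    bad = inliers & ((amide_vals <= _GATE_LOW + 0.02) | (amide_vals >= _GATE_HIGH - 0.05))
    for i in np.nonzero(bad)[0]:
        flat[i] *= 1.0 / flat[i, amide_idx]

    out_cube = SpectralCube(absorbance=cube, wavenumbers=w)
    return out_cube, layout.copy()


def _profile(name, extra_bands, noise_sigma):
    """Shared scaffold: protein amide bands + fingerprint bands common to
    soft tissue, plus the class-discriminating additions."""
    common = (
        (1650.0, 1.00, 16.0),   # Amide I
        (1540.0, 0.62, 13.0),   # Amide II
        (1455.0, 0.18, 10.0),   # CH2/CH3 deformation
        (1240.0, 0.30, 18.0),   # Amide III / phosphate
        (1080.0, 0.28, 20.0),   # nucleic acid / carbohydrate C–O
    )
    return TissueProfile(
        class_name=name,
        bands=common + tuple(extra_bands),
        baseline_coeffs=(0.04, 0.02),
        noise_sigma=noise_sigma,
    )


def default_seven_class_spec(seed: int = 0, noise_sigma: float = 0.02,
                             image_shape: tuple = (21, 21),
                             n_outlier_pixels: int = 0,
                             wavenumber_grid: tuple = (900.0, 1800.0, 4.0)) -> PhantomSpec:
    """Default seven-class phantom specification.

    Each class shares the soft-tissue scaffold and carries its own small set
    of discriminating bands (amplitudes 0.08–0.22 AU), so every pair of
    classes differs in at least one band position or amplitude.  The band
    positions echo the spectral neighbourhoods where the tissue classes are
    known to differ (amide shoulders near 1510–1570 cm⁻¹, high-wavenumber
    carbonyl bands near 1700 cm⁻¹), without attempting to reconstruct real
    tissue chemistry.  The default channel noise of 0.02 AU is a realistic
    detector-noise scale relative to the ≈1 AU Amide I peak.
    """
    extras = {
        "OSCC": ((1562.0, 0.20, 7.0), (1539.0, 0.14, 7.0)),
        "CS":   ((1570.0, 0.18, 7.0), (1684.0, 0.16, 8.0), (1284.0, 0.14, 9.0)),
        "BL":   ((1518.0, 0.18, 7.0), (1632.0, 0.16, 8.0)),
        "ML":   ((1699.0, 0.16, 7.0), (1514.0, 0.12, 7.0), (1168.0, 0.10, 9.0)),
        "NS":   ((1514.0, 0.20, 7.0), (1684.0, 0.10, 8.0), (1204.0, 0.12, 9.0)),
        "SM":   ((1643.0, 0.22, 8.0), (1510.0, 0.12, 7.0)),
        "LYM":  ((1715.0, 0.18, 7.0), (1703.0, 0.14, 7.0)),
    }
    profiles = tuple(_profile(name, extras[name], noise_sigma) for name in SEVEN_CLASSES)
    return PhantomSpec(
        class_profiles=profiles,
        image_shape=image_shape,
        n_outlier_pixels=n_outlier_pixels,
        paraffin_band=0.5,
        wavenumber_grid=wavenumber_grid,
        seed=int(seed),
    )
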