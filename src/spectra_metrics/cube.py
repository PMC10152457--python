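"""Core in-memory containers for hyperspectral absorbance data.

A :class:`SpectralCube` is a rows × cols × channels block of mid-IR
absorbance values (AU) on a shared, strictly increasing wavenumber grid
(cm⁻¹), together with two masks:

* ``pixel_mask`` — per-pixel usability flag (quality-gated pixels are
  switched off, their spectra are never deleted);
* ``channel_mask`` — per-channel analysis flag (e.g. the paraffin-dominated
  region is masked from analysis but kept in storage for display).

``provenance`` records the processing steps applied, in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "SpectralCube"]


@dataclass
class Spectrum:
    """A single pixel's absorbance sequence on a wavenumber grid."""

    values: np.ndarray
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.values.shape != self.wavenumbers.shape or self.values.ndim != 1:
            raise ValueError(
                "values and wavenumbers must be 1-D and of equal length, got "
                f"{self.values.shape} and {self.wavenumbers.shape}"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SpectralCube:
    """Hyperspectral absorbance cube with pixel/channel masks and provenance."""

    absorbance: np.ndarray                # (rows, cols, channels), AU
    wavenumbers: np.ndarray               # (channels,), cm⁻¹, strictly increasing
    pixel_mask: np.ndarray = None         # (rows, cols) bool, True = usable
    channel_mask: np.ndarray = None       # (channels,) bool, True = used in analysis
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.absorbance.ndim != 3:
            raise ValueError("absorbance must be rows × cols × channels")
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size != self.absorbance.shape[2]:
            raise ValueError("wavenumbers length must equal the channel dimension")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.pixel_mask is None:
            self.pixel_mask = np.ones(self.absorbance.shape[:2], dtype=bool)
        else:
            self.pixel_mask = np.asarray(self.pixel_mask, dtype=bool)
            if self.pixel_mask.shape != self.absorbance.shape[:2]:
                raise ValueError("pixel_mask shape must match the pixel grid")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.wavenumbers.size, dtype=bool)
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
            if self.channel_mask.shape != self.wavenumbers.shape:
                raise ValueError("channel_mask length must equal the channel dimension")

    @property
    def shape(self) -> tuple:
        return self.absorbance.shape

    @property
    def n_pixels(self) -> int:
        return self.absorbance.shape[0] * self.absorbance.shape[1]

    def copy(self) -> "SpectralCube":
        return SpectralCube(
            absorbance=self.absorbance.copy(),
            wavenumbers=self.wavenumbers.copy(),
            pixel_mask=self.pixel_mask.copy(),
            channel_mask=self.channel_mask.copy(),
            provenance=list(self.provenance),
        )

    def nearest_channel(self, wavenumber: float) -> int:
        """Index of the grid channel closest to ``wavenumber`` (cm⁻¹)."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def spectrum_at(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.absorbance[row, col], self.wavenumbers)


def nearest_channel(wavenumbers: np.ndarray, wavenumber: float) -> int:
    """Nearest-channel lookup on a bare wavenumber grid."""
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    return int(np.argmin(np.abs(wavenumbers - wavenumber)))
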