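"""Labelled spectra collections: the unit handed to training and evaluation.

Spectra are stored as a dense (n_spectra × n_channels) matrix rather than a
list of :class:`~spectra_metrics.cube.Spectrum` objects so that ratio and
AUC computations over tens of thousands of wavenumber pairs stay vectorised;
``spectrum(i)`` recovers the object view when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import Spectrum

__all__ = ["LabelledSpectra"]


@dataclass
class LabelledSpectra:
    """Parallel arrays of spectra, class labels and provenance identifiers.

    Parameters
    ----------
    values : (n, channels) absorbance matrix.
    wavenumbers : shared wavenumber grid (cm⁻¹).
    labels : class name per spectrum.
    image_ids : source image identifier per spectrum (for balanced sampling).
    patient_ids : source patient identifier per spectrum (for stratified CV).
    channel_mask : per-channel analysis flag shared by all spectra.
    """

    values: np.ndarray
    wavenumbers: np.ndarray
    labels: np.ndarray
    image_ids: np.ndarray = None
    patient_ids: np.ndarray = None
    channel_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        n = self.values.shape[0]
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.wavenumbers.size != self.values.shape[1]:
            raise ValueError("values must be (n, channels) matching wavenumbers")
        if self.labels.shape != (n,):
            raise ValueError("labels must parallel the spectra")
        if self.image_ids is None:
            self.image_ids = np.zeros(n, dtype=int)
        else:
            self.image_ids = np.asarray(self.image_ids)
            if self.image_ids.shape != (n,):
                raise ValueError("image_ids must parallel the spectra")
        if self.patient_ids is None:
            self.patient_ids = np.zeros(n, dtype=int)
        else:
            self.patient_ids = np.asarray(self.patient_ids)
            if self.patient_ids.shape != (n,):
                raise ValueError("patient_ids must parallel the spectra")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.wavenumbers.size, dtype=bool)
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
            if self.channel_mask.shape != self.wavenumbers.shape:
                raise ValueError("channel_mask must match the wavenumber grid")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def classes(self) -> list:
        return sorted(set(self.labels.tolist()))

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.values[i], self.wavenumbers)

    def subset(self, idx) -> "LabelledSpectra":
        idx = np.asarray(idx)
        return LabelledSpectra(
            values=self.values[idx],
            wavenumbers=self.wavenumbers,
            labels=self.labels[idx],
            image_ids=self.image_ids[idx],
            patient_ids=self.patient_ids[idx],
            channel_mask=self.channel_mask,
        )

    def concat(self, other: "LabelledSpectra") -> "LabelledSpectra":
        if not np.array_equal(self.wavenumbers, other.wavenumbers):
            raise ValueError("wavenumber grids differ")
        return LabelledSpectra(
            values=np.vstack([self.values, other.values]),
            wavenumbers=self.wavenumbers,
            labels=np.concatenate([self.labels, other.labels]),
            image_ids=np.concatenate([self.image_ids, other.image_ids]),
            patient_ids=np.concatenate([self.patient_ids, other.patient_ids]),
            channel_mask=self.channel_mask,
        )
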