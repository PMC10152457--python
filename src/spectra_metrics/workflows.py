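"""Convenience wiring between phantom generation, preprocessing and the
labelled-spectra containers used for training and evaluation."""

from __future__ import annotations

import numpy as np

from .cube import SpectralCube
from .dataset import LabelledSpectra
from .phantom import PhantomSpec, default_seven_class_spec, generate_phantom
from .preprocess import PreprocessParams, preprocess_cube

__all__ = ["cube_to_labelled", "make_phantom_dataset", "derive_seed"]

_SEED_STRIDE = 100003  # stage/image fan-out stride for the global seed


def derive_seed(seed: int, index: int) -> int:
    """Deterministic per-stage/per-image seed from one global seed."""
    return int((int(seed) * _SEED_STRIDE + index) % (2**31 - 1))


def cube_to_labelled(cube: SpectralCube, truth: np.ndarray, image_id=0,
                     patient_id=0) -> LabelledSpectra:
    """Flatten a (preprocessed) cube's unmasked pixels into labelled spectra."""
    live = cube.pixel_mask
    return LabelledSpectra(
        values=cube.absorbance[live],
        wavenumbers=cube.wavenumbers,
        labels=np.asarray(truth)[live].astype(object),
        image_ids=np.full(int(live.sum()), image_id),
        patient_ids=np.full(int(live.sum()), patient_id),
        channel_mask=cube.channel_mask,
    )


def make_phantom_dataset(n_images: int = 3, seed: int = 0,
                         spec: PhantomSpec = None,
                         params: PreprocessParams = PreprocessParams(),
                         one_patient_per_image: bool = True,
                         **spec_kwargs) -> LabelledSpectra:
    """Generate, preprocess and pool ``n_images`` phantom images.

    Each image gets its own derived seed (and, by default, its own patient
    identifier, so patient-stratified folds are exercised).  ``spec``
    overrides the default seven-class specification; ``spec_kwargs`` are
    forwarded to :func:`default_seven_class_spec` otherwise.
    """
    pooled = None
    for i in range(n_images):
        s = (spec or default_seven_class_spec(**spec_kwargs)).with_seed(
            derive_seed(seed, i))
        cube, truth = generate_phantom(s)
        cube = preprocess_cube(cube, params)
        part = cube_to_labelled(cube, truth, image_id=i,
                                patient_id=i if one_patient_per_image else 0)
        pooled = part if pooled is None else pooled.concat(part)
    return pooled
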