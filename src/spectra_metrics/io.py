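"""Cube containers: ENVI-style header+binary and a single HDF5 file.

The ENVI-style layout is the minimal interoperable subset: a text ``.hdr``
with samples/lines/bands, double-precision data, BSQ interleave and the
wavelength list, next to a flat ``.dat`` binary.  The HDF5 container holds
``/cube``, ``/wavenumbers``, ``/labels`` plus the two masks.  Ground-truth
labels also round-trip as ``(row, col, class_name)`` CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cube import SpectralCube

__all__ = [
    "write_envi", "read_envi",
    "write_hdf5", "read_hdf5",
    "write_labels_csv", "read_labels_csv",
]


def write_envi(cube: SpectralCube, path_base: str) -> tuple:
    """Write ``<path_base>.hdr`` + ``<path_base>.dat`` (BSQ, float64)."""
    rows, cols, bands = cube.shape
    hdr = path_base + ".hdr"
    dat = path_base + ".dat"
    wavelengths = ", ".join(f"{w:.6f}" for w in cube.wavenumbers)
    with open(hdr, "w") as fh:
        fh.write("ENVI\n")
        fh.write(f"samples = {cols}\n")
        fh.write(f"lines = {rows}\n")
        fh.write(f"bands = {bands}\n")
        fh.write("header offset = 0\n")
        fh.write("file type = ENVI Standard\n")
        fh.write("data type = 5\n")          # IEEE double
        fh.write("interleave = bsq\n")
        fh.write("byte order = 0\n")         # little endian
        fh.write("wavelength units = cm-1\n")
        fh.write(f"wavelength = {{ {wavelengths} }}\n")
    np.ascontiguousarray(np.moveaxis(cube.absorbance, 2, 0), dtype="<f8").tofile(dat)
    return hdr, dat


def read_envi(path_base: str) -> SpectralCube:
    fields = {}
    with open(path_base + ".hdr") as fh:
        text = fh.read()
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    if fields.get("interleave", "bsq") != "bsq" or fields.get("data type") != "5":
        raise ValueError("only BSQ float64 ENVI layouts are supported")
    w_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavenumbers = np.array([float(x) for x in w_text.split(",") if x.strip()])
    data = np.fromfile(path_base + ".dat", dtype="<f8")
    cube = np.moveaxis(data.reshape(bands, rows, cols), 0, 2)
    return SpectralCube(absorbance=cube, wavenumbers=wavenumbers)


def write_hdf5(cube: SpectralCube, path, labels: np.ndarray = None) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=cube.absorbance)
        fh.create_dataset("wavenumbers", data=cube.wavenumbers)
        fh.create_dataset("pixel_mask", data=cube.pixel_mask)
        fh.create_dataset("channel_mask", data=cube.channel_mask)
        fh.attrs["provenance"] = "\n".join(cube.provenance)
        if labels is not None:
            fh.create_dataset(
                "labels", data=np.char.encode(labels.astype(str), "utf-8"))


def read_hdf5(path) -> tuple:
    import h5py

    with h5py.File(path, "r") as fh:
        cube = SpectralCube(
            absorbance=fh["cube"][()],
            wavenumbers=fh["wavenumbers"][()],
            pixel_mask=fh["pixel_mask"][()],
            channel_mask=fh["channel_mask"][()],
            provenance=[s for s in fh.attrs.get("provenance", "").split("\n") if s],
        )
        labels = None
        if "labels" in fh:
            labels = np.char.decode(fh["labels"][()].astype("S"), "utf-8").astype(object)
    return cube, labels


def write_labels_csv(labels: np.ndarray, path) -> None:
    rows, cols = np.indices(labels.shape)
    pd.DataFrame({
        "row": rows.ravel(), "col": cols.ravel(), "class_name": labels.ravel(),
    }).to_csv(path, index=False)


def read_labels_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    out = np.empty((df["row"].max() + 1, df["col"].max() + 1), dtype=object)
    out[df["row"], df["col"]] = df["class_name"]
    return out
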