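"""Per-pixel classification result: predicted class + confidence grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LabelMap", "EXCLUDED_LABEL"]

#: Label for pixels removed by the quality gate or left unclassified.
EXCLUDED_LABEL = "excluded"


@dataclass
class LabelMap:
    """Rows × cols grid of class labels and confidence values in [0, 1].

    Excluded pixels carry :data:`EXCLUDED_LABEL` and confidence 0.
    """

    labels: np.ndarray       # (rows, cols) of class-name strings
    confidence: np.ndarray   # (rows, cols) floats in [0, 1]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.labels.shape != self.confidence.shape or self.labels.ndim != 2:
            raise ValueError("labels and confidence must be matching 2-D grids")
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise ValueError("confidence values must lie in [0, 1]")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.shape)
        return pd.DataFrame({
            "row": rows.ravel(), "col": cols.ravel(),
            "label": self.labels.ravel(), "confidence": self.confidence.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "LabelMap":
        df = pd.read_csv(path)
        rows, cols = df["row"].max() + 1, df["col"].max() + 1
        labels = np.empty((rows, cols), dtype=object)
        conf = np.zeros((rows, cols))
        labels[df["row"], df["col"]] = df["label"]
        conf[df["row"], df["col"]] = df["confidence"]
        return LabelMap(labels, conf)
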