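"""Committee-vote multi-class classifier built from ranked ratio metrics.

The model holds, for each tissue class, the top-k ranked metrics (k = 5 by
default, matching the size of the published per-class optimal sets).  To
classify a spectrum, every distinct metric in the union of the per-class
committees casts a vote: its ratio value is converted to per-class
likelihoods through the class PDFs, multiplied by the class prior and
normalised into a per-metric posterior.  The committee output is the mean
of these posteriors (equal-weight voting; a log-likelihood-sum combination
is available via ``combination="loglik"``).  Metrics whose ratio is
undefined for the spectrum abstain; if every metric abstains the spectrum
is unclassifiable.

The predicted label is the argmax class (ties broken by model class order)
and the confidence value is the maximum probability divided by the sum of
all class probabilities — equal to the maximum probability itself once the
outputs are normalised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cube import Spectrum, SpectralCube, nearest_channel
from .labelmap import EXCLUDED_LABEL, LabelMap
from .metrics import DEFAULT_EPS, Metric, Pdf

__all__ = [
    "DiscriminatorModel",
    "Prediction",
    "UnclassifiableSpectrumError",
    "build_model",
    "committee_probabilities",
    "predict",
    "predict_cube",
    "predict_matrix",
]


class UnclassifiableSpectrumError(ValueError):
    """Raised when every committee metric abstains on a spectrum."""


@dataclass
class Prediction:
    """Class probability vector plus the derived label and confidence."""

    class_probabilities: dict
    predicted: str
    confidence: float


@dataclass
class DiscriminatorModel:
    """Per-class optimal metric sets + committee voting rule."""

    classes: list
    committee: dict                      # class name → list of k Metrics
    k: int = 5
    prior: dict = None                   # class name → weight (default uniform)
    combination: str = "mean"            # "mean" | "loglik"
    eps: float = DEFAULT_EPS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a discriminator needs at least 2 classes")
        if self.prior is None:
            self.prior = {c: 1.0 / len(self.classes) for c in self.classes}
        for c, mets in self.committee.items():
            for m in mets:
                missing = [cl for cl in self.classes
                           if m.class_pdfs.get(cl) is None]
                if missing:
                    raise ValueError(
                        f"committee metric {m} for class {c!r} lacks PDFs for {missing}"
                    )

    def distinct_metrics(self) -> list:
        """Union of the per-class committees, deduplicated by pair."""
        seen, out = set(), []
        for c in self.classes:
            for m in self.committee.get(c, []):
                if m.pair not in seen:
                    seen.add(m.pair)
                    out.append(m)
        return out

    # --- serialisation (single JSON container; PDFs as grid arrays) -----

    def to_dict(self) -> dict:
        def metric_dict(m: Metric) -> dict:
            return {
                "numerator_wavenumber": m.numerator_wavenumber,
                "denominator_wavenumber": m.denominator_wavenumber,
                "auc": m.auc, "rank": m.rank,
                "class_pdfs": {c: p.to_dict() for c, p in m.class_pdfs.items()},
            }
        return {
            "classes": self.classes, "k": self.k, "prior": self.prior,
            "combination": self.combination, "eps": self.eps,
            "metadata": self.metadata,
            "committee": {c: [metric_dict(m) for m in mets]
                          for c, mets in self.committee.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "DiscriminatorModel":
        def metric_obj(md: dict) -> Metric:
            return Metric(
                md["numerator_wavenumber"], md["denominator_wavenumber"],
                class_pdfs={c: Pdf.from_dict(p) for c, p in md["class_pdfs"].items()},
                auc=md["auc"], rank=md["rank"],
            )
        return DiscriminatorModel(
            classes=list(d["classes"]),
            committee={c: [metric_obj(md) for md in mets]
                       for c, mets in d["committee"].items()},
            k=d["k"], prior=dict(d["prior"]), combination=d["combination"],
            eps=d["eps"], metadata=dict(d["metadata"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @staticmethod
    def load(path) -> "DiscriminatorModel":
        with open(path) as fh:
            return DiscriminatorModel.from_dict(json.load(fh))


def build_model(ranked: dict, k: int = 5, prior: dict = None,
                combination: str = "mean", eps: float = DEFAULT_EPS,
                metadata: dict = None) -> DiscriminatorModel:
    """Assemble the top-k ranked metrics per class into a committee model.

    ``ranked`` is the output of :func:`spectra_metrics.metrics.rank_metrics`.
    Raises (naming the class) when a class has fewer than k ranked metrics.
    """
    classes = sorted(ranked)
    committee = {}
    for c in classes:
        if len(ranked[c]) < k:
            raise ValueError(
                f"class {c!r} has only {len(ranked[c])} ranked metrics, need k={k}"
            )
        committee[c] = list(ranked[c][:k])
    return DiscriminatorModel(
        classes=classes, committee=committee, k=k, prior=prior,
        combination=combination, eps=eps, metadata=metadata or {},
    )


def predict_matrix(model: DiscriminatorModel, values: np.ndarray,
                   wavenumbers: np.ndarray) -> tuple:
    """Vectorised committee voting over an (n, channels) spectra matrix.

    Returns ``(probabilities (n, n_classes), n_votes (n,))`` in model class
    order; rows with ``n_votes == 0`` (all metrics abstained) carry NaN.
    """
    classes = model.classes
    mets = model.distinct_metrics()
    n = values.shape[0]
    post_sum = np.zeros((n, len(classes)))
    votes = np.zeros(n)
    prior = np.array([model.prior[c] for c in classes])
    for m in mets:
        i = nearest_channel(wavenumbers, m.numerator_wavenumber)
        j = nearest_channel(wavenumbers, m.denominator_wavenumber)
        den = values[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = values[:, i] / den
        defined = np.abs(den) >= model.eps
        lik = np.empty((n, len(classes)))
        for ci, c in enumerate(classes):
            lik[:, ci] = m.class_pdfs[c].evaluate(r)
        if model.combination == "loglik":
            contrib = np.log(lik) + np.log(prior)[None, :]
        else:
            weighted = lik * prior[None, :]
            contrib = weighted / weighted.sum(axis=1, keepdims=True)
        post_sum[defined] += contrib[defined]
        votes += defined
    probs = np.full((n, len(classes)), np.nan)
    ok = votes > 0
    if model.combination == "loglik":
        logp = post_sum[ok]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
    else:
        p = post_sum[ok]
    probs[ok] = p / p.sum(axis=1, keepdims=True)
    return probs, votes


def committee_probabilities(model: DiscriminatorModel, spectrum: Spectrum) -> dict:
    """Per-class probabilities for one spectrum (sums to 1).

    Raises :class:`UnclassifiableSpectrumError` if every metric abstains.
    """
    probs, votes = predict_matrix(model, spectrum.values[None, :], spectrum.wavenumbers)
    if votes[0] == 0:
        raise UnclassifiableSpectrumError(
            "all committee metrics abstained (undefined ratios)"
        )
    return {c: float(p) for c, p in zip(model.classes, probs[0])}


def predict(model: DiscriminatorModel, spectrum: Spectrum) -> Prediction:
    """Label one spectrum: argmax class and confidence = max / sum."""
    probs = committee_probabilities(model, spectrum)
    vec = np.array([probs[c] for c in model.classes])
    best = int(np.argmax(vec))  # first index on ties = model class order
    return Prediction(
        class_probabilities=probs,
        predicted=model.classes[best],
        confidence=float(vec[best] / vec.sum()),
    )


def predict_cube(model: DiscriminatorModel, cube: SpectralCube) -> LabelMap:
    """Per-pixel prediction over a preprocessed cube.

    Masked pixels — and pixels on which every metric abstains — are labelled
    :data:`~spectra_metrics.labelmap.EXCLUDED_LABEL` with confidence 0.
    """
    grid = model.metadata.get("wavenumbers")
    if grid is not None and not np.allclose(grid, cube.wavenumbers):
        raise ValueError("cube wavenumber grid does not match the model's grid")
    rows, cols, _ = cube.shape
    labels = np.full((rows, cols), EXCLUDED_LABEL, dtype=object)
    conf = np.zeros((rows, cols))
    live = cube.pixel_mask
    if live.any():
        vals = cube.absorbance[live]
        probs, votes = predict_matrix(model, vals, cube.wavenumbers)
        ok = votes > 0
        best = np.full(vals.shape[0], -1)
        best[ok] = np.argmax(probs[ok], axis=1)
        lab_flat = np.array(
            [model.classes[b] if b >= 0 else EXCLUDED_LABEL for b in best],
            dtype=object,
        )
        conf_flat = np.zeros(vals.shape[0])
        conf_flat[ok] = probs[ok][np.arange(ok.sum()), best[ok]]
        labels[live] = lab_flat
        conf[live] = conf_flat
    return LabelMap(labels, conf)
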