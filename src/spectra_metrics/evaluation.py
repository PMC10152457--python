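"""Training/testing protocol: balanced sampling, stratified five-fold
cross-validation, and per-class sensitivity/specificity reporting.

The protocol mirrors how multi-class discriminatory models are trained on
annotated FTIR tissue images:

* an equal number of spectra is sampled from every image, so no single
  image dominates the model (image-related bias);
* data from all patients is pooled and randomised so patients are equally
  represented in every stage — folds are stratified on class × patient
  cells, each fold receiving within ±1 spectrum of its proportional share
  of every cell;
* five-fold cross-validation with a three-stage split: inside each
  training fold, spectra are divided 50/50 (class-stratified) into a
  *metric-training* subset (PDF fitting) and a *metric-scoring* subset
  (AUC ranking); the held-out fold is touched only by the final committee
  model.

Sensitivity and specificity are one-vs-rest percentages per class; the
report carries their mean ± standard deviation across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import build_model, predict_matrix
from .dataset import LabelledSpectra
from .metrics import (DEFAULT_EPS, Metric, _tie_break_order, fit_pdf,
                      pair_aucs)
from .labelmap import EXCLUDED_LABEL

__all__ = [
    "CvParams",
    "CvReport",
    "sample_balanced",
    "five_fold_split",
    "sensitivity_specificity",
    "cross_validate",
    "permutation_null",
]


@dataclass(frozen=True)
class CvParams:
    """Cross-validation pipeline parameters."""

    k: int = 5                     # committee size per class
    n_folds: int = 5
    inner_train_frac: float = 0.5  # metric-training share of each training fold
    estimator: str = "kernel"      # PDF estimator
    combination: str = "mean"      # committee vote combination
    eps: float = DEFAULT_EPS


@dataclass
class CvReport:
    """Per-class performance summary across folds."""

    per_class: dict                # class → dict of summary statistics
    folds: list                    # per-fold confusion DataFrames (true × predicted)
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, d in self.per_class.items():
            rows.append({
                "tissue": c,
                "n_spectra": d["n_spectra"],
                "n_images": d["n_images"],
                "sensitivity_pct": d["sensitivity_mean"],
                "sensitivity_sd_pct": d["sensitivity_sd"],
                "specificity_pct": d["specificity_mean"],
                "specificity_sd_pct": d["specificity_sd"],
            })
        return pd.DataFrame(rows)

    def to_json(self, path=None):
        payload = {
            "seed": self.seed,
            "per_class": self.per_class,
            "folds": [
                {"index": i,
                 "true_classes": cm.index.tolist(),
                 "predicted_classes": cm.columns.tolist(),
                 "counts": cm.values.tolist()}
                for i, cm in enumerate(self.folds)
            ],
        }
        if path is None:
            return json.dumps(payload, indent=2, sort_keys=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_balanced(data: LabelledSpectra, n_per_image: int, seed: int) -> LabelledSpectra:
    """Sample exactly ``n_per_image`` spectra from each image, without
    replacement, reproducibly."""
    rng = np.random.default_rng(seed)
    keep = []
    for img in np.unique(data.image_ids):
        idx = np.nonzero(data.image_ids == img)[0]
        if idx.size < n_per_image:
            raise ValueError(
                f"image {img!r} has only {idx.size} spectra, need {n_per_image}"
            )
        keep.append(rng.choice(idx, size=n_per_image, replace=False))
    return data.subset(np.sort(np.concatenate(keep)))


def five_fold_split(data: LabelledSpectra, seed: int, n_folds: int = 5) -> list:
    """Class- and patient-stratified fold partition.

    Within every class × patient cell, shuffled indices are dealt
    round-robin to folds (with a rotating starting fold so remainders
    spread evenly), which puts each fold within ±1 spectrum of its
    proportional share of every cell.  Returns ``[(train_idx, test_idx)]``
    with every spectrum in exactly one test fold.
    """
    rng = np.random.default_rng(seed)
    classes = data.classes
    for c in classes:
        if int((data.labels == c).sum()) < n_folds:
            raise ValueError(f"class {c!r} has fewer than {n_folds} spectra")
    fold_members = [[] for _ in range(n_folds)]
    offset = 0
    for c in classes:
        for p in np.unique(data.patient_ids[data.labels == c]):
            cell = np.nonzero((data.labels == c) & (data.patient_ids == p))[0]
            cell = rng.permutation(cell)
            for pos, idx in enumerate(cell):
                fold_members[(offset + pos) % n_folds].append(idx)
            offset = (offset + cell.size) % n_folds
    all_idx = np.arange(len(data))
    out = []
    for f in range(n_folds):
        test = np.sort(np.array(fold_members[f], dtype=int))
        train = np.setdiff1d(all_idx, test)
        out.append((train, test))
    return out


def sensitivity_specificity(confusion: pd.DataFrame) -> dict:
    """One-vs-rest sensitivity/specificity (%) from a multi-class confusion
    matrix (rows = true class, columns = predicted class).

    Predicted columns absent from the true-class index (e.g. an "excluded"
    outcome) count against both sensitivity and specificity as
    misclassifications of their true class.
    """
    total = confusion.values.sum()
    out = {}
    for c in confusion.index:
        tp = float(confusion.loc[c, c]) if c in confusion.columns else 0.0
        row = float(confusion.loc[c].sum())
        col = float(confusion[c].sum()) if c in confusion.columns else 0.0
        fn = row - tp
        fp = col - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            raise ValueError(f"class {c!r} has no positive test spectra")
        if tn + fp == 0:
            raise ValueError(f"class {c!r} has no negative test spectra")
        out[c] = (100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp))
    return out


def _stratified_halves(labels: np.ndarray, idx: np.ndarray, frac: float,
                       rng: np.random.Generator) -> tuple:
    """Class-stratified split of ``idx`` into (first, second) parts."""
    first, second = [], []
    for c in np.unique(labels[idx]):
        cell = rng.permutation(idx[labels[idx] == c])
        n_first = max(1, int(round(frac * cell.size)))
        n_first = min(n_first, cell.size - 1)
        first.append(cell[:n_first])
        second.append(cell[n_first:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


def _ordered_pairs(channel_idx: np.ndarray) -> np.ndarray:
    """(m, 2) array of all ordered index pairs, i ≠ j."""
    a, b = np.meshgrid(channel_idx, channel_idx, indexing="ij")
    keep = a != b
    return np.column_stack([a[keep], b[keep]])


def _fit_fold_model(train: LabelledSpectra, params: CvParams,
                    rng: np.random.Generator) -> "DiscriminatorModel":
    """Rank all pairs on the scoring subset, fit committee PDFs on the
    training subset, assemble the model."""
    classes = train.classes
    fit_idx, score_idx = _stratified_halves(
        train.labels, np.arange(len(train)), params.inner_train_frac, rng)
    ch_idx = np.nonzero(train.channel_mask)[0]
    pairs = _ordered_pairs(ch_idx)
    aucs = pair_aucs(train.subset(score_idx), pairs, classes=classes, eps=params.eps)
    wn = train.wavenumbers
    pairs_wn = np.column_stack([wn[pairs[:, 0]], wn[pairs[:, 1]]])

    fit_sub = train.subset(fit_idx)
    class_rows = {c: np.nonzero(fit_sub.labels == c)[0] for c in classes}
    pdf_cache = {}

    def metric_for(pair_row: int, auc_val: float) -> Metric:
        i, j = pairs[pair_row]
        if (i, j) not in pdf_cache:
            with np.errstate(divide="ignore", invalid="ignore"):
                r = fit_sub.values[:, i] / fit_sub.values[:, j]
            r[np.abs(fit_sub.values[:, j]) < params.eps] = np.nan
            pdfs = {}
            for c in classes:
                rc = r[class_rows[c]]
                rc = rc[np.isfinite(rc)]
                pdfs[c] = fit_pdf(rc, params.estimator) if rc.size else None
            pdf_cache[(i, j)] = pdfs
        return Metric(float(wn[i]), float(wn[j]),
                      class_pdfs=pdf_cache[(i, j)], auc=float(auc_val))

    ranked = {}
    for c in classes:
        raw = aucs[c]
        oriented = np.maximum(raw, 1.0 - raw)
        usable = np.isfinite(oriented)
        order = _tie_break_order(oriented[usable], pairs_wn[usable])
        usable_rows = np.nonzero(usable)[0][order]
        top = []
        for row in usable_rows:
            m = metric_for(row, oriented[row])
            if m.has_empty_pdf():
                continue
            m.rank = len(top) + 1
            top.append(m)
            if len(top) >= params.k:
                break
        ranked[c] = top
    return build_model(ranked, k=params.k, combination=params.combination,
                       eps=params.eps)


def cross_validate(data: LabelledSpectra, params: CvParams = CvParams(),
                   seed: int = 0) -> CvReport:
    """Five-fold cross-validated committee classification of labelled spectra.

    For each fold the metric engine is fitted and ranked entirely inside the
    training portion; the held-out fold is labelled by the final model.
    Deterministic for identical (data, params, seed).
    """
    folds = five_fold_split(data, seed=seed, n_folds=params.n_folds)
    classes = data.classes
    fold_stats = {c: {"sens": [], "spec": []} for c in classes}
    confusions = []
    for f, (train_idx, test_idx) in enumerate(folds):
        rng = np.random.default_rng([seed, f])
        model = _fit_fold_model(data.subset(train_idx), params, rng)
        test = data.subset(test_idx)
        probs, votes = predict_matrix(model, test.values, test.wavenumbers)
        pred = np.full(len(test), EXCLUDED_LABEL, dtype=object)
        ok = votes > 0
        pred[ok] = np.asarray(model.classes, dtype=object)[np.argmax(probs[ok], axis=1)]
        pred_classes = classes + ([EXCLUDED_LABEL] if (~ok).any() else [])
        cm = pd.DataFrame(0, index=classes, columns=pred_classes, dtype=int)
        for t, p in zip(test.labels, pred):
            cm.loc[t, p] += 1
        confusions.append(cm)
        for c, (sens, spec) in sensitivity_specificity(cm).items():
            fold_stats[c]["sens"].append(sens)
            fold_stats[c]["spec"].append(spec)
    per_class = {}
    for c in classes:
        sens = np.array(fold_stats[c]["sens"])
        spec = np.array(fold_stats[c]["spec"])
        sel = data.labels == c
        per_class[c] = {
            "sensitivity_mean": float(sens.mean()),
            "sensitivity_sd": float(sens.std(ddof=1)),
            "specificity_mean": float(spec.mean()),
            "specificity_sd": float(spec.std(ddof=1)),
            "n_spectra": int(sel.sum()),
            "n_images": int(np.unique(data.image_ids[sel]).size),
        }
    return CvReport(per_class=per_class, folds=confusions, seed=seed)


def permutation_null(data: LabelledSpectra, params: CvParams = CvParams(),
                     seeds=range(10)) -> list:
    """Label-permutation null: shuffle labels, rerun the full CV.

    Returns the across-class mean sensitivity (%) per seed.  Guards against
    leakage between the metric-training, scoring and evaluation stages: with
    exchangeable labels, sensitivity must collapse to 100/n_classes %.
    """
    out = []
    for s in seeds:
        rng = np.random.default_rng([int(s), 0xA5])
        shuffled = LabelledSpectra(
            values=data.values, wavenumbers=data.wavenumbers,
            labels=rng.permutation(data.labels),
            image_ids=data.image_ids, patient_ids=data.patient_ids,
            channel_mask=data.channel_mask,
        )
        report = cross_validate(shuffled, params, seed=int(s))
        sens = [d["sensitivity_mean"] for d in report.per_class.values()]
        out.append(float(np.mean(sens)))
    return out
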