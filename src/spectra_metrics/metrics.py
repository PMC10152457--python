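"""Absorbance-ratio metrics: generation, PDF fitting, AUC scoring, ranking.

A *metric* is an ordered pair of wavenumbers (ν_num, ν_den).  Applied to a
spectrum it yields the scalar ratio A(ν_num)/A(ν_den); applied to a labelled
training set it yields one probability density function (PDF) of that ratio
per tissue class.  Metrics are generated for every ordered pair of analysis
channels, scored on held-out spectra by the area under the ROC curve (AUC)
of the one-vs-rest separation of their ratio values, and ranked per class.

AUC is computed with the Mann–Whitney convention (ties count ½) through the
rank-sum identity, and is *oriented* for ranking — ``max(a, 1 − a)`` — since
a PDF-based classifier is direction-free: a metric whose ratio is
consistently low for the positive class separates exactly as well as its
reciprocal.  Both orderings of a pair are kept as distinct metrics.

Ratios with a near-zero denominator (|A(ν_den)| < eps) are *undefined*: the
spectrum is excluded from that metric's PDF and scoring rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .cube import Spectrum, nearest_channel
from .dataset import LabelledSpectra

__all__ = [
    "Pdf",
    "KernelDensityPdf",
    "HistogramPdf",
    "fit_pdf",
    "Metric",
    "ratio_value",
    "ratio_matrix",
    "wavenumber_pairs",
    "generate_metrics",
    "score_metric_auc",
    "oriented_auc",
    "pair_aucs",
    "rank_metrics",
    "importance_histogram",
    "DEFAULT_EPS",
]

#: Denominator guard on the vector-normalised absorbance scale.
DEFAULT_EPS = 1e-6

_DENSITY_FLOOR = 1e-12
_GRID_POINTS = 512


class Pdf:
    """Base interface: a non-negative density on a finite support interval."""

    kind: str = "base"
    n_train: int = 0
    support: tuple = (0.0, 0.0)

    def evaluate(self, x):
        raise NotImplementedError

    def integral(self) -> float:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "Pdf":
        if d["kind"] == "kernel":
            return KernelDensityPdf(
                grid=np.asarray(d["grid"]), density=np.asarray(d["density"]),
                bandwidth=d["bandwidth"], n_train=d["n_train"],
            )
        if d["kind"] == "histogram":
            return HistogramPdf(
                edges=np.asarray(d["edges"]), density=np.asarray(d["density"]),
                n_train=d["n_train"],
            )
        raise ValueError(f"unknown Pdf kind {d['kind']!r}")


class KernelDensityPdf(Pdf):
    """Gaussian KDE evaluated on a fixed grid, renormalised to unit mass.

    Bandwidth follows Silverman's rule on the robust spread
    ``min(sd, IQR/1.34)``; when the training ratios are (nearly) degenerate
    the bandwidth falls back to a small fraction of the ratio magnitude so
    the density concentrates tightly around the common value.  Evaluation
    interpolates linearly on the grid with a floor of 1e-12 to avoid zero
    likelihoods in committee voting.
    """

    kind = "kernel"

    def __init__(self, train=None, *, grid=None, density=None, bandwidth=None, n_train=None):
        if train is not None:
            x = np.asarray(train, dtype=float)
            if x.size == 0:
                raise ValueError("cannot fit a PDF to zero training ratios")
            n = x.size
            sd = float(np.std(x))
            iqr = float(np.subtract(*np.percentile(x, [75, 25])))
            spread = min(sd, iqr / 1.34) if iqr > 0 else sd
            h = 0.9 * spread * n ** (-1 / 5)
            if h <= 0 or not math.isfinite(h):
                # degenerate (spread-free) ratios: bandwidth proportional to
                # the ratio magnitude, so the density resolves differences
                # at the scale the data actually lives on
                scale = float(np.max(np.abs(x)))
                h = 1e-3 * scale if scale > 0 else 1e-3
            # support spans the central 99.9% of training ratios, padded by 3h
            lo, hi = np.percentile(x, [0.05, 99.95])
            grid = np.linspace(lo - 3 * h, hi + 3 * h, _GRID_POINTS)
            z = (grid[:, None] - x[None, :]) / h
            density = np.exp(-0.5 * z * z).mean(axis=1) / (h * math.sqrt(2 * math.pi))
            density /= np.trapezoid(density, grid)
            bandwidth, n_train = h, n
        self.grid = np.asarray(grid, dtype=float)
        self.density = np.asarray(density, dtype=float)
        self.bandwidth = float(bandwidth)
        self.n_train = int(n_train)
        self.support = (float(self.grid[0]), float(self.grid[-1]))

    def evaluate(self, x):
        d = np.interp(x, self.grid, self.density, left=_DENSITY_FLOOR, right=_DENSITY_FLOOR)
        return np.maximum(d, _DENSITY_FLOOR)

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "grid": self.grid.tolist(),
            "density": self.density.tolist(), "bandwidth": self.bandwidth,
            "n_train": self.n_train,
        }


class HistogramPdf(Pdf):
    """Histogram density (Freedman–Diaconis bins), floor-protected."""

    kind = "histogram"

    def __init__(self, train=None, *, edges=None, density=None, n_train=None):
        if train is not None:
            x = np.asarray(train, dtype=float)
            if x.size == 0:
                raise ValueError("cannot fit a PDF to zero training ratios")
            if np.ptp(x) == 0:
                w = 1e-3 * max(1.0, abs(float(x[0])))
                edges = np.array([x[0] - w, x[0] + w])
            else:
                edges = np.histogram_bin_edges(x, bins="fd")
                if edges.size < 2:
                    edges = np.histogram_bin_edges(x, bins=10)
            density, edges = np.histogram(x, bins=edges, density=True)
            n_train = x.size
        self.edges = np.asarray(edges, dtype=float)
        self.density = np.asarray(density, dtype=float)
        self.n_train = int(n_train)
        self.support = (float(self.edges[0]), float(self.edges[-1]))

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, x, side="right") - 1, 0, self.density.size - 1)
        d = self.density[idx]
        outside = (x < self.edges[0]) | (x > self.edges[-1])
        d = np.where(outside, _DENSITY_FLOOR, d)
        return np.maximum(d, _DENSITY_FLOOR)

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.edges)))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "edges": self.edges.tolist(),
            "density": self.density.tolist(), "n_train": self.n_train,
        }


def fit_pdf(train, estimator: str = "kernel") -> Pdf:
    if estimator == "kernel":
        return KernelDensityPdf(train)
    if estimator == "histogram":
        return HistogramPdf(train)
    raise ValueError(f"unknown PDF estimator {estimator!r}")


@dataclass
class Metric:
    """Ordered wavenumber pair with per-class ratio PDFs and an AUC score.

    ``class_pdfs`` maps class name → fitted :class:`Pdf`, or ``None`` when
    the class had no usable (defined) training ratios for the pair — such
    metrics are excluded from ranking.  ``auc`` holds the oriented AUC once
    the metric has been ranked.
    """

    numerator_wavenumber: float
    denominator_wavenumber: float
    class_pdfs: dict = field(default_factory=dict)
    auc: float = None
    rank: int = None

    def __post_init__(self) -> None:
        if self.numerator_wavenumber == self.denominator_wavenumber:
            raise ValueError("metric numerator and denominator wavenumbers must differ")
        if self.auc is not None and not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC {self.auc} outside [0, 1]")

    @property
    def pair(self) -> tuple:
        return (self.numerator_wavenumber, self.denominator_wavenumber)

    def has_empty_pdf(self) -> bool:
        return any(p is None for p in self.class_pdfs.values()) or not self.class_pdfs

    def __str__(self) -> str:
        return f"{self.numerator_wavenumber:g}/{self.denominator_wavenumber:g}"


def ratio_value(spectrum: Spectrum, num_wn: float, den_wn: float,
                eps: float = DEFAULT_EPS, channel_mask: np.ndarray = None) -> float:
    """Ratio A(ν_num)/A(ν_den) with nearest-channel lookup.

    Returns NaN (the undefined-ratio sentinel) when |A(ν_den)| < eps;
    callers must exclude such spectra from the metric's PDF and scoring.
    """
    i = nearest_channel(spectrum.wavenumbers, num_wn)
    j = nearest_channel(spectrum.wavenumbers, den_wn)
    if i == j:
        raise ValueError(
            f"wavenumbers {num_wn:g} and {den_wn:g} resolve to the same channel"
        )
    if channel_mask is not None and not (channel_mask[i] and channel_mask[j]):
        raise ValueError("metric wavenumbers must resolve to unmasked analysis channels")
    den = spectrum.values[j]
    if abs(den) < eps:
        return float("nan")
    return float(spectrum.values[i] / den)


def ratio_matrix(values: np.ndarray, pairs_idx: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """(n_spectra × n_pairs) ratio matrix; NaN marks undefined ratios."""
    num = values[:, pairs_idx[:, 0]]
    den = values[:, pairs_idx[:, 1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[np.abs(den) < eps] = np.nan
    return out


def wavenumber_pairs(wavenumbers) -> list:
    """All ordered pairs (ν_i, ν_j), i ≠ j — exactly n·(n−1) of them."""
    w = list(wavenumbers)
    return [(a, b) for a in w for b in w if a != b]


def _analysis_channels(data: LabelledSpectra, channels=None) -> np.ndarray:
    """Channel indices to analyse: explicit wavenumber list or the unmasked set."""
    if channels is None:
        return np.nonzero(data.channel_mask)[0]
    return np.array([nearest_channel(data.wavenumbers, c) for c in channels])


def generate_metrics(train: LabelledSpectra, channels=None,
                     estimator: str = "kernel", eps: float = DEFAULT_EPS) -> list:
    """Generate a metric for every ordered pair of analysis channels.

    Each metric carries one PDF per class, fitted to the class's defined
    training ratios.  For ``n`` channels the result has exactly ``n(n−1)``
    metrics.
    """
    classes = train.classes
    if len(classes) < 2:
        raise ValueError("metric generation needs at least 2 classes")
    ch_idx = _analysis_channels(train, channels)
    if ch_idx.size < 2:
        raise ValueError("metric generation needs at least 2 analysis channels")
    wn = train.wavenumbers
    class_rows = {c: np.nonzero(train.labels == c)[0] for c in classes}
    metrics = []
    for i in ch_idx:
        for j in ch_idx:
            if i == j:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                r = train.values[:, i] / train.values[:, j]
            r[np.abs(train.values[:, j]) < eps] = np.nan
            pdfs = {}
            for c in classes:
                rc = r[class_rows[c]]
                rc = rc[np.isfinite(rc)]
                pdfs[c] = fit_pdf(rc, estimator) if rc.size else None
            metrics.append(Metric(float(wn[i]), float(wn[j]), class_pdfs=pdfs))
    return metrics


def _auc_from_values(values: np.ndarray, positive: np.ndarray) -> float:
    """Mann–Whitney AUC (ties ½) via the rank-sum identity."""
    n_pos = int(positive.sum())
    n_neg = values.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative value")
    ranks = rankdata(values, method="average")
    r_pos = float(ranks[positive].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def score_metric_auc(metric: Metric, test: LabelledSpectra, positive_class: str,
                     eps: float = DEFAULT_EPS) -> float:
    """Raw one-vs-rest AUC of the metric's ratio values on held-out spectra.

    Spectra with undefined ratios are excluded.  The returned value is the
    raw (unoriented) AUC in [0, 1]; use :func:`oriented_auc` for ranking.
    """
    i = nearest_channel(test.wavenumbers, metric.numerator_wavenumber)
    j = nearest_channel(test.wavenumbers, metric.denominator_wavenumber)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = test.values[:, i] / test.values[:, j]
    r[np.abs(test.values[:, j]) < eps] = np.nan
    ok = np.isfinite(r)
    positive = (test.labels == positive_class)[ok]
    return _auc_from_values(r[ok], positive)


def oriented_auc(auc: float) -> float:
    """Direction-free AUC: a perfectly anti-ordered metric is equally useful."""
    return max(auc, 1.0 - auc)


def _average_ranks(a: np.ndarray) -> np.ndarray:
    """Column-wise 1-based average ranks (ties share their mean rank).

    Vectorised equivalent of ``scipy.stats.rankdata(a, "average", axis=0)``,
    which is too slow for tens of thousands of columns.
    """
    # work on the transpose so sorts and scans run along contiguous memory
    at = np.ascontiguousarray(a.T)
    m, n = at.shape
    order = np.argsort(at, axis=1, kind="stable")
    sorted_a = np.take_along_axis(at, order, axis=1)
    avg_sorted = _sorted_average_ranks(sorted_a)
    ranks = np.empty((m, n))
    np.put_along_axis(ranks, order, avg_sorted, axis=1)
    return ranks.T


def _sorted_average_ranks(sorted_a: np.ndarray) -> np.ndarray:
    """Average (tie-shared) 1-based ranks of row-wise sorted values."""
    m, n = sorted_a.shape
    ar = np.arange(n)[None, :]
    is_first = np.ones((m, n), dtype=bool)
    is_first[:, 1:] = sorted_a[:, 1:] != sorted_a[:, :-1]
    is_last = np.ones((m, n), dtype=bool)
    is_last[:, :-1] = is_first[:, 1:]
    idx_first = np.maximum.accumulate(np.where(is_first, ar, 0), axis=1)
    idx_last = np.flip(np.minimum.accumulate(
        np.flip(np.where(is_last, ar, n), axis=1), axis=1), axis=1)
    return (idx_first + idx_last) / 2.0 + 1.0


def _class_rank_sums(values: np.ndarray, codes: np.ndarray, n_classes: int,
                     valid: np.ndarray = None) -> np.ndarray:
    """Per-class sums of average ranks over *valid* rows, column-wise.

    ``values`` is (n_rows, m_cols); ``codes`` assigns each row its class
    index.  Invalid entries (``valid`` False) must hold +inf so they sort
    past every finite value: the ranks of valid values are then identical
    to their ranks with the invalid rows excluded, and the returned
    (n_classes, m_cols) sums accumulate valid rows only, under the
    Mann–Whitney average-rank (ties ½) convention.  Ranks are summed in
    sorted order, so no scatter back to the original row order is needed —
    the dominant cost is one sort per column.
    """
    at = np.ascontiguousarray(values.T)
    m, n = at.shape
    order = np.argsort(at, axis=1, kind="stable")
    sorted_a = np.take_along_axis(at, order, axis=1)
    base = np.arange(1, n + 1, dtype=float)
    codes_sorted = codes[order]
    if valid is not None:
        valid_sorted = np.take_along_axis(
            np.ascontiguousarray(valid.T), order, axis=1)
        codes_sorted = np.where(valid_sorted, codes_sorted, -1)
    # ties among +inf (invalid) entries are irrelevant: they are never summed
    ties = (sorted_a[:, 1:] == sorted_a[:, :-1]) & np.isfinite(sorted_a[:, 1:])
    tie_rows = np.nonzero(ties.any(axis=1))[0]
    out = np.empty((n_classes, m))
    for ci in range(n_classes):
        out[ci] = (codes_sorted == ci) @ base
    if tie_rows.size:
        avg = _sorted_average_ranks(sorted_a[tie_rows])
        for ci in range(n_classes):
            out[ci, tie_rows] = ((codes_sorted[tie_rows] == ci) * avg).sum(axis=1)
    return out


def pair_aucs(test: LabelledSpectra, pairs_idx: np.ndarray, classes=None,
              eps: float = DEFAULT_EPS) -> dict:
    """Raw one-vs-rest AUC for every wavenumber pair, per class, vectorised.

    Returns class name → array of raw AUCs aligned with ``pairs_idx``; NaN
    where a pair has no defined positives or negatives for that class.
    Equivalent to calling :func:`score_metric_auc` per pair (tested).
    """
    if classes is None:
        classes = test.classes
    r = ratio_matrix(test.values, pairs_idx, eps)
    n, m = r.shape
    finite = np.isfinite(r)
    # undefined ratios sort past every finite value as +inf; the valid
    # mask keeps them out of the rank sums, which is exactly per-column
    # exclusion of undefined-ratio spectra
    np.copyto(r, np.inf, where=~finite)
    codes = np.full(n, -1)
    pos_masks = {c: test.labels == c for c in classes}
    for ci, c in enumerate(classes):
        codes[pos_masks[c]] = ci
    rank_sums = _class_rank_sums(r, codes, len(classes), valid=finite)
    n_def = finite.sum(axis=0)
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for ci, c in enumerate(classes):
            n_pos = pos_masks[c].astype(float) @ finite
            n_neg = n_def - n_pos
            auc = (rank_sums[ci] - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
            auc[(n_pos == 0) | (n_neg == 0)] = np.nan
            out[c] = auc
    return out


def _tie_break_order(aucs: np.ndarray, pairs_wn: np.ndarray) -> np.ndarray:
    """Sort by oriented AUC descending; ties by (numerator, denominator) asc."""
    return np.lexsort((pairs_wn[:, 1], pairs_wn[:, 0], -aucs))


def rank_metrics(metrics: list, test: LabelledSpectra, per_class: bool = True,
                 eps: float = DEFAULT_EPS) -> dict:
    """Rank metrics per class by oriented AUC on held-out spectra.

    Metrics with an empty class PDF or with no scorable ratios are excluded.
    Returns class name → list of ranked metric copies with ``auc`` set to
    the oriented value and ``rank`` set 1..N.
    """
    classes = test.classes
    pairs_wn = np.array([m.pair for m in metrics])
    ranked = {}
    for c in classes:
        scores = np.full(len(metrics), np.nan)
        for idx, m in enumerate(metrics):
            if m.has_empty_pdf():
                continue
            try:
                scores[idx] = oriented_auc(score_metric_auc(m, test, c, eps))
            except ValueError:
                continue
        usable = np.isfinite(scores)
        order = _tie_break_order(scores[usable], pairs_wn[usable])
        usable_idx = np.nonzero(usable)[0][order]
        ranked[c] = [
            replace(metrics[i], class_pdfs=metrics[i].class_pdfs,
                    auc=float(scores[i]), rank=pos + 1)
            for pos, i in enumerate(usable_idx)
        ]
    return ranked


def importance_histogram(top_metrics: dict) -> dict:
    """Wavenumber occurrence counts over each class's five best metrics.

    For each class, counts how often every wavenumber appears among the
    numerators and denominators of its top five metrics; the counts sum to
    10 per class.
    """
    out = {}
    for c, metrics in top_metrics.items():
        if len(metrics) != 5:
            raise ValueError(f"importance histogram needs exactly 5 metrics per class, "
                             f"got {len(metrics)} for {c!r}")
        counts = {}
        for m in metrics:
            for wn in m.pair:
                counts[wn] = counts.get(wn, 0) + 1
        out[c] = counts
    return out
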