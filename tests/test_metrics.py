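"""Metric engine: ratio guards, PDF normalisation, Mann–Whitney AUC against
exhaustive pair counting, ranking determinism, importance histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectra_metrics.cube import Spectrum
from spectra_metrics.dataset import LabelledSpectra
from spectra_metrics.metrics import (DEFAULT_EPS, HistogramPdf,
                                     KernelDensityPdf, Metric, fit_pdf,
                                     generate_metrics, importance_histogram,
                                     oriented_auc, pair_aucs, rank_metrics,
                                     ratio_value, score_metric_auc,
                                     wavenumber_pairs, _average_ranks)


def pair_counting_auc(pos, neg):
    """Independent oracle: exhaustive Mann–Whitney pair counting, ties ½."""
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def labelled(values_by_class, wn=None):
    labels, rows = [], []
    for c, vals in values_by_class.items():
        for v in vals:
            labels.append(c)
            rows.append(v)
    rows = np.asarray(rows, dtype=float)
    if wn is None:
        wn = np.arange(1000.0, 1000.0 + 4.0 * rows.shape[1], 4.0)
    return LabelledSpectra(rows, wn, np.array(labels))


class TestRatioValue:
    def test_arithmetic(self):
        s = Spectrum([0.5, 0.25], [1000.0, 1004.0])
        assert ratio_value(s, 1000.0, 1004.0) == pytest.approx(2.0)

    def test_same_channel_rejected(self):
        s = Spectrum([0.5, 0.25], [1000.0, 1004.0])
        with pytest.raises(ValueError, match="same channel"):
            ratio_value(s, 1000.0, 1001.0)

    def test_tiny_denominator_is_undefined(self):
        s = Spectrum([0.5, 1e-15], [1000.0, 1004.0])
        assert np.isnan(ratio_value(s, 1000.0, 1004.0, eps=1e-6))


class TestPdfs:
    @pytest.mark.parametrize("estimator", ["kernel", "histogram"])
    def test_integrates_to_one(self, estimator, rng):
        for _ in range(5):
            x = rng.normal(1.5, 0.3, size=rng.integers(5, 200))
            pdf = fit_pdf(x, estimator)
            assert pdf.integral() == pytest.approx(1.0, abs=1e-3)
            grid = np.linspace(pdf.support[0] - 1, pdf.support[1] + 1, 400)
            assert (pdf.evaluate(grid) >= 0).all()

    def test_degenerate_ratios_concentrate(self):
        pdf = KernelDensityPdf(np.full(40, 2.5))
        xs = np.linspace(2.5 - 4 * pdf.bandwidth, 2.5 + 4 * pdf.bandwidth, 2001)
        mass = np.trapezoid(pdf.evaluate(xs), xs)
        assert mass >= 0.99
        assert pdf.support[0] <= 2.5 <= pdf.support[1]

    def test_round_trip_serialisation(self, rng):
        for estimator in ("kernel", "histogram"):
            pdf = fit_pdf(rng.normal(size=50), estimator)
            clone = type(pdf).from_dict(pdf.to_dict())
            xs = np.linspace(-3, 3, 101)
            assert np.array_equal(pdf.evaluate(xs), clone.evaluate(xs))


class TestGenerateMetrics:
    def test_three_channels_give_six_metrics(self):
        data = labelled({"A": [[0.1, 0.2, 0.3]] * 4, "B": [[0.3, 0.2, 0.1]] * 4})
        mets = generate_metrics(data)
        assert len(mets) == 6
        for m in mets:
            assert set(m.class_pdfs) == {"A", "B"}
            assert not m.has_empty_pdf()

    def test_pair_count_law(self):
        for n in (2, 5, 9):
            wns = np.arange(1000.0, 1000.0 + 4 * n, 4.0)
            assert len(wavenumber_pairs(wns)) == n * (n - 1)

    def test_undefined_ratio_class_flagged_empty(self):
        # class B's denominator channel is ~0 for every spectrum
        data = labelled({"A": [[0.2, 0.4]] * 3, "B": [[0.2, 1e-12]] * 3})
        mets = generate_metrics(data)
        m = next(m for m in mets
                 if m.denominator_wavenumber == 1004.0)
        assert m.class_pdfs["B"] is None and m.has_empty_pdf()


class TestAuc:
    def test_perfect_separation(self):
        data = labelled({"P": [[0.5, 1.0], [0.6, 1.0]],
                         "N": [[0.2, 1.0], [0.3, 1.0]]})
        m = Metric(1000.0, 1004.0)
        assert score_metric_auc(m, data, "P") == pytest.approx(1.0)

    def test_interleaved_quarter(self):
        data = labelled({"P": [[0.1, 1.0], [0.5, 1.0]],
                         "N": [[0.3, 1.0], [0.7, 1.0]]})
        m = Metric(1000.0, 1004.0)
        raw = score_metric_auc(m, data, "P")
        assert raw == pytest.approx(0.25)
        assert oriented_auc(raw) == pytest.approx(0.75)

    def test_single_tied_pair_is_half(self):
        data = labelled({"P": [[0.4, 1.0]], "N": [[0.4, 1.0]]})
        assert score_metric_auc(Metric(1000.0, 1004.0), data, "P") == pytest.approx(0.5)

    def test_no_negatives_raises(self):
        data = labelled({"P": [[0.4, 1.0]]})
        with pytest.raises(ValueError):
            score_metric_auc(Metric(1000.0, 1004.0), data, "P")

    def test_matches_pair_counting_oracle(self, rng):
        """Rank-sum AUC equals exhaustive pair counting (ties ½) exactly."""
        for _ in range(50):
            n_pos = int(rng.integers(1, 51))
            n_neg = int(rng.integers(1, 51))
            # coarse grid of values → plenty of ties
            pos = rng.integers(0, 12, n_pos) * 0.25
            neg = rng.integers(0, 12, n_neg) * 0.25
            vals = np.concatenate([pos, neg])
            data = labelled({"P": [[v, 1.0] for v in pos],
                             "N": [[v, 1.0] for v in neg]})
            got = score_metric_auc(Metric(1000.0, 1004.0), data, "P")
            assert got == pytest.approx(pair_counting_auc(pos, neg), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_orientation_symmetric_under_inversion(self, seed):
        """Oriented AUC of a/b equals oriented AUC of b/a on tie-free
        positive data (inversion reverses the ordering)."""
        r = np.random.default_rng(seed)
        pos = np.unique(r.uniform(0.1, 5.0, 12))
        neg = np.unique(r.uniform(0.1, 5.0, 12))
        both = np.concatenate([pos, neg])
        if np.unique(both).size < both.size:
            return  # cross-group tie: inversion no longer exactly reverses
        data = labelled({"P": [[v, 1.0] for v in pos],
                         "N": [[v, 1.0] for v in neg]})
        fwd = score_metric_auc(Metric(1000.0, 1004.0), data, "P")
        rev = score_metric_auc(Metric(1004.0, 1000.0), data, "P")
        assert oriented_auc(fwd) == pytest.approx(oriented_auc(rev), abs=1e-12)


class TestBatchAuc:
    def test_matches_scalar_path_with_ties_and_undefined(self, rng):
        n_ch, n = 10, 48
        vals = rng.integers(1, 6, size=(n, n_ch)).astype(float) * 0.1
        vals[rng.random((n, n_ch)) < 0.08] = 1e-9  # undefined denominators
        data = LabelledSpectra(
            vals, np.arange(1000.0, 1000.0 + 4 * n_ch, 4.0),
            rng.choice(["A", "B", "C"], size=n))
        pairs = np.array([(i, j) for i in range(n_ch)
                          for j in range(n_ch) if i != j])
        batch = pair_aucs(data, pairs)
        for k, (i, j) in enumerate(pairs):
            m = Metric(data.wavenumbers[i], data.wavenumbers[j])
            for c in ("A", "B", "C"):
                try:
                    ref = score_metric_auc(m, data, c)
                except ValueError:
                    ref = np.nan
                if np.isnan(ref):
                    assert np.isnan(batch[c][k])
                else:
                    assert batch[c][k] == pytest.approx(ref, abs=1e-12)

    def test_average_ranks_match_scipy(self, rng):
        from scipy.stats import rankdata
        a = rng.integers(0, 5, size=(40, 17)).astype(float)
        ref = np.column_stack([rankdata(a[:, j]) for j in range(a.shape[1])])
        assert np.allclose(_average_ranks(a), ref, atol=0)


class TestRanking:
    def test_sorting_and_tie_break(self):
        rng = np.random.default_rng(5)
        # channel 0 separates perfectly; channels 1 and 2 are identical noise
        a = np.column_stack([rng.uniform(2, 3, 10), np.ones(10), np.ones(10) * 2])
        b = np.column_stack([rng.uniform(0.5, 1, 10), np.ones(10), np.ones(10) * 2])
        data = labelled({"A": a.tolist(), "B": b.tolist()})
        mets = generate_metrics(data)
        ranked = rank_metrics(mets, data)
        assert [m.rank for m in ranked["A"]] == list(range(1, len(ranked["A"]) + 1))
        aucs = [m.auc for m in ranked["A"]]
        assert aucs == sorted(aucs, reverse=True)
        # metrics not involving channel 0 are pure ties at AUC 0.5:
        # deterministic (numerator, denominator) ascending order
        tail = [m.pair for m in ranked["A"] if m.auc == pytest.approx(0.5)]
        assert tail == sorted(tail)


class TestImportanceHistogram:
    def top5(self, pairs):
        return [Metric(float(a), float(b)) for a, b in pairs]

    def test_carcinoma_column(self):
        # five best metrics discriminating the carcinoma class
        top = {"OSCC": self.top5([(1562, 1539), (1539, 1562), (1566, 1539),
                                  (1539, 1566), (1562, 1543)])}
        assert importance_histogram(top)["OSCC"] == {
            1539: 4, 1562: 3, 1566: 2, 1543: 1}

    def test_lymphoid_column(self):
        top = {"LYM": self.top5([(1715, 1703), (1703, 1715), (1703, 1719),
                                 (1707, 1715), (1715, 1707)])}
        assert importance_histogram(top)["LYM"] == {
            1715: 4, 1703: 3, 1707: 2, 1719: 1}

    def test_degenerate_repeats_and_count_sum(self):
        top = {"X": self.top5([(1000, 1004)] * 5)}
        counts = importance_histogram(top)["X"]
        assert counts == {1000: 5, 1004: 5}
        assert sum(counts.values()) == 10

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError, match="5 metrics"):
            importance_histogram({"X": self.top5([(1000, 1004)] * 4)})
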