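"""Evaluation protocol: balanced sampling, stratified folds, one-vs-rest
statistics, separable-phantom recovery, determinism, noise monotonicity."""

import numpy as np
import pandas as pd
import pytest

from spectra_metrics.dataset import LabelledSpectra
from spectra_metrics.evaluation import (CvParams, cross_validate,
                                        five_fold_split, sample_balanced,
                                        sensitivity_specificity)
from spectra_metrics.phantom import PhantomSpec, TissueProfile
from spectra_metrics.workflows import make_phantom_dataset

# reduced phantom conditions for protocol tests: coarser grid, small images
FAST_GRID = (900.0, 1800.0, 16.0)


def toy_data(n=120, n_ch=4, classes=("A", "B"), rng_seed=0,
             images=(0, 1, 2), patients=(0,)):
    rng = np.random.default_rng(rng_seed)
    return LabelledSpectra(
        values=rng.random((n, n_ch)) + 0.1,
        wavenumbers=np.arange(1000.0, 1000.0 + 4 * n_ch, 4.0),
        labels=rng.choice(classes, size=n).astype(object),
        image_ids=rng.choice(images, size=n),
        patient_ids=rng.choice(patients, size=n),
    )


class TestSampleBalanced:
    def test_counts_and_determinism(self):
        data = toy_data(300)
        out1 = sample_balanced(data, 30, seed=4)
        out2 = sample_balanced(data, 30, seed=4)
        for img in np.unique(out1.image_ids):
            assert int((out1.image_ids == img).sum()) == 30
        assert np.array_equal(out1.values, out2.values)

    def test_smallest_image_fully_included(self):
        data = toy_data(90)
        smallest = min(int((data.image_ids == i).sum())
                       for i in np.unique(data.image_ids))
        out = sample_balanced(data, smallest, seed=0)
        assert all(int((out.image_ids == i).sum()) == smallest
                   for i in np.unique(data.image_ids))

    def test_undersized_image_error_names_image(self):
        data = toy_data(30)
        with pytest.raises(ValueError, match="image"):
            sample_balanced(data, 1000, seed=0)


class TestFiveFoldSplit:
    def test_partition_property(self):
        data = toy_data(173, classes=("A", "B", "C"))
        folds = five_fold_split(data, seed=9)
        all_test = np.concatenate([t for _, t in folds])
        assert np.array_equal(np.sort(all_test), np.arange(len(data)))
        for train, test in folds:
            assert np.intersect1d(train, test).size == 0
            assert np.array_equal(np.sort(np.concatenate([train, test])),
                                  np.arange(len(data)))

    def test_class_stratification_exact(self):
        values = np.ones((500, 3))
        data = LabelledSpectra(values, np.array([1000.0, 1004.0, 1008.0]),
                               np.repeat(["A", "B", "C", "D", "E"], 100))
        for _, test in five_fold_split(data, seed=1):
            labs = data.labels[test]
            for c in "ABCDE":
                assert int((labs == c).sum()) == 20

    def test_patient_cells_within_one(self):
        values = np.ones((200, 3))
        data = LabelledSpectra(values, np.array([1000.0, 1004.0, 1008.0]),
                               np.repeat(["A", "B"], 100),
                               patient_ids=np.tile(np.repeat([0, 1], 50), 2))
        for _, test in five_fold_split(data, seed=3):
            for c in "AB":
                for p in (0, 1):
                    cell = int(((data.labels[test] == c)
                                & (data.patient_ids[test] == p)).sum())
                    assert 9 <= cell <= 11

    def test_small_class_raises(self):
        data = toy_data(20, classes=("A",))
        data.labels[:3] = "RARE"
        with pytest.raises(ValueError, match="RARE"):
            five_fold_split(data, seed=0)


class TestSensitivitySpecificity:
    def test_arithmetic(self):
        cm = pd.DataFrame([[9, 1], [10, 90]], index=["P", "N"],
                          columns=["P", "N"])
        out = sensitivity_specificity(cm)
        assert out["P"] == (pytest.approx(90.0), pytest.approx(90.0))

    def test_perfect_classifier(self):
        cm = pd.DataFrame(np.diag([5, 8, 13]), index=list("ABC"),
                          columns=list("ABC"))
        for sens, spec in sensitivity_specificity(cm).values():
            assert sens == pytest.approx(100.0)
            assert spec == pytest.approx(100.0)

    def test_degenerate_all_one_class(self):
        cm = pd.DataFrame([[10, 0], [20, 0]], index=["C", "D"],
                          columns=["C", "D"])
        out = sensitivity_specificity(cm)
        assert out["C"] == (pytest.approx(100.0), pytest.approx(0.0))
        assert out["D"] == (pytest.approx(0.0), pytest.approx(100.0))

    def test_empty_positive_set_raises(self):
        cm = pd.DataFrame([[0, 0], [3, 7]], index=["P", "N"],
                          columns=["P", "N"])
        with pytest.raises(ValueError, match="positive"):
            sensitivity_specificity(cm)


def separable_profiles():
    """Three noise-free classes with grossly different band sets."""
    mk = lambda name, extra: TissueProfile(
        name, ((1650.0, 1.0, 16.0), (1540.0, 0.6, 13.0)) + extra,
        (0.0,), 0.0)
    return (mk("A", ((1100.0, 0.5, 10.0),)),
            mk("B", ((1250.0, 0.5, 10.0),)),
            mk("C", ((1700.0, 0.5, 10.0),)))


class TestCrossValidate:
    def test_separable_noise_free_phantom_is_perfect(self):
        spec = PhantomSpec(class_profiles=separable_profiles(),
                           image_shape=(9, 10), wavenumber_grid=FAST_GRID,
                           paraffin_band=0.3, seed=0)
        data = make_phantom_dataset(n_images=2, seed=5, spec=spec)
        report = cross_validate(data, CvParams(k=3), seed=1)
        for stats in report.per_class.values():
            assert stats["sensitivity_mean"] == pytest.approx(100.0)
            assert stats["specificity_mean"] == pytest.approx(100.0)

    def test_deterministic_report(self):
        data = make_phantom_dataset(n_images=2, seed=3, image_shape=(10, 10),
                                    wavenumber_grid=FAST_GRID)
        r1 = cross_validate(data, CvParams(), seed=2)
        r2 = cross_validate(data, CvParams(), seed=2)
        assert r1.to_json() == r2.to_json()

    def test_confusion_rows_sum_to_fold_test_counts(self):
        data = make_phantom_dataset(n_images=2, seed=3, image_shape=(10, 10),
                                    wavenumber_grid=FAST_GRID)
        report = cross_validate(data, CvParams(), seed=2)
        folds = five_fold_split(data, seed=2)
        for cm, (_, test) in zip(report.folds, folds):
            for c in cm.index:
                assert cm.loc[c].sum() == int((data.labels[test] == c).sum())

    def test_noise_degrades_mean_sensitivity(self):
        """Averaged over seeds, higher channel noise cannot help recovery."""
        means = {}
        for sigma in (0.02, 0.3):
            sens = []
            for seed in range(10):
                data = make_phantom_dataset(
                    n_images=2, seed=seed, image_shape=(10, 10),
                    wavenumber_grid=FAST_GRID, noise_sigma=sigma)
                rep = cross_validate(data, CvParams(), seed=seed)
                sens.append(np.mean([d["sensitivity_mean"]
                                     for d in rep.per_class.values()]))
            means[sigma] = np.mean(sens)
        assert means[0.3] <= means[0.02] + 1e-9
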