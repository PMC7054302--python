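"""End-to-end harness: assemble datasets from the simulator, train every
classifier family on the same binned spectra, and score them with ACC_av.

Training sets are assembled by sampling line pixels from pool cubes after
the online preprocessing chain (median filter on the (y, lam) slice, then
121-sample binning). Background exemplars for the trainable families are
synthesized from dark pixels, impulse (cladding-like) spectra and 50/50
color mixtures, since the background class is an ordinary softmax output
and needs training signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baselines import (
    pearson_slice_classifier,
    supervised_unmix_slice_classifier,
    svm_slice_classifier,
    svm_train,
    unmix_unsupervised,
)
from .cnn import PixelCnn, TrainingConfig, build_pixel_cnn
from .evaluate import EvaluationReport, accuracy
from .preprocess import bin_spectrum, median_denoise, wrap_pixels
from .simulate import TrainingPool
from .types import BACKGROUND_LABEL, ReferenceLibrary


def preprocess_slice_spectra(slice2d: np.ndarray, n_bins: int = 121) -> np.ndarray:
    """Median-filter one normalized (y, lam) slice and bin it: (y, n_bins)."""
    return bin_spectrum(median_denoise(np.asarray(slice2d, dtype=np.float64)), n_bins)


@dataclass
class PixelDataset:
    spectra: np.ndarray  # (n, n_bins)
    labels: np.ndarray  # (n,)

    @property
    def patches(self) -> np.ndarray:
        return wrap_pixels(self.spectra)


def sample_pixel_dataset(
    pool: TrainingPool,
    indices: np.ndarray,
    n_per_cube: int,
    rng: np.random.Generator,
    n_bins: int = 121,
    n_slices_per_cube: int = 4,
) -> PixelDataset:
    """Sample preprocessed pixels with their ground-truth labels.

    For each selected pool cube a few scan steps are preprocessed in full
    (the median filter needs the whole slice) and pixels are drawn from
    them uniformly.
    """
    spectra_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    for idx in np.asarray(indices):
        entry = pool.cubes[int(idx)]
        nx, ny, _ = entry.cube.shape
        xs = rng.choice(nx, size=min(n_slices_per_cube, nx), replace=False)
        per_slice = int(np.ceil(n_per_cube / len(xs)))
        for x in xs:
            binned = preprocess_slice_spectra(entry.cube.data[int(x)], n_bins)
            ys = rng.choice(ny, size=min(per_slice, ny), replace=False)
            spectra_parts.append(binned[ys])
            label_parts.append(entry.label_map.labels[int(x), ys])
    return PixelDataset(np.concatenate(spectra_parts), np.concatenate(label_parts))


def make_background_exemplars(
    library: ReferenceLibrary,
    n: int,
    rng: np.random.Generator,
    n_bins: int = 121,
) -> PixelDataset:
    """Synthetic background training spectra: dark, impulse, 50/50 mixtures."""
    refs = np.stack([bin_spectrum(s, n_bins) for s in library.spectra])
    k = refs.shape[0]
    n_dark = n // 3
    n_imp = n // 3
    n_mix = n - n_dark - n_imp
    dark = np.abs(rng.normal(0.0, 0.01, size=(n_dark, n_bins)))
    imp = (rng.random((n_imp, n_bins)) < rng.random((n_imp, 1))).astype(float)
    i = rng.integers(k, size=n_mix)
    j = (i + 1 + rng.integers(k - 1, size=n_mix)) % k
    mix = 0.5 * refs[i] + 0.5 * refs[j]
    spectra = np.concatenate([dark, imp, mix])
    return PixelDataset(spectra, np.full(n, BACKGROUND_LABEL, dtype=np.int64))


def train_pixel_cnn_on_pool(
    pool: TrainingPool,
    train_idx: np.ndarray,
    val_idx: np.ndarray | None = None,
    config: TrainingConfig | None = None,
    n_per_cube: int = 100,
    n_val_per_cube: int = 40,
    background_fraction: float = 0.12,
    n_bins: int = 121,
    n_slices_per_cube: int = 4,
    seed: int = 0,
) -> tuple[PixelCnn, PixelDataset | None]:
    """Assemble a patch training set from the pool and fit the pixel CNN."""
    rng = np.random.default_rng(seed)
    train = sample_pixel_dataset(pool, train_idx, n_per_cube, rng, n_bins, n_slices_per_cube)
    n_bg = int(background_fraction * len(train.labels))
    bg = make_background_exemplars(pool.library, max(n_bg, 1), rng, n_bins)
    x = np.concatenate([train.spectra, bg.spectra])
    y = np.concatenate([train.labels, bg.labels])
    val = None
    if val_idx is not None and len(val_idx) > 0:
        val = sample_pixel_dataset(pool, val_idx, n_val_per_cube, rng, n_bins, n_slices_per_cube)
    model = build_pixel_cnn(seed=seed)
    model.fit(
        wrap_pixels(x),
        y,
        config or TrainingConfig(),
        val_patches=None if val is None else val.patches,
        val_labels=None if val is None else val.labels,
    )
    return model, val


def evaluate_cnn_fold(
    pool: TrainingPool,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainingConfig | None = None,
    **kwargs,
) -> EvaluationReport:
    """Train on one fold's training cubes, report ACC_av on its validation pixels."""
    model, val = train_pixel_cnn_on_pool(pool, train_idx, val_idx, config, **kwargs)
    assert val is not None
    pred = model.predict(val.patches)
    return accuracy(pred[None, :], val.labels[None, :])


@dataclass
class FamilyBenchmark:
    """ACC_av per classifier family on one common synthetic test set."""

    accuracies: dict[str, float]
    reports: dict[str, EvaluationReport]


def run_family_benchmark(
    pool: TrainingPool,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: TrainingConfig | None = None,
    n_per_cube: int = 120,
    n_test_per_cube: int = 60,
    n_bins: int = 121,
    nmf_components: int = 6,
    seed: int = 0,
) -> FamilyBenchmark:
    """Head-to-head comparison of all five families on identical pixels.

    Library families (Pearson, supervised and unsupervised unmixing) match
    against the gold reference library binned to the common grid; SVM and
    CNN are trained on the same sampled spectra (plus background
    exemplars). All are scored on the same held-out preprocessed pixels.
    """
    rng = np.random.default_rng(seed)
    train = sample_pixel_dataset(pool, train_idx, n_per_cube, rng, n_bins)
    test = sample_pixel_dataset(pool, test_idx, n_test_per_cube, rng, n_bins)
    n_bg = max(int(0.12 * len(train.labels)), 1)
    bg = make_background_exemplars(pool.library, n_bg, rng, n_bins)
    x_train = np.concatenate([train.spectra, bg.spectra])
    y_train = np.concatenate([train.labels, bg.labels])
    library_binned = pool.library.binned(n_bins)

    reports: dict[str, EvaluationReport] = {}

    cnn = build_pixel_cnn(seed=seed)
    cnn.fit(
        wrap_pixels(x_train), y_train, config or TrainingConfig(),
        val_patches=test.patches, val_labels=test.labels,
    )
    reports["cnn_pixel"] = accuracy(cnn.predict(test.patches)[None, :], test.labels[None, :])

    svm = svm_train(x_train, y_train)
    svm_clf = svm_slice_classifier(svm)
    reports["svm"] = accuracy(
        svm_clf.classify_slice(test.spectra).labels[None, :], test.labels[None, :]
    )

    sup = supervised_unmix_slice_classifier(library_binned)
    reports["unmix_supervised"] = accuracy(
        sup.classify_slice(test.spectra).labels[None, :], test.labels[None, :]
    )

    _, _, unsup_labels = unmix_unsupervised(
        test.spectra, library_binned, k=nmf_components, seed=seed
    )
    reports["unmix_unsupervised"] = accuracy(unsup_labels[None, :], test.labels[None, :])

    pear = pearson_slice_classifier(library_binned)
    reports["pearson"] = accuracy(
        pear.classify_slice(test.spectra).labels[None, :], test.labels[None, :]
    )

    return FamilyBenchmark({k: r.acc_av for k, r in reports.items()}, reports)
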