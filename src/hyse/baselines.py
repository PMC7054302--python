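"""Conventional spectral classifiers: Pearson, unmixing, one-vs-one SVM.

All families classify the same 121-sample binned spectra as the CNN, for
comparability. Library-matching families (Pearson, unmixing) use the gold
reference-spectrum library binned to the same grid; the SVM is trained on
labeled spectra like the CNN. Background policy for the library families:
a winning score below a per-family threshold (correlation < 0.5, abundance
< 0.2, both configurable) yields the background label.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.svm import SVC

from .cnn import ClassificationResult
from .types import BACKGROUND_LABEL, Hypercube, ReferenceLibrary

PEARSON_BACKGROUND_THRESHOLD = 0.5
ABUNDANCE_BACKGROUND_THRESHOLD = 0.2


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation of two spectra (1/(N-1) over z-scores)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n = len(a)
    za = (a - a.mean()) / a.std(ddof=1)
    zb = (b - b.mean()) / b.std(ddof=1)
    return float((za * zb).sum() / (n - 1))


def pearson_scores(spectra: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Correlation of each spectrum (n, d) against each reference (k, d)."""
    x = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    r = np.atleast_2d(np.asarray(references, dtype=np.float64))
    xc = x - x.mean(axis=1, keepdims=True)
    rc = r - r.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1, keepdims=True))
    rs = np.sqrt((rc**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (xc @ rc.T) / (xs @ rs.T)
    return rho


def pearson_classify(
    pixel_spectrum: np.ndarray,
    library: ReferenceLibrary,
    threshold: float = PEARSON_BACKGROUND_THRESHOLD,
) -> tuple[int, float]:
    """Label by the highest correlation against the library; ties → lowest index.

    A zero-variance spectrum (correlation undefined) and a winning
    correlation below the threshold both map to the background label.
    """
    spec = np.asarray(pixel_spectrum, dtype=np.float64)
    if np.std(spec) == 0.0:
        return BACKGROUND_LABEL, float("nan")
    rho = pearson_scores(spec[None], library.spectra)[0]
    rho = np.where(np.isnan(rho), -np.inf, rho)
    label = int(np.argmax(rho))  # argmax takes the lowest index on ties
    score = float(rho[label])
    if score < threshold:
        return BACKGROUND_LABEL, score
    return label, score


# ---------------------------------------------------------------------------
# spectral unmixing
# ---------------------------------------------------------------------------

def unmix_supervised(
    pixel_spectrum: np.ndarray,
    library: ReferenceLibrary,
    threshold: float = ABUNDANCE_BACKGROUND_THRESHOLD,
) -> tuple[np.ndarray, int]:
    """Non-negative least-squares abundances against the reference spectra.

    Non-negativity is enforced; abundances are not constrained to sum to
    one (illumination variation makes the sum physically meaningful).
    Label = argmax abundance, or background when the winning abundance
    falls below the threshold.
    """
    design = _checked_design(library)
    spec = np.asarray(pixel_spectrum, dtype=np.float64)
    abundances, _ = nnls(design, spec)
    label = int(np.argmax(abundances))
    if abundances[label] < threshold:
        return abundances, BACKGROUND_LABEL
    return abundances, label


def _successive_projection(x: np.ndarray, k: int) -> np.ndarray:
    """Successive-projection pure-pixel selection: indices of the k pixels
    that successively maximize the norm of their residual after projecting
    out the span of the pixels already chosen."""
    residual = x.astype(np.float64).copy()
    chosen: list[int] = []
    for _ in range(k):
        j = int(np.linalg.norm(residual, axis=1).argmax())
        chosen.append(j)
        v = residual[j]
        norm = np.linalg.norm(v)
        if norm <= 1e-12:
            break
        v = v / norm
        residual = residual - np.outer(residual @ v, v)
    while len(chosen) < k:  # degenerate rank: pad with repeats
        chosen.append(chosen[-1])
    return np.array(chosen)


def _checked_design(library: ReferenceLibrary) -> np.ndarray:
    design = library.spectra.T  # (channels, endmembers)
    k = design.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            if np.allclose(design[:, i], design[:, j]):
                raise ValueError(
                    f"duplicate reference spectra ({library.names[i]!r} / "
                    f"{library.names[j]!r}): unmixing design is singular"
                )
    return design


def unmix_pixels(
    spectra: np.ndarray,
    library: ReferenceLibrary,
    threshold: float = ABUNDANCE_BACKGROUND_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized supervised unmixing of many pixels: (abundances, labels)."""
    design = _checked_design(library)
    spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    abundances = np.stack([nnls(design, s)[0] for s in spectra])
    labels = abundances.argmax(axis=1)
    labels[abundances.max(axis=1) < threshold] = BACKGROUND_LABEL
    return abundances, labels


def unmix_unsupervised(
    cube: Hypercube | np.ndarray,
    library: ReferenceLibrary,
    k: int = 18,
    seed: int = 0,
    max_iter: int = 400,
    threshold: float = ABUNDANCE_BACKGROUND_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Blind endmember extraction by non-negative matrix factorization.

    The cube (or an already-flat pixels × channels matrix) is factored into
    ``k`` non-negative endmembers and abundances by multiplicative updates
    (a standard stand-in for the published geometric/sparse unmixing
    solvers). Plain randomly initialized NMF is rotation-ambiguous, so the
    factorization is seeded with the successive-projection pure-pixel
    heuristic: the ``k`` mutually most extreme pixels initialize the
    endmembers and their NNLS abundances initialize the loadings, after
    which the multiplicative updates refine both. Each discovered
    endmember is then matched to the library class it correlates with
    best, and each pixel takes the matched class of its largest abundance.
    Deterministic given the seed (the pure-pixel init itself is
    deterministic; the seed breaks hypothetical ties).

    Returns ``(endmembers (k, channels), abundances (n_pixels, k),
    labels (n_pixels,))``.
    """
    if isinstance(cube, Hypercube):
        pixels = cube.data.reshape(-1, cube.shape[2])
    else:
        pixels = np.atleast_2d(np.asarray(cube, dtype=np.float64))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > pixels.shape[0]:
        raise ValueError(f"k={k} exceeds the number of pixels ({pixels.shape[0]})")
    x = np.maximum(pixels, 0.0)
    h0 = np.maximum(x[_successive_projection(x, k)], 1e-6)
    w0 = np.stack([nnls(h0.T, row)[0] for row in x]) + 1e-6
    model = NMF(
        n_components=k,
        init="custom",
        solver="mu",
        max_iter=max_iter,
        random_state=seed,
        tol=1e-9,
    )
    abundances = model.fit_transform(x, W=w0, H=h0.copy())
    endmembers = model.components_
    refs = library.spectra
    if refs.shape[1] != endmembers.shape[1]:
        raise ValueError("library grid does not match the cube's spectral extent")
    rho = pearson_scores(endmembers, refs)
    rho = np.where(np.isnan(rho), -np.inf, rho)
    matched = rho.argmax(axis=1)  # endmember -> library class
    winner = abundances.argmax(axis=1)
    labels = matched[winner]
    labels[abundances.max(axis=1) < threshold] = BACKGROUND_LABEL
    return endmembers, abundances, labels


# ---------------------------------------------------------------------------
# one-vs-one SVM
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    family: str
    svc: SVC
    classes: np.ndarray

    @property
    def n_binary_classifiers(self) -> int:
        """k(k-1)/2 pairwise maximum-margin classifiers."""
        k = len(self.classes)
        return k * (k - 1) // 2


def svm_train(
    spectra: np.ndarray,
    labels: np.ndarray,
    C: float = 10.0,
    gamma: str | float = "scale",
    seed: int = 0,
) -> SvmModel:
    """Train the one-vs-one multi-class SVM (RBF kernel) on binned spectra."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("SVM training requires at least 2 classes")
    svc = SVC(
        kernel="rbf",
        C=C,
        gamma=gamma,
        decision_function_shape="ovo",
        random_state=seed,
    )
    svc.fit(np.asarray(spectra, dtype=np.float64), labels)
    return SvmModel("svm", svc, svc.classes_)


def svm_classify(model: SvmModel, spectrum: np.ndarray) -> int:
    """Majority vote over the pairwise classifiers; ties → lowest class index."""
    spec = np.atleast_2d(np.asarray(spectrum, dtype=np.float64))
    return int(model.svc.predict(spec)[0])


def svm_predict(model: SvmModel, spectra: np.ndarray) -> np.ndarray:
    return model.svc.predict(np.atleast_2d(np.asarray(spectra, dtype=np.float64)))


# ---------------------------------------------------------------------------
# uniform per-slice contract
# ---------------------------------------------------------------------------

class SpectrumClassifier:
    """Uniform wrapper: any family classifying binned spectra per slice."""

    def __init__(self, family: str, predict_fn) -> None:
        self.family = family
        self._predict = predict_fn

    def classify_slice(self, spectra: np.ndarray) -> ClassificationResult:
        spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
        t0 = time.perf_counter()
        labels = np.asarray(self._predict(spectra))
        elapsed = time.perf_counter() - t0
        return ClassificationResult(labels, None, elapsed)


def pearson_slice_classifier(
    library: ReferenceLibrary, threshold: float = PEARSON_BACKGROUND_THRESHOLD
) -> SpectrumClassifier:
    refs = library.spectra

    def predict(spectra: np.ndarray) -> np.ndarray:
        rho = pearson_scores(spectra, refs)
        degenerate = np.isnan(rho).all(axis=1)
        rho = np.where(np.isnan(rho), -np.inf, rho)
        labels = rho.argmax(axis=1)
        labels[rho.max(axis=1) < threshold] = BACKGROUND_LABEL
        labels[degenerate] = BACKGROUND_LABEL
        return labels

    return SpectrumClassifier("pearson", predict)


def supervised_unmix_slice_classifier(
    library: ReferenceLibrary, threshold: float = ABUNDANCE_BACKGROUND_THRESHOLD
) -> SpectrumClassifier:
    return SpectrumClassifier(
        "unmix_supervised", lambda s: unmix_pixels(s, library, threshold)[1]
    )


def svm_slice_classifier(model: SvmModel) -> SpectrumClassifier:
    return SpectrumClassifier("svm", lambda s: svm_predict(model, s))
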