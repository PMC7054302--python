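"""Quantitative evaluation and operator-facing rendering.

The headline metric is the average classification accuracy

    ACC_av = (1 - sum(max_L |E_L - R_L|) / N) * 100

where ``E_L`` and ``R_L`` are the predicted and reference label maps in
one-hot (categorical) encoding over the 19 labels, ``max_L`` is the
maximum along the label dimension — 1 exactly when the two labels differ —
and ``N`` the number of pixels. Timing summaries report per-slice seconds
and the derived frames-per-second; they are hardware-dependent and are
reported, never asserted against published figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn import ClassificationResult
from .types import BACKGROUND_LABEL, N_LABELS, LabelMap, ReferenceLibrary


@dataclass
class EvaluationReport:
    acc_av: float
    confusion: np.ndarray
    n_pixels: int
    per_slice_seconds: list[float] = field(default_factory=list)

    @property
    def fps(self) -> float | None:
        if not self.per_slice_seconds:
            return None
        return 1.0 / float(np.mean(self.per_slice_seconds))


def accuracy(
    predicted: LabelMap | np.ndarray,
    reference: LabelMap | np.ndarray,
    n_labels: int = N_LABELS,
    per_slice_seconds: list[float] | None = None,
) -> EvaluationReport:
    """ACC_av via one-hot encoding, plus the 19×19 confusion matrix."""
    e = predicted.labels if isinstance(predicted, LabelMap) else np.asarray(predicted)
    r = reference.labels if isinstance(reference, LabelMap) else np.asarray(reference)
    if e.shape != r.shape:
        raise ValueError(f"shape mismatch: predicted {e.shape} vs reference {r.shape}")
    if isinstance(predicted, LabelMap) and isinstance(reference, LabelMap):
        if predicted.legend != reference.legend:
            raise ValueError("legend mismatch between predicted and reference maps")
    e = e.ravel().astype(np.int64)
    r = r.ravel().astype(np.int64)
    if e.size == 0:
        raise ValueError("empty label maps")
    n = e.size
    e_onehot = np.zeros((n, n_labels), dtype=np.int8)
    r_onehot = np.zeros((n, n_labels), dtype=np.int8)
    e_onehot[np.arange(n), e] = 1
    r_onehot[np.arange(n), r] = 1
    disagreement = np.abs(e_onehot - r_onehot).max(axis=1)  # 1 iff labels differ
    acc_av = (1.0 - disagreement.sum() / n) * 100.0
    confusion = np.zeros((n_labels, n_labels), dtype=np.int64)
    np.add.at(confusion, (r, e), 1)
    return EvaluationReport(
        float(acc_av), confusion, int(n), list(per_slice_seconds or [])
    )


@dataclass
class TimingSummary:
    mean_seconds: float
    median_seconds: float
    max_seconds: float
    fps: float
    n_slices: int


def timing_report(results: list[ClassificationResult] | list[float]) -> TimingSummary:
    """Per-slice timing summary and derived fps (hardware-dependent)."""
    if len(results) == 0:
        raise ValueError("timing report requires at least one slice")
    seconds = np.array(
        [r.per_slice_time if isinstance(r, ClassificationResult) else float(r) for r in results]
    )
    return TimingSummary(
        mean_seconds=float(seconds.mean()),
        median_seconds=float(np.median(seconds)),
        max_seconds=float(seconds.max()),
        fps=float(1.0 / seconds.mean()),
        n_slices=len(seconds),
    )


def render_prediction_map(
    labels: LabelMap | np.ndarray, library: ReferenceLibrary
) -> np.ndarray:
    """Per-pixel RGB from the library's display codes; background is black."""
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    lut = np.zeros((N_LABELS, 3), dtype=np.uint8)
    lut[: library.n_classes] = library.rgb
    lut[library.background_label] = (0, 0, 0)
    if lab.min() < 0 or lab.max() >= N_LABELS:
        raise ValueError(f"labels outside 0..{N_LABELS - 1} cannot be rendered")
    return lut[lab]


def decode_rgb_to_labels(rgb: np.ndarray, library: ReferenceLibrary) -> np.ndarray:
    """Nearest display-color decoding: RGB image → label map (inverse render)."""
    img = np.asarray(rgb, dtype=np.float64)
    lut = np.zeros((N_LABELS, 3), dtype=np.float64)
    lut[: library.n_classes] = library.rgb
    d2 = ((img[..., None, :] - lut) ** 2).sum(axis=-1)
    return d2.argmin(axis=-1).astype(np.int64)


def render_line_overlay(
    wide_field: np.ndarray,
    slice_result: ClassificationResult | np.ndarray,
    line_position: int,
    library: ReferenceLibrary,
    tint_background: bool = False,
) -> np.ndarray:
    """Overlay one classified line on a wide-field RGB image.

    The classified line replaces row ``line_position``; elsewhere the image
    is untouched. Background-class pixels on the line are left untinted by
    default (configurable), matching how an operator display keeps the
    white-light view where nothing was recognized.
    """
    img = np.asarray(wide_field)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("wide_field must be an (H, W, 3) RGB image")
    labels = (
        slice_result.labels
        if isinstance(slice_result, ClassificationResult)
        else np.asarray(slice_result)
    )
    if not 0 <= line_position < img.shape[0]:
        raise ValueError(f"line position {line_position} outside image height {img.shape[0]}")
    if len(labels) != img.shape[1]:
        raise ValueError("classified line length must match the image width")
    out = img.copy()
    colors = render_prediction_map(labels[None, :].astype(np.int64), library)[0]
    if tint_background:
        out[line_position] = colors
    else:
        keep = labels == library.background_label
        row = colors.copy()
        row[keep] = img[line_position][keep]
        out[line_position] = row
    return out


def downsample_reference(
    reference: np.ndarray,
    target_shape: tuple[int, int],
    library: ReferenceLibrary | None = None,
    legend: dict[int, str] | None = None,
) -> LabelMap:
    """Block-majority downsampling of a high-resolution reference raster.

    ``reference`` is either an integer label raster or an RGB image (which
    is first decoded by nearest display color, requiring ``library``).
    Each target cell takes the most frequent label of its source block;
    ties break to the lowest label. The target must not exceed the source.
    """
    ref = np.asarray(reference)
    if ref.ndim == 3:
        if library is None:
            raise ValueError("decoding an RGB reference requires the library")
        ref = decode_rgb_to_labels(ref, library)
    th, tw = target_shape
    sh, sw = ref.shape
    if th > sh or tw > sw:
        raise ValueError(f"target {target_shape} larger than source {ref.shape}")
    row_edges = np.linspace(0, sh, th + 1).astype(int)
    col_edges = np.linspace(0, sw, tw + 1).astype(int)
    out = np.empty((th, tw), dtype=np.int64)
    for i in range(th):
        for j in range(tw):
            block = ref[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            out[i, j] = np.bincount(block.ravel(), minlength=N_LABELS).argmax()
    if legend is None:
        legend = library.legend() if library is not None else {
            int(v): str(v) for v in np.unique(out)
        }
    return LabelMap(out, legend)
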