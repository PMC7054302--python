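"""Core containers for line-scan hyperspectral endoscopy data.

Axis convention, fixed at the API boundary: a hypercube is indexed
``(x, y, lam)`` where ``x`` is the scan step (one per acquired line),
``y`` the spatial pixel along the measured line, and ``lam`` the spectral
channel. All indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Integer label reserved for the background (non-chart) class.
BACKGROUND_LABEL = 18

#: Total number of labels: 18 chart colors plus background.
N_LABELS = 19


@dataclass
class Hypercube:
    """A 3-D reflectance (or raw-count) array with its wavelength axis.

    Parameters
    ----------
    data
        Array of shape ``(x, y, lam)``; non-negative.
    wavelengths
        Strictly increasing wavelength vector in nm, length ``data.shape[2]``.
    meta
        Free-form acquisition metadata (grating, exposure, simulator draws...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"hypercube data must have 3 axes, got {self.data.ndim}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                "wavelength vector length must equal the spectral extent "
                f"({len(self.wavelengths)} != {self.data.shape[2]})"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("hypercube data must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def slice(self, x: int) -> np.ndarray:
        """The 2-D spatial-spectral image ``(y, lam)`` at scan step ``x``."""
        return self.data[x]


@dataclass
class CalibrationFrames:
    """White-reference and dark frames used for reflectance normalization.

    Both are 2-D ``(y, lam)`` frames (broadcast over scan steps) or full
    3-D arrays matching the cube.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")
        if self.white.ndim not in (2, 3):
            raise ValueError("calibration frames must be 2-D (y, lam) or 3-D")


@dataclass
class SpectralClass:
    """One named color class: reference reflectance spectrum + display RGB."""

    name: str
    spectrum: np.ndarray
    rgb: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=np.float64)


@dataclass
class ReferenceLibrary:
    """The 18-class reference-spectrum library defining the label vocabulary.

    Labels 0..17 are the chart colors in ``classes`` order; label 18 is the
    reserved background class (rendered black, no reference spectrum).
    """

    wavelengths: np.ndarray
    classes: list[SpectralClass]
    background_label: int = BACKGROUND_LABEL

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        for c in self.classes:
            if len(c.spectrum) != len(self.wavelengths):
                raise ValueError(
                    f"class {c.name!r} spectrum not on the library wavelength grid"
                )

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    @property
    def spectra(self) -> np.ndarray:
        """Matrix of reference spectra, shape ``(n_classes, n_wavelengths)``."""
        return np.stack([c.spectrum for c in self.classes])

    @property
    def rgb(self) -> np.ndarray:
        """Display colors, shape ``(n_classes, 3)``, uint8."""
        return np.array([c.rgb for c in self.classes], dtype=np.uint8)

    def legend(self) -> dict[int, str]:
        out = {i: c.name for i, c in enumerate(self.classes)}
        out[self.background_label] = "background"
        return out

    def binned(self, n_bins: int) -> "ReferenceLibrary":
        """The same library with every spectrum binned to ``n_bins`` samples."""
        from .preprocess import bin_spectrum  # local import avoids a cycle

        wl = bin_spectrum(self.wavelengths, n_bins)
        classes = [
            SpectralClass(c.name, bin_spectrum(c.spectrum, n_bins), c.rgb)
            for c in self.classes
        ]
        return ReferenceLibrary(wl, classes, self.background_label)


@dataclass
class LabelMap:
    """Per-pixel categorical labels over ``(x, y)`` with a label legend."""

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D (x, y)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        used = set(np.unique(self.labels).tolist())
        missing = used - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from the legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]
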