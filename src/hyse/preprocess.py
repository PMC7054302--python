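"""Raw cube → classifier-ready inputs.

The online pipeline applied to every acquired 2-D spatial-spectral slice:

1. reflectance normalization against white/dark references,
   ``I_n = (I - I_dark) / (I_white - I_dark)``, clipped to [0, 1];
2. a 7×7 2-D median filter over the (y, lam) slice, removing the
   salt-and-pepper impulses introduced by the fiber-bundle cladding;
3. binning of the spectral axis to 121 equispaced samples, making the
   classifier robust to the spectral resolution of the grating in use;
4. wrapping of each pixel's 121-sample spectrum into an 11×11 patch so a
   2-D convolutional network can consume single-pixel spectra.

The median filter operates per (y, lam) slice — the only choice that works
identically online (one slice at a time) and offline. Binning aggregates by
averaging over contiguous near-equal index ranges. Wrapping is row-major
(sample k → row k//11, column k%11) and exactly invertible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import CalibrationFrames, Hypercube

DEFAULT_N_BINS = 121
MEDIAN_SIZE = 7


@dataclass
class SpectralPatch:
    """An 11×11 wrap of one pixel's binned spectrum, plus its source pixel."""

    patch: np.ndarray
    origin: tuple[int, int] | None = None


@dataclass
class PreparedSlice:
    """Output of :func:`prepare_slice`: one patch per line pixel plus timing."""

    patches: list[SpectralPatch]
    array: np.ndarray  # (n_pixels, side, side) stacked patches
    seconds: float


def normalize_reflectance(cube: Hypercube, cal: CalibrationFrames) -> Hypercube:
    """White/dark reflectance normalization, clipped to [0, 1].

    Pixels whose denominator ``white - dark`` is non-positive are set to 0;
    their fraction is recorded under ``meta['invalid_calibration_fraction']``.
    """
    norm = normalize_array(cube.data, cal)
    meta = dict(cube.meta)
    denom = cal.white - cal.dark
    meta["invalid_calibration_fraction"] = float(np.mean(denom <= 0))
    meta["normalized"] = True
    return Hypercube(norm, cube.wavelengths, meta)


def normalize_array(data: np.ndarray, cal: CalibrationFrames) -> np.ndarray:
    """Array-level Eq-free core of the normalization; broadcasts calibration."""
    data = np.asarray(data, dtype=np.float64)
    try:
        np.broadcast_shapes(data.shape, cal.white.shape)
    except ValueError as exc:
        raise ValueError(
            f"calibration shape {cal.white.shape} not broadcastable to cube "
            f"shape {data.shape}"
        ) from exc
    denom = cal.white - cal.dark
    valid = denom > 0
    safe = np.where(valid, denom, 1.0)
    out = (data - cal.dark) / safe
    out = np.clip(out, 0.0, 1.0)
    return np.where(np.broadcast_to(valid, out.shape), out, 0.0)


def median_denoise(data: Hypercube | np.ndarray) -> Hypercube | np.ndarray:
    """7×7 median filter per (y, lam) slice with reflective edge padding."""
    if isinstance(data, Hypercube):
        out = np.empty_like(data.data, dtype=np.float64)
        for x in range(data.shape[0]):
            out[x] = _median2d(data.data[x])
        return Hypercube(out, data.wavelengths, dict(data.meta))
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D (y, lam) slice or a Hypercube")
    return _median2d(arr)


def _median2d(slc: np.ndarray) -> np.ndarray:
    return ndimage.median_filter(slc, size=MEDIAN_SIZE, mode="reflect")


def bin_spectrum(spectrum: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Average the last axis down to ``n_bins`` contiguous near-equal ranges.

    Range lengths follow :func:`numpy.array_split` (they differ by at most 1,
    longer ranges first). Upsampling is refused.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    length = spectrum.shape[-1]
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if length < n_bins:
        raise ValueError(f"cannot bin a length-{length} spectrum into {n_bins} bins")
    if length % n_bins == 0:
        width = length // n_bins
        return spectrum.reshape(spectrum.shape[:-1] + (n_bins, width)).mean(axis=-1)
    sizes = np.full(n_bins, length // n_bins)
    sizes[: length % n_bins] += 1
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    sums = np.add.reduceat(spectrum, starts, axis=-1)
    return sums / sizes


def wrap_patch(binned: np.ndarray, origin: tuple[int, int] | None = None) -> SpectralPatch:
    """Row-major wrap of a length-121 (or any perfect-square) vector."""
    binned = np.asarray(binned, dtype=np.float64)
    if binned.ndim != 1:
        raise ValueError("wrap_patch expects a 1-D binned spectrum")
    side = int(round(np.sqrt(binned.size)))
    if side * side != binned.size:
        raise ValueError(f"length {binned.size} is not a perfect square")
    return SpectralPatch(binned.reshape(side, side), origin)


def unwrap_patch(patch: SpectralPatch | np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`wrap_patch`."""
    arr = patch.patch if isinstance(patch, SpectralPatch) else np.asarray(patch)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square 2-D patch")
    return arr.reshape(-1)


def wrap_pixels(binned: np.ndarray) -> np.ndarray:
    """Vectorized wrap: (..., n_bins) → (..., side, side), row-major."""
    binned = np.asarray(binned, dtype=np.float64)
    side = int(round(np.sqrt(binned.shape[-1])))
    if side * side != binned.shape[-1]:
        raise ValueError(f"length {binned.shape[-1]} is not a perfect square")
    return binned.reshape(binned.shape[:-1] + (side, side))


def prepare_slice(
    slc: np.ndarray,
    cal: CalibrationFrames,
    n_bins: int = DEFAULT_N_BINS,
    x_index: int = 0,
) -> PreparedSlice:
    """Normalize → median → bin → wrap one (y, lam) slice; time the work.

    Preprocessing dominates the online run-time budget, so the elapsed
    wall-clock seconds are recorded for the frames-per-second accounting.
    """
    slc = np.asarray(slc, dtype=np.float64)
    if slc.ndim != 2:
        raise ValueError("expected a 2-D (y, lam) slice")
    t0 = time.perf_counter()
    norm = normalize_array(slc, cal)
    den = _median2d(norm)
    binned = bin_spectrum(den, n_bins)
    arr = wrap_pixels(binned)
    seconds = time.perf_counter() - t0
    patches = [SpectralPatch(arr[y], (x_index, y)) for y in range(arr.shape[0])]
    return PreparedSlice(patches, arr, seconds)
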