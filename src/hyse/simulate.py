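"""Synthetic line-scan hyperspectral datasets of a 24-square color chart.

This module replaces the physical acquisition: it renders hypercubes of a
Macbeth-type chart (18 color squares + 6 grayscale squares) section by
section, together with matching white/dark calibration frames and exact
ground-truth label maps, and implements the augmentation procedure used to
grow 12 base measurements into a training pool (additive Gaussian noise plus
linear illumination fields with a bias toward under-illumination).

What is emulated
----------------
* a halogen-like illumination spectrum spanning 400–750 nm, divided out
  exactly by white-reference normalization;
* CCD counts with additive Gaussian read noise on a 16-bit-like full scale;
* fiber-cladding "salt and pepper" impulses at a configurable pixel fraction;
* a fixed smooth per-class deviation between the gold reference-spectrum
  library and the paint actually on the chart (the reference spectra of a
  real system come from a separate spectrometer and never match the imaged
  chart perfectly) — this is the *calibration mismatch*;
* planar geometry at a configurable incidence angle, and a tube (lumen)
  geometry with inverse-square intensity fall-off and a boundary blur whose
  width grows with working distance.

Every operation is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import normalize_array
from .types import (
    BACKGROUND_LABEL,
    CalibrationFrames,
    Hypercube,
    LabelMap,
    ReferenceLibrary,
    SpectralClass,
)

DEFAULT_SHAPE = (50, 512, 1209)
DEFAULT_NOISE_SD = 0.01  # fraction of the count full scale
DEFAULT_ARTIFACT_FRACTION = 0.01
DEFAULT_MISMATCH_SD = 0.02
FULL_SCALE = 60000.0
DARK_LEVEL = 500.0
WHITE_REFLECTANCE = 1.0  # ideal reflectance target, so normalization is exact

# Classic 24-patch chart: 18 color names with manufacturer-style RGB codes.
_MACBETH = [
    ("dark skin", (115, 82, 68)),
    ("light skin", (194, 150, 130)),
    ("blue sky", (98, 122, 157)),
    ("foliage", (87, 108, 67)),
    ("blue flower", (133, 128, 177)),
    ("bluish green", (103, 189, 170)),
    ("orange", (214, 126, 44)),
    ("purplish blue", (80, 91, 166)),
    ("moderate red", (193, 90, 99)),
    ("purple", (94, 60, 108)),
    ("yellow green", (157, 188, 64)),
    ("orange yellow", (224, 163, 46)),
    ("blue", (56, 61, 150)),
    ("green", (70, 148, 73)),
    ("red", (175, 54, 60)),
    ("yellow", (231, 199, 31)),
    ("magenta", (187, 86, 149)),
    ("cyan", (8, 133, 161)),
]
_GRAY_LEVELS = (0.90, 0.59, 0.36, 0.19, 0.09, 0.031)


@dataclass
class ChartSpec:
    """Layout of the 24-square chart: which class sits in each grid cell.

    ``square_classes`` holds, per (row, col) of the 4×6 grid, either a color
    label in 0..17 or ``18 + g`` for grayscale square ``g`` (g in 0..5).
    Grayscale squares are never assigned color-class labels; in ground-truth
    label maps they carry the background label.
    """

    square_classes: np.ndarray
    gray_levels: tuple[float, ...] = _GRAY_LEVELS
    n_color_classes: int = 18
    n_gray: int = 6

    def __post_init__(self) -> None:
        self.square_classes = np.asarray(self.square_classes, dtype=np.int64)
        if self.square_classes.size != self.n_color_classes + self.n_gray:
            raise ValueError("chart must have 24 squares")
        vals = sorted(self.square_classes.ravel().tolist())
        if vals != list(range(self.n_color_classes + self.n_gray)):
            raise ValueError("each color and gray square must appear exactly once")

    @property
    def n_sections(self) -> int:
        return (self.square_classes.shape[0] // 2) * (self.square_classes.shape[1] // 2)

    def section_squares(self, section: int) -> np.ndarray:
        """The 2×2 block of square codes imaged as one 25 mm × 25 mm section."""
        rows, cols = self.square_classes.shape
        n_block_cols = cols // 2
        if not 0 <= section < self.n_sections:
            raise ValueError(f"section {section} out of range 0..{self.n_sections - 1}")
        br, bc = divmod(section, n_block_cols)
        return self.square_classes[2 * br : 2 * br + 2, 2 * bc : 2 * bc + 2]


def default_chart() -> ChartSpec:
    """Colors 0..17 row-major in rows 0–2, the 6-step gray scale in row 3."""
    grid = np.arange(24).reshape(4, 6)
    return ChartSpec(grid)


@dataclass
class SceneGeometry:
    """Imaging geometry for one rendered section.

    ``working_distance_profile`` is a per-line-pixel relative working
    distance (1 = nearest point). Planar mode is constant; tube mode rises
    monotonically toward the lumen center of the line. Intensity falls off
    with the inverse square of the distance factor, and (tube only) square
    boundaries are blurred with a Gaussian whose sigma grows linearly with
    the distance factor up to ``blur_sigma_max``.
    """

    mode: str = "planar"
    incidence_angle: float = 90.0
    max_distance_factor: float = 1.0
    blur_sigma_max: float = 0.0
    working_distance_profile: np.ndarray | None = None
    attenuation_enabled: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("planar", "tube"):
            raise ValueError("geometry mode must be 'planar' or 'tube'")
        if not 0.0 < self.incidence_angle <= 90.0:
            raise ValueError("incidence angle must be in (0, 90] degrees")

    def distance_profile(self, ny: int) -> np.ndarray:
        if self.working_distance_profile is not None:
            prof = np.asarray(self.working_distance_profile, dtype=np.float64)
            if len(prof) != ny:
                raise ValueError("working_distance_profile length must equal ny")
            return prof
        if self.mode == "planar" or self.max_distance_factor <= 1.0:
            return np.ones(ny)
        u = np.linspace(0.0, 1.0, ny)
        bump = np.cos(np.pi * (u - 0.5)) ** 2  # 0 at line edges, 1 at lumen center
        bump = bump / bump.max()  # attain the configured maximum on any grid
        return 1.0 + (self.max_distance_factor - 1.0) * bump

    def blur_sigmas(self, ny: int) -> np.ndarray:
        prof = self.distance_profile(ny)
        if self.blur_sigma_max <= 0 or self.max_distance_factor <= 1.0:
            return np.zeros(ny)
        return self.blur_sigma_max * (prof - 1.0) / (self.max_distance_factor - 1.0)


def planar_geometry(incidence_angle: float = 90.0) -> SceneGeometry:
    return SceneGeometry(mode="planar", incidence_angle=incidence_angle)


def tube_geometry(
    max_distance_factor: float = 1.15,
    blur_sigma_max: float = 2.0,
    incidence_angle: float = 90.0,
    attenuation_enabled: bool = True,
) -> SceneGeometry:
    return SceneGeometry(
        mode="tube",
        incidence_angle=incidence_angle,
        max_distance_factor=max_distance_factor,
        blur_sigma_max=blur_sigma_max,
        attenuation_enabled=attenuation_enabled,
    )


@dataclass
class AugmentationParams:
    """Distributions for the linear illumination fields added in augmentation.

    A normalized base cube is multiplied by ``1 + sign_b*b + sign_s*s*u``
    with ``u`` the line coordinate normalized to [0, 1], ``b ~ N(bias_mean,
    bias_sd)`` and ``s ~ N(slope_mean, slope_sd)`` — illumination scales
    reflected intensity, it does not offset it. Signs are negative with
    probability ``under_illumination_prob``, biasing toward under-illuminated
    scenes as encountered in endoscopy.
    """

    bias_mean: float = 0.1
    bias_sd: float = 0.04
    slope_mean: float = 0.01
    slope_sd: float = 0.03
    noise_sd: float = 0.01
    n_augmented: int = 300
    seed: int = 0
    under_illumination_prob: float = 0.7

    def __post_init__(self) -> None:
        if self.bias_sd < 0 or self.slope_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_augmented < 0:
            raise ValueError("n_augmented must be >= 0")
        if not 0.0 <= self.under_illumination_prob <= 1.0:
            raise ValueError("under_illumination_prob must be a probability")


def make_reference_library(
    seed: int = 0,
    n_wavelengths: int = 1209,
    wl_min: float = 400.0,
    wl_max: float = 750.0,
) -> ReferenceLibrary:
    """Synthesize 18 smooth, distinct reflectance spectra in [0, 1].

    Each spectrum is a baseline plus Gaussian bumps in the blue/green/red
    bands with amplitudes guided by the class's display RGB (so "red" really
    reflects in the red), plus a seeded per-class jitter. The published chart
    reflectances are not reproduced — these are documented stand-ins with
    the same qualitative structure, including a few low-chroma (flat)
    classes. Deterministic given the seed; pairwise Pearson correlation of
    distinct classes is below 0.99 by construction (violating classes are
    re-jittered deterministically).
    """
    rng = np.random.default_rng(seed)
    wl = np.linspace(wl_min, wl_max, n_wavelengths)
    classes: list[SpectralClass] = []
    for name, rgb in _MACBETH:
        classes.append(SpectralClass(name, _synth_spectrum(wl, rgb, rng), rgb))

    # Enforce distinctness: re-jitter the later member of any pair that is
    # too correlated. Deterministic because draws come from the same rng.
    for _ in range(100):
        spectra = np.stack([c.spectrum for c in classes])
        corr = np.corrcoef(spectra)
        ii, jj = np.where(np.triu(corr, k=1) >= 0.99)
        if len(ii) == 0:
            break
        j = int(jj[0])
        classes[j] = SpectralClass(
            classes[j].name, _synth_spectrum(wl, classes[j].rgb, rng), classes[j].rgb
        )
    else:  # pragma: no cover - construction failure
        raise RuntimeError("could not synthesize 18 sufficiently distinct spectra")
    return ReferenceLibrary(wl, classes)


def _synth_spectrum(wl: np.ndarray, rgb: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    r, g, b = (v / 255.0 for v in rgb)
    base = 0.04 + 0.05 * rng.random()
    centers = np.array([455.0, 545.0, 625.0]) + rng.normal(0, 8, 3)
    widths = np.array([32.0, 34.0, 48.0]) + rng.normal(0, 5, 3)
    amps = 0.85 * np.array([b, g, r]) * (0.9 + 0.2 * rng.random(3))
    spec = np.full_like(wl, base)
    for c, w, a in zip(centers, widths, amps):
        spec = spec + a * np.exp(-0.5 * ((wl - c) / max(w, 10.0)) ** 2)
    # long-wavelength tail: warm colors keep reflecting into the NIR
    spec = spec + 0.6 * r * _sigmoid((wl - (660 + rng.normal(0, 10))) / 25.0) * (
        0.5 + 0.5 * rng.random()
    )
    # small seeded wiggle so no two spectra are exact scalings of each other
    spec = spec + 0.02 * np.sin(2 * np.pi * (wl - wl[0]) / (120 + 60 * rng.random()) + 2 * np.pi * rng.random())
    return np.clip(spec, 0.005, 0.97)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def chart_paint_spectra(
    chart: ChartSpec,
    library: ReferenceLibrary,
    mismatch_sd: float = DEFAULT_MISMATCH_SD,
) -> np.ndarray:
    """Effective reflectance of every square code (24, n_wl).

    Color squares are the library spectra warped by a fixed smooth per-class
    deviation of relative amplitude ``mismatch_sd`` (the calibration
    mismatch); the warp is seeded per class, independent of the render seed,
    so it is stable across sections and replicates like real paint. Gray
    squares are flat at the chart's gray levels.
    """
    wl = library.wavelengths
    u = (wl - wl[0]) / max(wl[-1] - wl[0], 1e-9)
    out = np.zeros((chart.n_color_classes + chart.n_gray, len(wl)))
    for k in range(chart.n_color_classes):
        spec = library.classes[k].spectrum
        if mismatch_sd > 0:
            crng = np.random.default_rng(7000 + k)
            curve = np.zeros_like(u)
            for _ in range(3):
                curve = curve + crng.normal(0, 1) * np.cos(
                    2 * np.pi * crng.integers(1, 4) * u + 2 * np.pi * crng.random()
                )
            curve = curve / max(np.abs(curve).max(), 1e-9)
            spec = spec * (1.0 + mismatch_sd * curve)
        out[k] = np.clip(spec, 0.0, 1.0)
    for g, level in enumerate(chart.gray_levels):
        out[chart.n_color_classes + g] = level
    return out


def illumination_spectrum(wl: np.ndarray) -> np.ndarray:
    """Halogen-like relative spectral power: rising smoothly toward the red."""
    u = (wl - 400.0) / 350.0
    return 0.45 + 0.55 * np.clip(u, 0.0, 1.0)


def render_base_hypercube(
    chart: ChartSpec,
    section: int,
    library: ReferenceLibrary,
    geometry: SceneGeometry | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    noise_sd: float = DEFAULT_NOISE_SD,
    artifact_fraction: float = DEFAULT_ARTIFACT_FRACTION,
    mismatch_sd: float = DEFAULT_MISMATCH_SD,
    full_scale: float = FULL_SCALE,
    dark_level: float = DARK_LEVEL,
) -> tuple[Hypercube, CalibrationFrames, LabelMap]:
    """Render one 4-square chart section as a raw-count hypercube.

    Returns the cube (counts, float, on a 16-bit-like full scale), the
    matching white/dark calibration frames (white rendered at the reference
    planar geometry), and the exact ground-truth label map. Gray squares are
    labeled background.
    """
    geometry = geometry or planar_geometry()
    nx, ny, nl = shape
    if nl != len(library.wavelengths):
        raise ValueError(
            f"cube spectral extent {nl} != library grid {len(library.wavelengths)}; "
            "build the library with matching n_wavelengths"
        )
    rng = np.random.default_rng(seed)
    wl = library.wavelengths

    block = chart.section_squares(section)  # (2, 2) square codes
    labels = _section_label_map(chart, block, nx, ny)

    paints = chart_paint_spectra(chart, library, mismatch_sd)
    lamp = illumination_spectrum(wl)
    inc = np.sin(np.deg2rad(geometry.incidence_angle))
    prof = geometry.distance_profile(ny)
    atten = 1.0 / prof**2 if geometry.attenuation_enabled else np.ones(ny)
    sigmas = geometry.blur_sigmas(ny)
    gain = 0.85 * full_scale

    # Reflectance templates per x-half: (ny, nl) each, blurred along y in
    # tube mode (colors blend near square boundaries at long working
    # distance; the label map stays exact).
    x_split = nx // 2
    counts = np.empty((nx, ny, nl), dtype=np.float64)
    for half, (x0, x1) in enumerate(((0, x_split), (x_split, nx))):
        square_codes = block[half]  # the two squares along y for this x-half
        template = np.empty((ny, nl))
        y_split = ny // 2
        template[:y_split] = paints[square_codes[0]]
        template[y_split:] = paints[square_codes[1]]
        if sigmas.max() > 0:
            template = _variable_blur_y(template, sigmas)
        signal = template * (lamp * inc * gain)[None, :] * atten[:, None]
        counts[x0:x1] = signal[None, :, :]
    counts += dark_level

    if noise_sd > 0:
        counts += rng.normal(0.0, noise_sd * full_scale, size=counts.shape)
    if artifact_fraction > 0:
        mask = rng.random(counts.shape) < artifact_fraction
        polarity = rng.random(counts.shape) < 0.5
        counts[mask & polarity] = 0.0
        counts[mask & ~polarity] = full_scale
    counts = np.clip(counts, 0.0, full_scale)

    white = WHITE_REFLECTANCE * (lamp * inc * gain)[None, :] * np.ones((ny, 1)) + dark_level
    dark = np.full((ny, nl), dark_level)

    meta = {
        "section": section,
        "seed": seed,
        "geometry_mode": geometry.mode,
        "incidence_angle": geometry.incidence_angle,
        "noise_sd": noise_sd,
        "artifact_fraction": artifact_fraction,
        "mismatch_sd": mismatch_sd,
        "blur_sigma_per_y": sigmas,
        "max_blur_sigma": float(sigmas.max()),
        "square_codes": block,
    }
    cube = Hypercube(counts, wl, meta)
    cal = CalibrationFrames(white=white, dark=dark)
    return cube, cal, LabelMap(labels, library.legend())


def _section_label_map(chart: ChartSpec, block: np.ndarray, nx: int, ny: int) -> np.ndarray:
    labels = np.empty((nx, ny), dtype=np.int64)
    x_split, y_split = nx // 2, ny // 2
    for i in range(2):
        for j in range(2):
            code = int(block[i, j])
            lab = code if code < chart.n_color_classes else BACKGROUND_LABEL
            xs = slice(0, x_split) if i == 0 else slice(x_split, nx)
            ys = slice(0, y_split) if j == 0 else slice(y_split, ny)
            labels[xs, ys] = lab
    return labels


def _variable_blur_y(template: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Gaussian blur along y with a per-row sigma (banded weight matrix)."""
    ny = template.shape[0]
    radius = int(np.ceil(3 * sigmas.max())) + 1
    offsets = np.arange(-radius, radius + 1)
    idx = np.clip(np.arange(ny)[:, None] + offsets[None, :], 0, ny - 1)
    sig = np.maximum(sigmas, 1e-6)[:, None]
    w = np.exp(-0.5 * (offsets[None, :] / sig) ** 2)
    w[sigmas <= 0] = 0.0
    w[sigmas <= 0, radius] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    # out[y] = sum_k w[y, k] * template[idx[y, k]]
    return np.einsum("yk,ykl->yl", w, template[idx])


@dataclass
class AugmentationResult:
    cubes: list[Hypercube]
    manifest: dict


def augment(base: Sequence[Hypercube], params: AugmentationParams) -> AugmentationResult:
    """Grow a set of base cubes by noise + linear illumination fields.

    Each augmented cube is a randomly chosen base cube scaled by the
    linear illumination field ``1 + sign_b*b + sign_s*s*u`` along the
    normalized line coordinate ``u``, plus additive Gaussian sensor noise.
    The relative change ``(out - base)/base`` therefore equals the drawn
    field exactly in the noiseless case. Base cubes are expected on the
    normalized reflectance scale. All draws (bias and slope magnitudes,
    signs, base indices) are logged in the manifest so their empirical
    moments are recoverable. Values are floored at 0; over-illuminated
    cubes may slightly exceed 1, which downstream preprocessing tolerates.
    """
    if len(base) == 0:
        raise ValueError("base cube list must be non-empty")
    rng = np.random.default_rng(params.seed)
    cubes: list[Hypercube] = []
    biases, slopes, sign_b_list, sign_s_list, base_idx_list = [], [], [], [], []
    for i in range(params.n_augmented):
        bi = int(rng.integers(len(base)))
        b = float(rng.normal(params.bias_mean, params.bias_sd))
        s = float(rng.normal(params.slope_mean, params.slope_sd))
        sign_b = -1.0 if rng.random() < params.under_illumination_prob else 1.0
        sign_s = -1.0 if rng.random() < params.under_illumination_prob else 1.0
        src = base[bi]
        ny = src.shape[1]
        u = np.linspace(0.0, 1.0, ny)
        fld = (1.0 + sign_b * b + sign_s * s * u)[None, :, None]
        out = src.data * fld
        if params.noise_sd > 0:
            out = out + rng.normal(0.0, params.noise_sd, size=src.shape)
        out = np.maximum(out, 0.0).astype(np.float32)
        meta = dict(src.meta)
        meta.update(
            {"augmented": True, "base_index": bi, "bias": b, "slope": s,
             "sign_bias": sign_b, "sign_slope": sign_s}
        )
        cubes.append(Hypercube(out, src.wavelengths, meta))
        biases.append(b)
        slopes.append(s)
        sign_b_list.append(sign_b)
        sign_s_list.append(sign_s)
        base_idx_list.append(bi)
    manifest = {
        "bias": biases,
        "slope": slopes,
        "sign_bias": sign_b_list,
        "sign_slope": sign_s_list,
        "base_index": base_idx_list,
        "params": {
            "bias_mean": params.bias_mean,
            "bias_sd": params.bias_sd,
            "slope_mean": params.slope_mean,
            "slope_sd": params.slope_sd,
            "noise_sd": params.noise_sd,
            "n_augmented": params.n_augmented,
            "seed": params.seed,
            "under_illumination_prob": params.under_illumination_prob,
        },
    }
    return AugmentationResult(cubes, manifest)


@dataclass
class PoolCube:
    """One member of the training pool with provenance for fold assignment."""

    cube: Hypercube
    label_map: LabelMap
    base_id: int
    kind: str  # "base" or "augmented"


@dataclass
class TrainingPool:
    cubes: list[PoolCube]
    manifest: dict
    library: ReferenceLibrary

    def __len__(self) -> int:
        return len(self.cubes)


def make_training_pool(
    library: ReferenceLibrary,
    chart: ChartSpec | None = None,
    n_replicates: int = 2,
    n_augmented: int = 300,
    seed: int = 0,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    sections: Sequence[int] | None = None,
    augmentation: AugmentationParams | None = None,
    geometry: SceneGeometry | None = None,
    **render_kwargs,
) -> TrainingPool:
    """Render the full training pool: sections × replicates, then augment.

    With the defaults (6 sections × 2 replicates, 300 augmented) this
    reproduces the 12-base / 312-cube pool bookkeeping. Base cubes are
    normalized to reflectance before augmentation; every pool cube carries
    the id of the base measurement it derives from, which the
    cross-validation fold assignment uses as its leakage guard.
    """
    chart = chart or default_chart()
    sections = list(sections) if sections is not None else list(range(chart.n_sections))
    base_cubes: list[Hypercube] = []
    entries: list[PoolCube] = []
    label_maps: list[LabelMap] = []
    for rep in range(n_replicates):
        for sec in sections:
            cube, cal, lmap = render_base_hypercube(
                chart, sec, library, geometry=geometry,
                seed=seed + 1000 * rep + 10 * sec, shape=shape, **render_kwargs
            )
            norm = Hypercube(
                normalize_array(cube.data, cal).astype(np.float32),
                cube.wavelengths,
                dict(cube.meta),
            )
            base_cubes.append(norm)
            label_maps.append(lmap)
            entries.append(PoolCube(norm, lmap, base_id=len(base_cubes) - 1, kind="base"))
    aug_params = augmentation or AugmentationParams(n_augmented=n_augmented, seed=seed + 999)
    if aug_params.n_augmented != n_augmented and augmentation is None:
        aug_params.n_augmented = n_augmented
    result = augment(base_cubes, aug_params)
    for cube in result.cubes:
        bi = int(cube.meta["base_index"])
        entries.append(PoolCube(cube, label_maps[bi], base_id=bi, kind="augmented"))
    return TrainingPool(entries, result.manifest, library)


@dataclass
class TubeDataset:
    cubes: list[Hypercube]
    calibrations: list[CalibrationFrames]
    label_maps: list[LabelMap]


def render_tube_dataset(
    chart: ChartSpec,
    library: ReferenceLibrary,
    seed: int = 0,
    sections: Sequence[int] | None = None,
    geometry: SceneGeometry | None = None,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    **render_kwargs,
) -> TubeDataset:
    """Render sections of the chart bent into a cylindrical lumen.

    Per-pixel intensity falls off with the inverse square of the working
    distance and square boundaries blur with a kernel whose width grows
    with distance; ground-truth labels are unchanged by either effect.
    With attenuation disabled and zero blur the output equals the planar
    rendering at the same seed.
    """
    sections = list(sections) if sections is not None else list(range(chart.n_sections))
    geometry = geometry or tube_geometry()
    cubes, cals, lmaps = [], [], []
    for sec in sections:
        cube, cal, lmap = render_base_hypercube(
            chart, sec, library, geometry=geometry, seed=seed + 10 * sec,
            shape=shape, **render_kwargs
        )
        cubes.append(cube)
        cals.append(cal)
        lmaps.append(lmap)
    return TubeDataset(cubes, cals, lmaps)
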