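# Methods

This note documents the models, defaults and design choices behind the
package, and what the synthetic experiments do and do not demonstrate.

## Data model and conventions

A hypercube is a 3-D array indexed `(x, y, λ)`: scan step, line pixel,
spectral channel; 0-based everywhere. Wavelengths are a strictly
increasing vector in nm and are mandatory metadata. On disk, cubes and
label rasters use the plain ENVI header + raw-binary pair (BSQ/BIL/BIP
interleaves; `lines = x`, `samples = y`, `bands = λ`); reference
libraries and label legends are JSON sidecars. Normalized cubes are
stored as 32-bit floats; simulated raw counts live on a 16-bit-like full
scale (the numeric type of real camera data is an instrument detail the
simulator does not commit to — the float "counts" are written as uint16
only on request). The label vocabulary is fixed at 19: chart colors 0–17
plus background 18.

## Preprocessing

* **Normalization** `I_n = (I − I_dark)/(I_white − I_dark)`, clipped to
  [0, 1]. Clipping (rather than rejection) handles specular out-of-range
  pixels; pixels where `white ≤ dark` are set to 0 and their fraction is
  recorded in the cube metadata.
* **Median filter**: 7×7, applied to each 2-D `(y, λ)` slice with
  reflective (symmetric) edge padding. The per-slice domain is the only
  choice that behaves identically online (one slice at a time) and
  offline; a per-band spatial filter would need future scan steps.
* **Binning**: the spectral axis is partitioned into 121 contiguous
  index ranges whose lengths differ by at most one (longer ranges
  first), and each output sample is the range mean. Averaging, not
  decimation: it reduces noise and preserves the spectrum's mean when
  the ranges are equal. Upsampling is refused.
* **Wrapping**: row-major, sample `k → (k // 11, k mod 11)`; exactly
  invertible. Any fixed bijection would serve the purpose of giving the
  2-D convolution access to spectral correlations; row-major is the
  documented, tested one.
* Order of operations is normalize → median → bin → wrap, fixed and
  tested as a composition.

## Classifiers

All families consume the same 121-sample binned spectra, for
comparability.

* **Pearson matching**: sample correlation (the `1/(N−1)` z-score form)
  of the pixel spectrum against each library spectrum; highest
  coefficient wins, ties break to the lowest class index. A
  zero-variance spectrum, or a winning ρ below 0.5 (configurable), is
  background.
* **Supervised unmixing**: non-negative least squares of the spectrum
  against the 18 reference spectra. Non-negativity is enforced;
  sum-to-one is not, because illumination variation rescales the whole
  spectrum and a sum constraint would push that scale into the wrong
  endmembers. Label = argmax abundance; a winning abundance below 0.2
  (configurable) is background.
* **Unsupervised unmixing**: NMF with multiplicative updates. Randomly
  initialized NMF is rotation-ambiguous — in testing its impure
  endmembers made the subsequent correlation matching flip between
  similar colors — so the factorization is initialized with the
  classical successive-projection pure-pixel heuristic (the k mutually
  most extreme pixels, plus their NNLS abundances) and then refined.
  Discovered endmembers are matched to library classes by maximum
  Pearson correlation.
* **SVM**: one-vs-one multi-class with `k(k−1)/2` pairwise RBF
  classifiers (scikit-learn SVC, `C = 10`, `gamma = "scale"`); the
  kernel is unspecified upstream, RBF is the standard default.
* **Pixel-wise CNN**: 2 conv (32 and 64 filters, 3×3, valid) + 2 fully
  connected (128, 19), ReLU throughout, 40% dropout after fc1, L2
  coefficient 1e-4, momentum 0.9 — filter counts, momentum and L2 are
  implementation defaults, all configurable. The fully connected stages
  are expressed as valid convolutions, so the whole network is four
  convolutions over the 11×11 patch. Training: mini-batch 100, learning
  rate 0.001, up to 900 epochs, early stopping with patience 20 (and
  best-state restore) on the per-epoch validation misclassification rate
  `argmax E ≠ argmax R`. Loss is cross-entropy on one-hot labels — the
  canonical softmax pairing. The engine is plain numpy (im2col
  convolution, exact gradients verified against finite differences in
  the tests); no autodiff framework is involved.
* **Slice-wise CNN**: 4 conv (same-padded 3×3) with max-pooling along
  the spectral axis only, then two fully connected stages applied per
  line pixel (a spectral-extent convolution followed by 1×1), emitting
  one 19-way decision per pixel of the line. Per-pixel output was chosen
  over one-label-per-slice because the variant is meant to be accuracy-
  comparable with the pixel-wise network.
* **Background class**: a softmax cannot emit an untrained label, so
  background exemplars are synthesized at training-set assembly from
  dark spectra, impulse (cladding-like) spectra and 50/50 color
  mixtures; grayscale chart squares also carry the background label.

## Evaluation

`ACC_av = (1 − Σ max_L |E_L − R_L| / N) × 100`, computed literally via
one-hot encoding (the per-pixel `max_L` of the absolute one-hot
difference is 1 exactly when the labels differ) and verified against the
naive disagreement count on random instances. The 19×19 confusion matrix
and per-slice timing (mean/median/max seconds, fps = 1/mean) accompany
it. Timing is hardware-dependent and is never asserted against published
figures. The reference-image path for real acquisitions (affine
co-registration, panoramic stitching) is out of scope; for synthetic
data the simulator knows the geometry exactly, and a majority-vote
block downsampler (ties to the lowest label) stands in for the
unspecified downsampling kernel.

## The simulator: what it emulates, and what it does not

Defaults, chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| cube shape | (50, 512, 1209) | scan steps × line pixels × channels per 4-square section |
| wavelength span | 400–750 nm | illumination span of the lamp |
| noise_sd | 0.01 | Gaussian read noise, fraction of the count full scale |
| artifact_fraction | 0.01 | salt-and-pepper impulse fraction (cladding stand-in) |
| mismatch_sd | 0.02 | smooth relative deviation between gold library and chart paint |
| bias, slope | N(0.1, 0.04), N(0.01, 0.03) | illumination-field draws during augmentation |
| under-illumination prob. | 0.7 | probability the drawn field is applied as a reduction |
| tube distance factor | 1.15 | relative working distance at the lumen center |
| tube blur σ_max | 2.0 px | boundary blur width at maximum distance |

The 18 reference spectra are synthesized (the chart's published
reflectances are not reproduced): a baseline plus blue/green/red Gaussian
bumps with amplitudes guided by each class's display RGB, a warm-color
NIR tail, and a seeded per-class jitter; pairwise correlations are kept
below 0.99 by deterministic re-jittering. The gold library and the paint
actually rendered on the chart differ by a fixed smooth per-class warp
(`mismatch_sd`), seeded per class independently of the render seed —
emulating that real reference spectra come from a second spectrometer
and never match the imaging instrument exactly.

**Augmentation** multiplies a normalized base cube by
`1 + sign_b·b + sign_s·s·u` along the line coordinate `u ∈ [0, 1]` —
illumination scales reflected intensity rather than offsetting it (an
additive reading was tried first and rejected: no physical illumination
process shifts reflectance by a constant, and the offset systematically
breaks intercept-free NNLS unmixing). Signs are negative with
probability 0.7, the stated bias toward under-illuminated endoscopy
scenes. Every draw is logged in a manifest so the empirical moments are
recoverable; the acceptance script recomputes them.

**Tube geometry.** The working-distance profile rises monotonically from
the line edges to the lumen center (`1 + (f_max − 1)·cos²`), intensity
falls with the inverse square of the distance factor, and square
boundaries are blurred along `y` with a Gaussian whose σ grows linearly
with distance (schedule logged in the cube metadata). The default depth
is deliberately mild (`f_max = 1.15`, ≈ 24% darkening at the center):
the scene is an extended, statically and externally illuminated
Lambertian surface, whose image irradiance is to first order independent
of working distance — the residual fall-off models oblique-incidence
vignetting, and the dominant degradation in a lumen is boundary color
blending, not darkness. The white reference is always rendered at the
planar reference geometry, as a flat calibration target cannot follow
the lumen wall.

Not emulated: fiber-bundle honeycomb structure beyond impulse noise,
spectrograph optics and the merging of multiple center-wavelength
acquisitions, co-registration error between the wide-field camera and
the spectral line, specularities, and tissue reflectance. Consequently
the synthetic task is *cleaner* than the real one: with the default
noise levels every trained classifier operates near its ceiling, so the
end-to-end tests demonstrate that the pipeline is correct and that the
qualitative relationships hold (the CNN is never beaten, the family
ordering is non-strict, tube costs at most a few points), not that the
absolute error rates of real acquisitions are reproduced — those are
driven by the physical effects listed above.

## Numerical choices and degenerate inputs

* Ties: argmax everywhere takes the lowest index (Pearson, abundances,
  softmax, majority downsampling).
* `white ≤ dark` calibration pixels are zeroed and flagged, never
  divided.
* Augmented cubes are floored at 0 (reflectance cannot be negative);
  over-illuminated values may slightly exceed 1 and are tolerated
  downstream.
* The NMF stand-in uses `tol = 1e-9` with a fixed iteration cap;
  reconstruction error is non-increasing in the cap, which the tests
  assert.
* Cross-validation folds are assigned per *base measurement*: every
  augmented copy lands in the same fold as its source cube, so no
  augmented twin of a validation cube can leak into training. Groups are
  dealt round-robin after a seeded shuffle; fold sizes differ by at most
  one group.
* Problem sizes in the test suite are reduced renderings of the same
  protocol — (50, 128, 605) cubes, 60 augmented copies, ~100 sampled
  pixels per cube — chosen so the full suite runs on one CPU core in a
  few minutes; the pipeline is size-agnostic and the defaults render the
  full (50, 512, 1209) protocol.

## Known limitations

* The chart-section layout tiles the 4×6 chart into six 2×2 blocks, so
  the bottom-row sections contain grayscale squares (labeled
  background) rather than four colors each; the upstream sectioning of
  the physical chart is not described precisely enough to reproduce.
* The slice-wise CNN shares the training contract but has received less
  empirical attention than the pixel-wise network, mirroring its role as
  the weaker alternative.
* fps figures depend entirely on the host; only their decomposition
  (preprocessing dominates) is expected to transfer.
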