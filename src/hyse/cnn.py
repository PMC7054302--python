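"""Pixel-wise and slice-wise convolutional classifiers.

The pixel-wise network is the central method: each pixel's 121-sample
binned spectrum, wrapped into an 11×11 patch, passes through two
convolutional layers and two fully connected layers (ReLU throughout), a
40% dropout and L2 regularization, and a 19-way softmax decision layer —
18 chart colors plus a background class for spectra matching none of them.
Training is mini-batch momentum SGD on one-hot labels with cross-entropy;
the per-epoch validation statistic is the misclassification rate
(argmax of the prediction differs from the argmax of the reference), which
also drives patience-based early stopping.

The slice-wise variant consumes a whole 2-D spatial-spectral slice
(line pixels × 121 binned channels) through four convolutional layers with
max-pooling along the spectral axis and two fully connected stages applied
per line pixel, emitting one 19-way decision per pixel of the line.

The background class is an ordinary trained output: a softmax cannot emit
an untrained label, so background exemplars (dark pixels, impulse
artifacts, 50/50 color mixtures) are synthesized at training-set assembly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .types import N_LABELS

PATCH_SIDE = 11


@dataclass
class CnnArchitecture:
    """Layer plan shared by both variants.

    ``conv_layers`` is a list of (n_filters, kernel_size); ``fc_layers`` the
    fully connected widths, the last of which must equal ``n_outputs``. The
    filter counts and sizes are implementation defaults (configurable), the
    layer structure itself is fixed per variant: 2 conv + 2 fc for the
    pixel-wise network, 4 conv + 2 fc with max-pooling for the slice-wise
    network.
    """

    conv_layers: list[tuple[int, int]] = field(default_factory=lambda: [(32, 3), (64, 3)])
    fc_layers: list[int] = field(default_factory=lambda: [128, N_LABELS])
    dropout_rate: float = 0.40
    l2_coefficient: float = 1e-4
    n_outputs: int = N_LABELS


def slice_architecture() -> CnnArchitecture:
    return CnnArchitecture(
        conv_layers=[(16, 3), (16, 3), (32, 3), (32, 3)],
        fc_layers=[64, N_LABELS],
    )


@dataclass
class TrainingConfig:
    batch_size: int = 100
    learning_rate: float = 0.001
    momentum: float = 0.9
    max_epochs: int = 900
    patience: int = 20
    min_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainingLog:
    losses: list[float]
    val_errors: list[float]
    stopped_epoch: int
    early_stopped: bool


@dataclass
class ClassificationResult:
    """Per-slice prediction: labels, optional softmax probabilities, timing."""

    labels: np.ndarray
    probabilities: np.ndarray | None
    per_slice_time: float


class PixelCnn:
    """The patch-input pixel-wise CNN (2 conv + 2 fc, 19-way softmax)."""

    family = "cnn_pixel"

    def __init__(self, arch: CnnArchitecture, seed: int = 0) -> None:
        if len(arch.conv_layers) != 2 or len(arch.fc_layers) != 2:
            raise ValueError(
                "pixel-wise architecture must have exactly 2 convolutional "
                "and 2 fully connected layers"
            )
        if arch.fc_layers[-1] != arch.n_outputs:
            raise ValueError("final fully connected width must equal n_outputs")
        self.arch = arch
        self.seed = seed
        self.trained = False
        rng = np.random.default_rng(seed)
        (c1, k1), (c2, k2) = arch.conv_layers
        side = PATCH_SIDE - (k1 - 1) - (k2 - 1)
        if side < 1:
            raise ValueError("kernels too large for an 11x11 patch")
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.net = nn.Sequential(
            [
                nn.Conv2D(1, c1, (k1, k1), rng),
                nn.ReLU(),
                nn.Conv2D(c1, c2, (k2, k2), rng),
                nn.ReLU(),
                # fc1 expressed as a valid convolution over the remaining extent
                nn.Conv2D(c2, arch.fc_layers[0], (side, side), rng),
                nn.ReLU(),
                nn.Dropout(arch.dropout_rate, self._dropout_rng),
                nn.Conv2D(arch.fc_layers[0], arch.fc_layers[1], (1, 1), rng),
            ]
        )

    # -- inference -------------------------------------------------------
    def forward_probs(self, patches: np.ndarray, train: bool = False) -> np.ndarray:
        """Softmax probabilities, shape (n, n_outputs); patches (n, 11, 11)."""
        x = np.asarray(patches, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        logits = self.net.forward(x[:, None, :, :], train=train)
        return nn.softmax(logits, axis=1)[:, :, 0, 0]

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.forward_probs(patches).argmax(axis=1)

    def classify_slice(self, patches: np.ndarray) -> ClassificationResult:
        """Classify one prepared slice (list/array of patches) with timing."""
        if not self.trained:
            raise RuntimeError("model must be trained before classification")
        arr = _patches_to_array(patches)
        t0 = time.perf_counter()
        probs = self.forward_probs(arr)
        labels = probs.argmax(axis=1)
        elapsed = time.perf_counter() - t0
        return ClassificationResult(labels, probs, elapsed)

    # -- training --------------------------------------------------------
    def fit(
        self,
        patches: np.ndarray,
        labels: np.ndarray,
        config: TrainingConfig | None = None,
        val_patches: np.ndarray | None = None,
        val_labels: np.ndarray | None = None,
    ) -> TrainingLog:
        config = config or TrainingConfig()
        x = np.asarray(patches, dtype=np.float64)[:, None, :, :]
        y = _check_labels(labels, self.arch.n_outputs)[:, None, None]
        log = _train_network(
            self.net,
            x,
            y,
            config,
            self.arch.l2_coefficient,
            None if val_patches is None else np.asarray(val_patches)[:, None, :, :],
            None if val_labels is None else _check_labels(val_labels, self.arch.n_outputs)[:, None, None],
        )
        self.trained = True
        return log

    # -- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path: str) -> "PixelCnn":
        return load_model(path, expected_family=cls.family)


class SliceCnn:
    """Slice-input CNN: 4 conv + 2 fc with spectral max-pooling, per-pixel output."""

    family = "cnn_slice"

    def __init__(self, arch: CnnArchitecture | None = None, seed: int = 0, n_bins: int = 121) -> None:
        arch = arch or slice_architecture()
        if len(arch.conv_layers) != 4 or len(arch.fc_layers) != 2:
            raise ValueError(
                "slice-wise architecture must have exactly 4 convolutional "
                "and 2 fully connected layers"
            )
        if arch.fc_layers[-1] != arch.n_outputs:
            raise ValueError("final fully connected width must equal n_outputs")
        self.arch = arch
        self.seed = seed
        self.n_bins = n_bins
        self.trained = False
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        layers: list[nn.Layer] = []
        in_ch = 1
        spectral = n_bins
        for n_filters, k in arch.conv_layers:
            layers += [nn.Conv2D(in_ch, n_filters, (k, k), rng, padding="same"), nn.ReLU()]
            if spectral // 2 >= 4:  # pool along the spectral axis only
                layers.append(nn.MaxPool2D((1, 2)))
                spectral //= 2
            in_ch = n_filters
        # fc stages applied per line pixel: span the remaining spectral extent
        layers += [
            nn.Conv2D(in_ch, arch.fc_layers[0], (1, spectral), rng),
            nn.ReLU(),
            nn.Dropout(arch.dropout_rate, self._dropout_rng),
            nn.Conv2D(arch.fc_layers[0], arch.fc_layers[1], (1, 1), rng),
        ]
        self.net = nn.Sequential(layers)

    def forward_probs(self, slices: np.ndarray, train: bool = False) -> np.ndarray:
        """(batch, y, n_bins) binned slices → probabilities (batch, K, y)."""
        x = np.asarray(slices, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        logits = self.net.forward(x[:, None, :, :], train=train)
        return nn.softmax(logits, axis=1)[:, :, :, 0]

    def predict(self, slices: np.ndarray) -> np.ndarray:
        """Per-pixel labels for each slice: (batch, y)."""
        return self.forward_probs(slices).argmax(axis=1)

    def classify_slice(self, binned_slice: np.ndarray) -> ClassificationResult:
        if not self.trained:
            raise RuntimeError("model must be trained before classification")
        t0 = time.perf_counter()
        probs = self.forward_probs(np.asarray(binned_slice)[None])[0]
        labels = probs.argmax(axis=0)
        elapsed = time.perf_counter() - t0
        return ClassificationResult(labels, probs.T, elapsed)

    def fit(
        self,
        slices: np.ndarray,
        labels: np.ndarray,
        config: TrainingConfig | None = None,
        val_slices: np.ndarray | None = None,
        val_labels: np.ndarray | None = None,
    ) -> TrainingLog:
        """``slices``: (n, y, n_bins); ``labels``: per-pixel (n, y)."""
        config = config or TrainingConfig()
        x = np.asarray(slices, dtype=np.float64)[:, None, :, :]
        y = _check_labels(labels, self.arch.n_outputs)[:, :, None]
        log = _train_network(
            self.net,
            x,
            y,
            config,
            self.arch.l2_coefficient,
            None if val_slices is None else np.asarray(val_slices)[:, None, :, :],
            None if val_labels is None else _check_labels(val_labels, self.arch.n_outputs)[:, :, None],
        )
        self.trained = True
        return log


def build_pixel_cnn(arch: CnnArchitecture | None = None, seed: int = 0) -> PixelCnn:
    return PixelCnn(arch or CnnArchitecture(), seed)


def build_slice_cnn(
    arch: CnnArchitecture | None = None, seed: int = 0, n_bins: int = 121
) -> SliceCnn:
    return SliceCnn(arch, seed, n_bins)


def _check_labels(labels: np.ndarray, n_outputs: int) -> np.ndarray:
    y = np.asarray(labels)
    if y.min() < 0 or y.max() >= n_outputs:
        raise ValueError(f"labels must lie in 0..{n_outputs - 1}")
    return y.astype(np.int64)


def _patches_to_array(patches) -> np.ndarray:
    from .preprocess import SpectralPatch

    if isinstance(patches, np.ndarray):
        return patches
    return np.stack(
        [p.patch if isinstance(p, SpectralPatch) else np.asarray(p) for p in patches]
    )


def _train_network(
    net: nn.Sequential,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    l2: float,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
) -> TrainingLog:
    rng = np.random.default_rng(config.seed)
    opt = nn.MomentumSGD(net.params(), config.learning_rate, config.momentum, l2)
    n = x.shape[0]
    losses: list[float] = []
    val_errors: list[float] = []
    best_err = np.inf
    best_state: list[np.ndarray] | None = None
    since_best = 0
    early = False
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            net.zero_grad()
            logits = net.forward(x[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss + nn.l2_penalty(net.params(), l2)
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
        if x_val is not None and y_val is not None:
            err = _misclassification_rate(net, x_val, y_val)
            val_errors.append(err)
            if err < best_err - config.min_delta:
                best_err = err
                best_state = [p.value.copy() for p in net.params()]
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    early = True
                    break
    if best_state is not None:
        for p, v in zip(net.params(), best_state):
            p.value[...] = v
    return TrainingLog(losses, val_errors, epoch, early)


def _misclassification_rate(
    net: nn.Sequential, x: np.ndarray, y: np.ndarray, batch: int = 512
) -> float:
    """The monitored statistic: fraction of argmax(E) != argmax(R)."""
    wrong = 0
    total = 0
    for start in range(0, x.shape[0], batch):
        logits = net.forward(x[start : start + batch], train=False)
        pred = logits.argmax(axis=1)
        ref = y[start : start + batch]
        wrong += int((pred != ref).sum())
        total += ref.size
    return wrong / max(total, 1)


# ---------------------------------------------------------------------------
# persistence: single .npz container with a JSON architecture header
# ---------------------------------------------------------------------------

def save_model(model: "PixelCnn | SliceCnn", path: str) -> None:
    header = {
        "family": model.family,
        "seed": model.seed,
        "trained": model.trained,
        "arch": {
            "conv_layers": [list(c) for c in model.arch.conv_layers],
            "fc_layers": list(model.arch.fc_layers),
            "dropout_rate": model.arch.dropout_rate,
            "l2_coefficient": model.arch.l2_coefficient,
            "n_outputs": model.arch.n_outputs,
        },
    }
    if isinstance(model, SliceCnn):
        header["n_bins"] = model.n_bins
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.net.params())}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_model(path: str, expected_family: str | None = None):
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        arch = CnnArchitecture(
            conv_layers=[tuple(c) for c in header["arch"]["conv_layers"]],
            fc_layers=list(header["arch"]["fc_layers"]),
            dropout_rate=header["arch"]["dropout_rate"],
            l2_coefficient=header["arch"]["l2_coefficient"],
            n_outputs=header["arch"]["n_outputs"],
        )
        if expected_family and header["family"] != expected_family:
            raise ValueError(f"checkpoint holds a {header['family']} model")
        if header["family"] == "cnn_pixel":
            model: PixelCnn | SliceCnn = PixelCnn(arch, header["seed"])
        else:
            model = SliceCnn(arch, header["seed"], header.get("n_bins", 121))
        for i, p in enumerate(model.net.params()):
            p.value[...] = data[f"param_{i}"]
    model.trained = bool(header["trained"])
    return model


# ---------------------------------------------------------------------------
# cross-validation fold machinery (augmentation-aware)
# ---------------------------------------------------------------------------

def make_folds(base_ids: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Partition pool indices into k folds keeping each base-cube group whole.

    Augmented cubes derived from the same base measurement land in the same
    fold as that base cube — the leakage guard for cross-validation. Groups
    are shuffled, then dealt round-robin so fold sizes differ by at most one
    group. Returns per-fold index arrays covering the pool exactly once.
    """
    base_ids = np.asarray(base_ids)
    groups = np.unique(base_ids)
    if k > len(groups):
        raise ValueError(f"cannot make {k} folds from {len(groups)} base-cube groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(groups)
    folds: list[list[int]] = [[] for _ in range(k)]
    for i, g in enumerate(order):
        folds[i % k].extend(np.flatnonzero(base_ids == g).tolist())
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def cross_validate(pool, k: int = 5, config: TrainingConfig | None = None, **harness_kwargs):
    """Five-fold cross-validation of the pixel-wise CNN over a training pool.

    Delegates dataset assembly and evaluation to the benchmark harness;
    returns one evaluation report per fold. ``pool`` is a
    :class:`hyse.simulate.TrainingPool`.
    """
    from .benchmark import evaluate_cnn_fold

    base_ids = np.array([c.base_id for c in pool.cubes])
    folds = make_folds(base_ids, k, seed=(config.seed if config else 0))
    reports = []
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(pool.cubes)), val_idx)
        reports.append(
            evaluate_cnn_fold(pool, train_idx, val_idx, config=config, **harness_kwargs)
        )
    return reports
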