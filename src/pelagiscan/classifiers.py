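"""The two-channel CNN and the classical SVM/HOG baselines.

The CNN has a *spatial* channel (2-D convolutions over the standardized RGB
image) and a *spectral* channel (1-D convolutions over the reflectance
signature).  Each channel is two stages of
``conv -> batch-norm -> ReLU -> 2x max-pool -> dropout``; their flattened
feature vectors are concatenated (in ``fused`` mode) and classified by a
dense head with a softmax output.  At the default geometry — 256x256x3
images, 8 then 16 spatial filters, length-200 signatures, 4 then 2 spectral
filters — the flattened channels carry 65,536 and 100 features.

Training: plain SGD (lr 0.05) on categorical cross-entropy, batch size 32,
with a stratified validation split and early stopping on validation loss.

Baselines: one-vs-rest linear SVMs on spectral signatures, raw pixels, HOG
descriptors, and concatenations thereof.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augment import Dataset
from .rgb import RGBImage

__all__ = [
    "CNNConfig",
    "TrainConfig",
    "HOGParams",
    "CNNModel",
    "TrainingHistory",
    "build_cnn",
    "train_cnn",
    "predict",
    "hog_features",
    "train_svm",
    "SVMBaseline",
]

MODES = ("spatial", "spectral", "fused")


@dataclass
class CNNConfig:
    """Architecture hyperparameters (defaults give 65,536 + 100 features)."""

    classes: tuple[str, ...] = ("c1", "c2", "c3", "c4", "c5")
    image_size: int = 256
    input_signature_length: int = 200
    spatial_filters: tuple[int, int] = (8, 16)
    spatial_kernel: int = 3
    spectral_filters: tuple[int, int] = (4, 2)
    spectral_kernel: int = 5
    dropout: float = 0.25
    hidden_units: int = 64

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if self.image_size % 4 != 0:
            raise ValueError("image size must survive two 2x pools")
        if self.input_signature_length % 4 != 0:
            raise ValueError("spectral length must survive two pools")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def spatial_flat_length(self) -> int:
        return (self.image_size // 4) ** 2 * self.spatial_filters[1]

    @property
    def spectral_flat_length(self) -> int:
        return (self.input_signature_length // 4) * self.spectral_filters[1]


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    learning_rate: float = 0.05
    batch_size: int = 32
    max_epochs: int = 4000
    patience: int = 50  # early stopping on validation loss
    val_fraction: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("validation fraction must be in (0, 1)")
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("all training parameters must be positive")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


class CNNModel:
    """An inspectable two-channel CNN; build via :func:`build_cnn`."""

    def __init__(self, cfg: CNNConfig, mode: str, seed: int = 0):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.cfg, self.mode = cfg, mode
        self.rng = np.random.default_rng(seed)
        k1, k2 = cfg.spatial_filters
        f1, f2 = cfg.spectral_filters
        self.spatial = None
        self.spectral = None
        if mode in ("spatial", "fused"):
            self.spatial = nn.Sequential([
                nn.Conv2D(3, k1, cfg.spatial_kernel, self.rng),
                nn.BatchNorm(k1),
                nn.ReLU(),
                nn.MaxPool2D(),
                nn.Dropout(cfg.dropout, self.rng),
                nn.Conv2D(k1, k2, cfg.spatial_kernel, self.rng),
                nn.BatchNorm(k2),
                nn.ReLU(),
                nn.MaxPool2D(),
                nn.Dropout(cfg.dropout, self.rng),
                nn.Flatten(),
            ])
        if mode in ("spectral", "fused"):
            self.spectral = nn.Sequential([
                nn.Conv1D(1, f1, cfg.spectral_kernel, self.rng),
                nn.BatchNorm(f1),
                nn.ReLU(),
                nn.MaxPool1D(),
                nn.Dropout(cfg.dropout, self.rng),
                nn.Conv1D(f1, f2, cfg.spectral_kernel, self.rng),
                nn.BatchNorm(f2),
                nn.ReLU(),
                nn.MaxPool1D(),
                nn.Dropout(cfg.dropout, self.rng),
                nn.Flatten(),
            ])
        self.head = nn.Sequential([
            nn.Dense(self.feature_length, cfg.hidden_units, self.rng),
            nn.ReLU(),
            nn.Dropout(cfg.dropout, self.rng),
            nn.Dense(cfg.hidden_units, cfg.n_classes, self.rng),
        ])

    # -- introspection ----------------------------------------------------
    @property
    def feature_length(self) -> int:
        total = 0
        if self.spatial is not None:
            total += self.cfg.spatial_flat_length
        if self.spectral is not None:
            total += self.cfg.spectral_flat_length
        return total

    def channel_output_shapes(self) -> dict[str, list[tuple[int, ...]]]:
        """Per-layer output shapes of each channel, from a dummy forward."""
        out = {}
        if self.spatial is not None:
            out["spatial"] = self.spatial.output_shapes(
                (3, self.cfg.image_size, self.cfg.image_size)
            )
        if self.spectral is not None:
            out["spectral"] = self.spectral.output_shapes(
                (1, self.cfg.input_signature_length)
            )
        return out

    def flatten_lengths(self) -> dict[str, int]:
        """Flattened feature-vector length per channel, read off layer shapes."""
        return {
            name: int(np.prod(shapes[-1]))
            for name, shapes in self.channel_output_shapes().items()
        }

    # -- forward / backward ----------------------------------------------
    def _all_layer_lists(self):
        lists = []
        if self.spatial is not None:
            lists.append(self.spatial.layers)
        if self.spectral is not None:
            lists.append(self.spectral.layers)
        lists.append(self.head.layers)
        return [layer for lst in lists for layer in lst]

    def forward(
        self, images: np.ndarray | None, signatures: np.ndarray | None, train: bool
    ) -> np.ndarray:
        feats = []
        if self.spatial is not None:
            feats.append(self.spatial.forward(images, train))
        if self.spectral is not None:
            feats.append(self.spectral.forward(signatures, train))
        self._split = [f.shape[1] for f in feats]
        x = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        chunks = np.split(dx, np.cumsum(self._split)[:-1], axis=1)
        branches = [b for b in (self.spatial, self.spectral) if b is not None]
        for branch, chunk in zip(branches, chunks):
            branch.backward(chunk)

    def sgd_step(self, lr: float) -> None:
        nn.sgd_step(self._all_layer_lists(), lr)

    def snapshot(self):
        return nn.collect_weights(self._all_layer_lists())

    def restore(self, snap) -> None:
        nn.restore_weights(self._all_layer_lists(), snap)

    # -- data marshalling --------------------------------------------------
    def inputs_from(self, ds: Dataset) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Extract (images, signatures) arrays in network layout.

        Images are scaled to [0, 1]; signatures are fed as-is (already
        reflectance).
        """
        images = signatures = None
        if self.spatial is not None:
            images = ds.images().astype(float).transpose(0, 3, 1, 2) / 255.0
            if images.shape[2] != self.cfg.image_size:
                raise ValueError("dataset image size does not match model config")
        if self.spectral is not None:
            signatures = ds.signatures()[:, np.newaxis, :].astype(float)
            if signatures.shape[2] != self.cfg.input_signature_length:
                raise ValueError("dataset signature length does not match model config")
        return images, signatures


def build_cnn(cfg: CNNConfig, mode: str = "fused", seed: int = 0) -> CNNModel:
    """Construct a :class:`CNNModel` in ``spatial``, ``spectral`` or
    ``fused`` mode with seeded He-normal initialization."""
    return CNNModel(cfg, mode, seed=seed)


def _onehot(labels: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out


def _batched_logits(model: CNNModel, images, signatures, n, chunk=256):
    parts = []
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        parts.append(
            model.forward(
                None if images is None else images[lo:hi],
                None if signatures is None else signatures[lo:hi],
                train=False,
            )
        )
    return np.concatenate(parts, axis=0)


def train_cnn(
    model: CNNModel, train: Dataset, cfg: TrainConfig | None = None
) -> tuple[CNNModel, TrainingHistory]:
    """Train with SGD + early stopping; restores the best-validation weights.

    A stratified ``val_fraction`` of the samples is held out for validation;
    training halts when the validation loss has not improved for
    ``patience`` consecutive epochs (or at ``max_epochs``) and the weights
    from the best epoch are restored.
    """
    from sklearn.model_selection import StratifiedShuffleSplit

    if cfg is None:
        cfg = TrainConfig()
    labels = train.labels()
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least 2 classes")
    splitter = StratifiedShuffleSplit(
        n_splits=1, test_size=cfg.val_fraction, random_state=cfg.seed % (2**32)
    )
    (tr_idx, va_idx), = splitter.split(np.zeros(len(labels)), labels)

    images, signatures = model.inputs_from(train)
    onehot = _onehot(labels, model.cfg.classes)

    def take(arr, idx):
        return None if arr is None else arr[idx]

    xi_tr, xs_tr, y_tr = take(images, tr_idx), take(signatures, tr_idx), onehot[tr_idx]
    xi_va, xs_va, y_va = take(images, va_idx), take(signatures, va_idx), onehot[va_idx]

    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    best_loss, best_snap, since_best = np.inf, model.snapshot(), 0
    n_tr = len(tr_idx)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n_tr)
        epoch_losses = []
        for lo in range(0, n_tr, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            logits = model.forward(take(xi_tr, sel), take(xs_tr, sel), train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_tr[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN loss at epoch {epoch}; aborting")
            model.backward(dlogits)
            model.sgd_step(cfg.learning_rate)
            epoch_losses.append(loss)
        val_logits = _batched_logits(model, xi_va, xs_va, len(va_idx))
        val_loss, _ = nn.softmax_cross_entropy(val_logits, y_va)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        if val_loss < best_loss - 1e-12:
            best_loss, since_best = val_loss, 0
            best_snap = model.snapshot()
            history.best_epoch = epoch
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    history.stopped_epoch = len(history.val_loss)
    model.restore(best_snap)
    return model, history


def predict(model: CNNModel, samples: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax probabilities for every sample.

    Dropout is inactive, so the output is deterministic for a fixed model;
    probability ties resolve to the lowest class index.
    """
    images, signatures = model.inputs_from(samples)
    logits = _batched_logits(model, images, signatures, len(samples))
    probs = nn.softmax(logits)
    idx = probs.argmax(axis=1)  # argmax picks the first (lowest) on ties
    labels = np.array([model.cfg.classes[i] for i in idx])
    return labels, probs


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------

@dataclass
class HOGParams:
    """Histogram-of-oriented-gradients parameters."""

    orientations: int = 8
    pixels_per_cell: tuple[int, int] = (16, 16)
    cells_per_block: tuple[int, int] = (4, 4)
    block_norm: str = "L2-Hys"


#: Rec. 601 luminance weights used for grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def hog_features(img: RGBImage, p: HOGParams | None = None) -> np.ndarray:
    """Block-normalized gradient-orientation histogram descriptor.

    The image is converted to grayscale with Rec. 601 luminance weights,
    then cell histograms are computed, block-normalized (stride one cell)
    and concatenated.  For the default parameters on a 256x256 image the
    descriptor has (16-4+1)^2 * 4*4*8 = 21,632 entries.
    """
    from skimage.feature import hog

    if p is None:
        p = HOGParams()
    h, w = img.pixels.shape[:2]
    cy, cx = p.pixels_per_cell
    by, bx = p.cells_per_block
    if h % cy or w % cx or h // cy < by or w // cx < bx:
        raise ValueError(
            f"image size {h}x{w} incompatible with cells {p.pixels_per_cell} "
            f"and blocks {p.cells_per_block}"
        )
    gray = img.pixels.astype(float) @ _LUMA / 255.0
    return hog(
        gray,
        orientations=p.orientations,
        pixels_per_cell=p.pixels_per_cell,
        cells_per_block=p.cells_per_block,
        block_norm=p.block_norm,
        feature_vector=True,
    )


def train_svm(features: np.ndarray, labels: np.ndarray, kernel: str = "linear"):
    """One-vs-rest linear SVM with default regularization (C = 1)."""
    from sklearn.svm import LinearSVC

    if kernel != "linear":
        raise ValueError("only the linear kernel is supported")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("SVM training requires at least 2 classes")
    clf = LinearSVC(C=1.0)
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


SVM_FEATURE_KINDS = ("spectral", "pixels", "pixels+spectral", "hog", "hog+spectral")


class SVMBaseline:
    """A linear-SVM baseline over one of the standard feature variants.

    ``spectral`` features are z-scored (scaler fitted on the training set);
    pixel and HOG features are used raw, with pixels pre-scaled to [0, 1].
    """

    def __init__(self, kind: str, hog_params: HOGParams | None = None):
        if kind not in SVM_FEATURE_KINDS:
            raise ValueError(f"kind must be one of {SVM_FEATURE_KINDS}")
        self.kind = kind
        self.hog_params = hog_params or HOGParams()
        self._scaler = None
        self._clf = None

    def _blocks(self, ds: Dataset) -> dict[str, np.ndarray]:
        blocks = {}
        if "spectral" in self.kind:
            blocks["spectral"] = ds.signatures()
        if "pixels" in self.kind:
            blocks["pixels"] = ds.images().reshape(len(ds), -1).astype(float) / 255.0
        if "hog" in self.kind:
            blocks["hog"] = np.stack(
                [hog_features(s.image, self.hog_params) for s in ds.samples]
            )
        return blocks

    def features(self, ds: Dataset, fit_scaler: bool = False) -> np.ndarray:
        from sklearn.preprocessing import StandardScaler

        blocks = self._blocks(ds)
        if "spectral" in blocks:
            if fit_scaler:
                self._scaler = StandardScaler().fit(blocks["spectral"])
            if self._scaler is not None:
                blocks["spectral"] = self._scaler.transform(blocks["spectral"])
        order = [k for k in ("hog", "pixels", "spectral") if k in blocks]
        return np.concatenate([blocks[k] for k in order], axis=1)

    def fit(self, ds: Dataset, seed: int = 0) -> "SVMBaseline":
        x = self.features(ds, fit_scaler=True)
        self._clf = train_svm(x, ds.labels())
        return self

    def predict(self, ds: Dataset) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("fit the baseline first")
        return self._clf.predict(self.features(ds))
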