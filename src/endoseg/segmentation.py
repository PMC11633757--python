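"""Semantic segmentation: chessboard patching, augmentation, model
construction, training and majority-vote tiled inference.

Mosaics are partitioned into square patches on a chessboard: patches of
"white" parity ((row + col) even) are reserved for testing, the others
for training, so train and test pixels never overlap spatially.  During
optimization, patches are augmented (perspective, rotation, flip,
contrast, brightness and a random cut slightly larger than the model
input, followed by a center crop).  At inference the mosaic is processed
``n_shifts`` times with slightly different tile positions and the final
per-pixel class is decided by majority vote across the shifts, which
suppresses grid artifacts; ties are broken by the highest accumulated
softmax score, then the lowest class index.

The full-scale UNet3+/VGG16 configuration is specified exactly in
:mod:`endoseg.architecture` for parameter accounting.  A reduced-width
variant with a trainable encoder (``width_factor < 1``) runs on the
package's numpy engine for desk-scale training; it is flagged and never
used for parameter-count checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from skimage import transform as sktf
from sklearn.base import BaseEstimator

from . import _nn
from .architecture import (
    BOTTLENECK_WIDTH,
    FUSION_CHANNELS,
    SKIP_CHANNELS,
    VGG16_BLOCKS,
    ModelSpec,
    ParameterCounts,
    parameter_counts,
)
from .images import AnnotationMask, MultimodalImage

__all__ = [
    "Patch",
    "PatchSet",
    "TrainConfig",
    "chessboard_split",
    "AugmentConfig",
    "augment",
    "SegmentationModel",
    "build_model",
    "train",
    "predict_tiled",
    "TiledSegmenter",
]


class Patch(NamedTuple):
    image: np.ndarray  # (3, p, p)
    labels: np.ndarray  # (p, p)
    position: tuple[int, int]  # (row, col) in the patch grid
    parity: int  # 0 = white/test, 1 = train


@dataclass
class PatchSet:
    patches: list[Patch]
    patch_px: int

    def __len__(self) -> int:
        return len(self.patches)


def chessboard_split(
    mosaic: MultimodalImage, labels: AnnotationMask, patch_px: int = 512
) -> tuple[PatchSet, PatchSet]:
    """Partition a mosaic into train/test patches by chessboard parity.

    The grid is anchored at the origin; white patches ((row + col) even)
    go to the test set, the others to training.  Partial border patches
    are dropped.  The two sets are disjoint and together cover every full
    patch.
    """
    if mosaic.shape != labels.shape:
        raise ValueError("mosaic and labels must share a pixel grid")
    h, w = mosaic.shape
    if h < patch_px or w < patch_px:
        raise ValueError(f"mosaic {mosaic.shape} smaller than one {patch_px}-px patch")
    train, test = [], []
    for i in range(h // patch_px):
        for j in range(w // patch_px):
            sl = np.s_[i * patch_px : (i + 1) * patch_px, j * patch_px : (j + 1) * patch_px]
            parity = (i + j) % 2
            patch = Patch(mosaic.data[(slice(None),) + sl], labels.labels[sl], (i, j), parity)
            (test if parity == 0 else train).append(patch)
    return PatchSet(train, patch_px), PatchSet(test, patch_px)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Probabilities and ranges of the joint image/label augmentations."""

    p_perspective: float = 0.3
    p_rotation: float = 0.5
    p_flip: float = 0.5
    p_contrast: float = 0.3
    p_brightness: float = 0.3
    max_angle_deg: float = 15.0
    perspective_jitter: float = 0.05
    contrast_range: tuple[float, float] = (0.8, 1.25)
    brightness_range: tuple[float, float] = (-0.1, 0.1)
    crop_px: int = 226
    out_px: int = 224
    random_cut: bool = True

    @classmethod
    def disabled(cls, crop_px: int = 226, out_px: int = 224) -> "AugmentConfig":
        """All probabilities zero and a deterministic center cut."""
        return cls(
            p_perspective=0, p_rotation=0, p_flip=0, p_contrast=0, p_brightness=0,
            crop_px=crop_px, out_px=out_px, random_cut=False,
        )

    @classmethod
    def scaled(cls, crop_px: int, out_px: int) -> "AugmentConfig":
        """Default augmentation protocol at a reduced patch/input size."""
        return cls(crop_px=crop_px, out_px=out_px)


def _warp_pair(image, labels, tf):
    warped = np.stack(
        [sktf.warp(ch, tf, order=1, mode="reflect", preserve_range=True) for ch in image]
    )
    lab = sktf.warp(
        labels.astype(float), tf, order=0, mode="reflect", preserve_range=True
    ).astype(labels.dtype)
    return warped, lab


def augment(
    image_patch: np.ndarray,
    label_patch: np.ndarray,
    seed: int,
    config: AugmentConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly augment an image/label patch and crop to the model input size.

    Geometric transforms (perspective, rotation, flip) are applied
    identically to image and labels (labels with nearest-neighbour
    interpolation); photometric transforms (contrast, brightness) to the
    image only.  A random ``crop_px`` cut is taken, then a center crop to
    ``out_px``.  Deterministic given ``seed``.
    """
    cfg = config or AugmentConfig()
    p = image_patch.shape[-1]
    if image_patch.shape[-2] != p or label_patch.shape != image_patch.shape[-2:]:
        raise ValueError("expected square image patch with matching label patch")
    if p < cfg.crop_px:
        raise ValueError(f"patch ({p} px) smaller than crop size ({cfg.crop_px} px)")
    rng = np.random.default_rng(seed)
    img = np.asarray(image_patch, dtype=float).copy()
    lab = np.asarray(label_patch).copy()

    if rng.random() < cfg.p_perspective:
        src = np.array([[0, 0], [0, p], [p, p], [p, 0]], dtype=float)
        dst = src + rng.uniform(-cfg.perspective_jitter * p, cfg.perspective_jitter * p, src.shape)
        tf = sktf.ProjectiveTransform.from_estimate(dst, src)
        if tf:
            img, lab = _warp_pair(img, lab, tf)
    if rng.random() < cfg.p_rotation:
        angle = rng.uniform(-cfg.max_angle_deg, cfg.max_angle_deg)
        img = np.stack(
            [sktf.rotate(ch, angle, order=1, mode="reflect", preserve_range=True) for ch in img]
        )
        lab = sktf.rotate(
            lab.astype(float), angle, order=0, mode="reflect", preserve_range=True
        ).astype(lab.dtype)
    if rng.random() < cfg.p_flip:
        axis = int(rng.integers(0, 2))
        img = np.flip(img, axis=axis + 1).copy()
        lab = np.flip(lab, axis=axis).copy()
    if rng.random() < cfg.p_contrast:
        gain = rng.uniform(*cfg.contrast_range)
        img = np.clip(img * gain, 0.0, 1.0)
    if rng.random() < cfg.p_brightness:
        img = np.clip(img + rng.uniform(*cfg.brightness_range), 0.0, 1.0)

    # random cut of crop_px, then center crop to out_px
    if cfg.random_cut:
        r = int(rng.integers(0, p - cfg.crop_px + 1))
        c = int(rng.integers(0, p - cfg.crop_px + 1))
    else:
        r = c = (p - cfg.crop_px) // 2
    img = img[:, r : r + cfg.crop_px, c : c + cfg.crop_px]
    lab = lab[r : r + cfg.crop_px, c : c + cfg.crop_px]
    off = (cfg.crop_px - cfg.out_px) // 2
    img = img[:, off : off + cfg.out_px, off : off + cfg.out_px]
    lab = lab[off : off + cfg.out_px, off : off + cfg.out_px]
    return img, lab


def center_crop(image: np.ndarray, labels: np.ndarray, out_px: int):
    """Deterministic center crop of an image/label pair."""
    p = labels.shape[-1]
    off = (p - out_px) // 2
    return (
        image[:, off : off + out_px, off : off + out_px],
        labels[off : off + out_px, off : off + out_px],
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class _ReducedUNet3Plus:
    """Trainable reduced-width UNet3+ on the numpy engine.

    Mirrors the full-scale topology — encoder taps, pooled bottleneck,
    full-scale skip connections with fused decoder stages, 1x1 softmax
    head — with all widths scaled by ``width_factor`` and a single
    convolution per encoder stack.  The encoder is trainable by default;
    ``freeze_encoder=True`` substitutes a seeded random frozen encoder.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0, freeze_encoder: bool = False):
        self.spec = spec
        self.seed = seed
        n = spec.n_stacks
        wf = spec.width_factor
        scale = lambda w, lo: max(lo, int(round(w * wf)))
        self.tap_widths = [scale(w, 4) for w, _ in VGG16_BLOCKS[:n]]
        self.skip = scale(SKIP_CHANNELS, 4)
        self.fusion = scale(FUSION_CHANNELS, 8)
        self.bott = scale(BOTTLENECK_WIDTH, 8)
        if spec.input_px % (2**n) != 0:
            raise ValueError(f"input_px must be divisible by {2**n}")
        rng = np.random.default_rng(seed)
        P = {}
        cin = 3
        for i, w in enumerate(self.tap_widths):
            P[f"enc{i}_w"] = _nn.Param(_nn.he_init(rng, (w, cin, 3, 3)), trainable=not freeze_encoder)
            P[f"enc{i}_b"] = _nn.Param(np.zeros(w), trainable=not freeze_encoder)
            cin = w
        P["bott_w"] = _nn.Param(_nn.he_init(rng, (self.bott, cin, 3, 3)))
        P["bott_b"] = _nn.Param(np.zeros(self.bott))
        dec_chan = {}
        for j in range(n - 1, -1, -1):
            srcs = self._sources(j)
            for idx, (_, _, c) in enumerate(srcs):
                P[f"de{j}_s{idx}_w"] = _nn.Param(_nn.he_init(rng, (self.skip, c, 3, 3)))
                P[f"de{j}_s{idx}_b"] = _nn.Param(np.zeros(self.skip))
            agg = self.skip * len(srcs)
            P[f"de{j}_f_w"] = _nn.Param(_nn.he_init(rng, (self.fusion, agg, 3, 3)))
            P[f"de{j}_f_b"] = _nn.Param(np.zeros(self.fusion))
            dec_chan[j] = self.fusion
        P["head_w"] = _nn.Param(_nn.he_init(rng, (spec.n_classes, self.fusion, 1, 1)))
        P["head_b"] = _nn.Param(np.zeros(spec.n_classes))
        self.params = P
        self.trained_ = False

    def _sources(self, j: int):
        """(origin, level, channels) feeding decoder stage j."""
        n = self.spec.n_stacks
        srcs = [("enc", lev, self.tap_widths[lev]) for lev in range(j + 1)]
        srcs += [("dec", lev, self.fusion) for lev in range(j + 1, n)]
        srcs += [("bott", n, self.bott)]
        return srcs

    def forward(self, x: np.ndarray) -> _nn.Var:
        P = self.params
        n = self.spec.n_stacks
        v = _nn.Var(x)
        enc = []
        for i in range(n):
            v = _nn.relu(_nn.conv2d(v, P[f"enc{i}_w"], P[f"enc{i}_b"]))
            enc.append(v)
            v = _nn.maxpool2(v)
        bott = _nn.relu(_nn.conv2d(v, P["bott_w"], P["bott_b"]))
        nodes = {n: bott}
        for lev, e in enumerate(enc):
            nodes[("enc", lev)] = e
        dec = {}
        for j in range(n - 1, -1, -1):
            branches = []
            for idx, (origin, lev, _) in enumerate(self._sources(j)):
                src = {"enc": nodes.get(("enc", lev)), "dec": dec.get(lev), "bott": nodes[n]}[origin]
                steps = lev - j
                t = src
                for _ in range(max(steps, 0)):
                    t = _nn.upsample2(t)
                for _ in range(max(-steps, 0)):
                    t = _nn.maxpool2(t)
                branches.append(_nn.relu(_nn.conv2d(t, P[f"de{j}_s{idx}_w"], P[f"de{j}_s{idx}_b"])))
            fused = _nn.relu(_nn.conv2d(_nn.concat(branches), P[f"de{j}_f_w"], P[f"de{j}_f_b"]))
            dec[j] = fused
        return _nn.conv2d(dec[0], P["head_w"], P["head_b"])

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Softmax class scores for a (N, 3, input_px, input_px) batch."""
        return _nn.softmax(self.forward(np.asarray(batch, dtype=float)).value)

    def parameter_list(self) -> list[_nn.Param]:
        return list(self.params.values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: p.value.copy() for k, p in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.value = weights[k].copy()


@dataclass
class SegmentationModel:
    """Model handle: specification, parameter counts and (for the desk-scale
    variant) the trainable network."""

    spec: ModelSpec
    counts: ParameterCounts
    network: _ReducedUNet3Plus | None = None
    history: dict | None = None

    @property
    def input_px(self) -> int:
        return self.spec.input_px

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    @property
    def is_trained(self) -> bool:
        return self.network is not None and self.network.trained_


def build_model(spec: ModelSpec, seed: int = 0, freeze_encoder: bool = False) -> SegmentationModel:
    """Instantiate a model for ``spec`` and report its parameter counts.

    The full-scale configuration (``width_factor = 1``) is represented by
    its exact layer graph — the counts are the architecture's; its weights
    are not materialized here.  A ``width_factor < 1`` builds the reduced
    desk-scale network (trainable; counts reflect the reduced graph and
    are never compared to the full-scale budget).
    """
    if spec.desk_scale:
        net = _ReducedUNet3Plus(spec, seed=seed, freeze_encoder=freeze_encoder)
        trainable = sum(p.value.size for p in net.parameter_list() if p.trainable)
        frozen = sum(p.value.size for p in net.parameter_list() if not p.trainable)
        counts = ParameterCounts(total=trainable + frozen, trainable=trainable, frozen=frozen)
        return SegmentationModel(spec=spec, counts=counts, network=net)
    return SegmentationModel(spec=spec, counts=parameter_counts(spec), network=None)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings (defaults are the full-scale protocol)."""

    epochs: int = 400
    patience: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-5
    n_val_tiles: int = 50
    seed: int = 0
    augment: AugmentConfig | None = None
    steps_per_epoch: int | None = None

    def __post_init__(self) -> None:
        if min(self.epochs, self.patience, self.batch_size, self.n_val_tiles) <= 0:
            raise ValueError("epochs, patience, batch_size and n_val_tiles must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


def train(model: SegmentationModel, train_set: PatchSet, config: TrainConfig) -> SegmentationModel:
    """Train a desk-scale model with Adam, sparse categorical cross-entropy,
    a held-out validation split and early stopping on the validation loss.

    ``config.n_val_tiles`` patches are reserved for validation; training
    stops at ``epochs`` or once the validation loss has not improved for
    ``patience`` consecutive epochs, and the best-validation weights are
    restored.  Per-epoch train/val losses are recorded in
    ``model.history``.
    """
    if model.network is None:
        raise ValueError("training requires a desk-scale model (width_factor < 1)")
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if config.n_val_tiles >= len(train_set):
        raise ValueError(
            f"validation split ({config.n_val_tiles}) must be smaller than "
            f"the training set ({len(train_set)})"
        )
    net = model.network
    in_px = model.input_px
    aug_cfg = config.augment or AugmentConfig.scaled(
        crop_px=min(in_px + 2, train_set.patch_px), out_px=in_px
    )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(train_set))
    val_idx = order[: config.n_val_tiles]
    fit_idx = order[config.n_val_tiles :]
    val = [center_crop(train_set.patches[i].image, train_set.patches[i].labels, in_px)
           for i in val_idx]
    opt = _nn.Adam(net.parameter_list(), lr=config.learning_rate)

    def _val_loss() -> float:
        total = 0.0
        for img, lab in val:
            logits = net.forward(img[None])
            total += float(_nn.softmax_cross_entropy(logits, lab[None]).value)
        return total / len(val)

    history = {"train_loss": [], "val_loss": []}
    best_loss, best_weights, wait = np.inf, None, 0
    for epoch in range(config.epochs):
        epoch_rng = np.random.default_rng([config.seed, epoch])
        if config.steps_per_epoch is not None:
            # oversample small patch sets so every epoch takes the
            # configured number of gradient steps
            idx = epoch_rng.choice(fit_idx, size=config.steps_per_epoch * config.batch_size)
        else:
            idx = epoch_rng.permutation(fit_idx)
        losses = []
        for start in range(0, len(idx), config.batch_size):
            batch_idx = idx[start : start + config.batch_size]
            imgs, labs = [], []
            for i in batch_idx:
                patch = train_set.patches[i]
                im, la = augment(
                    patch.image, patch.labels,
                    seed=int(epoch_rng.integers(2**31)), config=aug_cfg,
                )
                imgs.append(im)
                labs.append(la)
            logits = net.forward(np.stack(imgs))
            loss = _nn.softmax_cross_entropy(logits, np.stack(labs))
            opt.zero_grad()
            _nn.backward(loss)
            opt.step()
            losses.append(float(loss.value))
        vloss = _val_loss()
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(vloss)
        if vloss < best_loss:
            best_loss, best_weights, wait = vloss, net.get_weights(), 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_weights is not None:
        net.set_weights(best_weights)
    net.trained_ = True
    model.history = history
    return model


# ---------------------------------------------------------------------------
# Tiled inference with majority voting
# ---------------------------------------------------------------------------

def _predict_shift(net, mosaic: np.ndarray, offset: tuple[int, int], batch: int = 16):
    """Class scores for one tile-grid offset, reflect-padded to full cover."""
    in_px = net.spec.input_px
    _, h, w = mosaic.shape
    oy, ox = offset
    ph = int(np.ceil((h + oy) / in_px)) * in_px
    pw = int(np.ceil((w + ox) / in_px)) * in_px
    padded = np.pad(mosaic, ((0, 0), (oy, ph - h - oy), (ox, pw - w - ox)), mode="reflect")
    tiles, slots = [], []
    for r in range(0, ph, in_px):
        for c in range(0, pw, in_px):
            tiles.append(padded[:, r : r + in_px, c : c + in_px])
            slots.append((r, c))
    scores = np.zeros((net.spec.n_classes, ph, pw))
    for start in range(0, len(tiles), batch):
        chunk = np.stack(tiles[start : start + batch])
        probs = net.predict_proba(chunk)
        for p, (r, c) in zip(probs, slots[start : start + batch]):
            scores[:, r : r + in_px, c : c + in_px] = p
    return scores[:, oy : oy + h, ox : ox + w]


def predict_tiled(
    model: SegmentationModel,
    mosaic: MultimodalImage,
    n_shifts: int = 20,
    seed: int = 0,
    offsets: list[tuple[int, int]] | None = None,
) -> AnnotationMask:
    """Segment a mosaic by majority vote over shifted tilings.

    The mosaic is processed ``n_shifts`` times with tile grids offset by
    slightly different amounts (the first offset is (0, 0); the rest are
    drawn without replacement from a seeded uniform grid over
    ``[0, input_px)^2``).  Each pixel's final label is the majority vote
    across shifts; ties are broken by the highest accumulated softmax
    score, then the lowest class index.  Deterministic given ``seed``.
    """
    if model.network is None or not model.network.trained_:
        raise ValueError("predict_tiled requires a trained model")
    in_px = model.input_px
    h, w = mosaic.shape
    if h < 1 or w < 1:
        raise ValueError("empty mosaic")
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    if offsets is None:
        rng = np.random.default_rng(seed)
        n_cells = in_px * in_px
        offsets = [(0, 0)]
        if n_shifts > 1:
            pool = np.setdiff1d(np.arange(n_cells), [0])
            picks = rng.choice(pool, size=min(n_shifts - 1, pool.size), replace=False)
            offsets += [(int(p // in_px), int(p % in_px)) for p in picks]

    k = model.n_classes
    votes = np.zeros((k, h, w), dtype=np.int32)
    scores = np.zeros((k, h, w))
    for off in offsets:
        s = _predict_shift(model.network, mosaic.data, off)
        lab = s.argmax(axis=0)
        votes[lab, np.arange(h)[:, None], np.arange(w)[None, :]] += 1
        scores += s
    winners = votes == votes.max(axis=0, keepdims=True)
    masked = np.where(winners, scores, -np.inf)
    final = masked.argmax(axis=0).astype(np.int64)
    level = model.n_classes if model.n_classes in (3, 6, 15) else 2
    return AnnotationMask(final, level=level)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class TiledSegmenter(BaseEstimator):
    """Chessboard-trained tissue segmenter with majority-vote inference.

    ``fit(mosaic, labels)`` performs the chessboard split, trains the
    (reduced-width) UNet3+ on the training parity and keeps the white
    patches as the held-out test set (``test_set_``); ``predict(mosaic)``
    runs shifted tiled inference.  Fitted attributes: ``model_``,
    ``train_set_``, ``test_set_``, ``history_``.
    """

    def __init__(
        self,
        n_classes: int = 6,
        n_stacks: int = 2,
        width_factor: float = 1 / 16,
        input_px: int = 48,
        patch_px: int = 64,
        epochs: int = 40,
        patience: int = 10,
        batch_size: int = 8,
        steps_per_epoch: int = 5,
        learning_rate: float = 5e-3,
        n_val_tiles: int = 4,
        n_shifts: int = 5,
        seed: int = 0,
    ):
        self.n_classes = n_classes
        self.n_stacks = n_stacks
        self.width_factor = width_factor
        self.input_px = input_px
        self.patch_px = patch_px
        self.epochs = epochs
        self.patience = patience
        self.batch_size = batch_size
        self.steps_per_epoch = steps_per_epoch
        self.learning_rate = learning_rate
        self.n_val_tiles = n_val_tiles
        self.n_shifts = n_shifts
        self.seed = seed

    def fit(self, mosaic: MultimodalImage, labels: AnnotationMask) -> "TiledSegmenter":
        spec = ModelSpec(
            n_classes=self.n_classes,
            input_px=self.input_px,
            n_stacks=self.n_stacks,
            width_factor=self.width_factor,
        )
        self.train_set_, self.test_set_ = chessboard_split(mosaic, labels, self.patch_px)
        model = build_model(spec, seed=self.seed)
        config = TrainConfig(
            epochs=self.epochs,
            patience=self.patience,
            batch_size=self.batch_size,
            steps_per_epoch=self.steps_per_epoch,
            learning_rate=self.learning_rate,
            n_val_tiles=self.n_val_tiles,
            seed=self.seed,
        )
        self.model_ = train(model, self.train_set_, config)
        self.history_ = self.model_.history
        return self

    def predict(self, mosaic: MultimodalImage) -> AnnotationMask:
        return predict_tiled(self.model_, mosaic, n_shifts=self.n_shifts, seed=self.seed)
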