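"""Corrosion-phase segmentation with an orthogonal-plane 2D U-Net.

A grey micro-CT volume is segmented into four labels (background/soft
tissue, metallic Mg, degraded Mg, severely degraded Mg) by a 2D U-Net.
3D context is partially preserved by training on 2D patches drawn from
the three orthogonal plane families (x-y, y-z, x-z) and, at inference,
averaging the three per-plane class-probability fields before taking
the per-voxel argmax.

Two head modes are provided: ``multiclass_4`` (default; one network,
4-channel softmax) and ``binary_per_class`` (three single-channel
networks, one per material phase, combined by highest probability with
background elsewhere).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .unet import Adam, UNet2D, sigmoid_bce, softmax_cross_entropy
from .volumes import GreyVolume, LabelVolume, VALID_LABELS

PLANES = ("xy", "yz", "xz")
# slices of plane family f are taken perpendicular to this axis
PLANE_AXIS = {"xy": 0, "yz": 2, "xz": 1}

N_CLASSES = 4
FOREGROUND_CLASSES = (1, 2, 3)


@dataclass
class UNetSpec:
    """Architecture and training hyper-parameters.

    Defaults: three encoding stages of two 3x3 convolutions each,
    16 feature maps doubled per stage, mirrored decoder with 2x2
    up-convolutions, Adam at 1e-3 on class-weighted cross-entropy.
    """

    n_encoding_stages: int = 3
    convs_per_stage: int = 2
    base_features: int = 16
    kernel_size: int = 3
    head_mode: str = "multiclass_4"
    loss_name: str = "weighted_cross_entropy"
    learning_rate: float = 1e-3
    epochs: int = 12
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encoding_stages < 1:
            raise ValueError("n_encoding_stages must be >= 1")
        if self.base_features < 1:
            raise ValueError("base_features must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.head_mode not in ("multiclass_4", "binary_per_class"):
            raise ValueError(f"unknown head_mode {self.head_mode!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class PatchPair:
    grey: np.ndarray  # (p, p) view into the source volume
    labels: np.ndarray
    plane: str
    slice_index: int


@dataclass
class TrainingPatchSet:
    pairs: list[PatchPair]
    patch_size: int
    overlap: int

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# patch extraction


def _tile_starts(dim: int, patch: int, overlap: int) -> list[int]:
    """Tile start offsets; the last tile is placed flush to the edge."""
    step = patch - overlap
    if step < 1:
        raise ValueError("overlap must be smaller than patch_size")
    starts = list(range(0, dim - patch + 1, step))
    if starts[-1] != dim - patch:
        starts.append(dim - patch)
    return starts


def patch_pair_count(
    shape: tuple[int, int, int], patch_size: int, overlap: int = 0
) -> int:
    """Closed-form number of orthogonal-plane patch pairs.

    For a volume (a, b, c) with zero overlap this is
    a*ceil(b/p)*ceil(c/p) + b*ceil(a/p)*ceil(c/p) + c*ceil(a/p)*ceil(b/p):
    every slice of each of the three plane families is tiled
    independently. An 800^3 volume at patch 800 gives 2400 pairs.
    """
    a, b, c = shape
    n = {d: len(_tile_starts(d, patch_size, overlap)) for d in {a, b, c}}
    return a * n[b] * n[c] + c * n[a] * n[b] + b * n[a] * n[c]


def extract_patches(
    grey: GreyVolume,
    labels: LabelVolume,
    patch_size: int,
    overlap: int = 0,
) -> TrainingPatchSet:
    """Tile every slice of the three orthogonal plane families.

    Patches are congruent (grey, label) views of size
    ``patch_size x patch_size``; partial tiles are taken flush to the
    volume edge. Raises if the patch exceeds any volume dimension.
    """
    if grey.shape != labels.shape:
        raise ValueError("grey and label volumes must be congruent")
    if patch_size > min(grey.shape):
        raise ValueError(
            f"patch_size {patch_size} exceeds volume extent {grey.shape}"
        )
    g, l = grey.intensities, labels.labels
    pairs: list[PatchPair] = []
    for plane in PLANES:
        ax = PLANE_AXIS[plane]
        gm = np.moveaxis(g, ax, 0)
        lm = np.moveaxis(l, ax, 0)
        n0, n1, n2 = gm.shape
        s1 = _tile_starts(n1, patch_size, overlap)
        s2 = _tile_starts(n2, patch_size, overlap)
        for i in range(n0):
            for y in s1:
                for x in s2:
                    pairs.append(
                        PatchPair(
                            grey=gm[i, y : y + patch_size, x : x + patch_size],
                            labels=lm[i, y : y + patch_size, x : x + patch_size],
                            plane=plane,
                            slice_index=i,
                        )
                    )
    return TrainingPatchSet(pairs=pairs, patch_size=patch_size, overlap=overlap)


def subsample_patches(
    patches: TrainingPatchSet,
    k: int,
    rng: np.random.Generator,
    balance: bool = True,
) -> TrainingPatchSet:
    """Seeded subset of ``k`` patches, oversampling rare classes.

    Scaffold volumes are dominated by background; severely degraded
    material may appear in only a handful of patches. With ``balance``
    every patch containing the rarest foreground class is kept first
    (then the next-rarest, and so on) before filling up uniformly at
    random, so small classes stay represented in the training set.
    """
    n = len(patches)
    if n <= k:
        return patches
    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    if balance:
        has = np.array(
            [[(p.labels == c).any() for c in FOREGROUND_CLASSES] for p in patches.pairs]
        )
        rarity = has.sum(axis=0)
        for ci in np.argsort(rarity):
            if len(chosen) >= k // 2:
                break
            cand = np.flatnonzero(has[:, ci] & ~taken)
            room = k // 2 - len(chosen)
            if cand.size > room:
                cand = rng.choice(cand, size=room, replace=False)
            chosen.extend(int(i) for i in cand)
            taken[cand] = True
    rest = np.flatnonzero(~taken)
    fill = rng.choice(rest, size=k - len(chosen), replace=False)
    chosen.extend(int(i) for i in fill)
    chosen.sort()
    return TrainingPatchSet(
        pairs=[patches.pairs[i] for i in chosen],
        patch_size=patches.patch_size,
        overlap=patches.overlap,
    )


# ---------------------------------------------------------------------------
# parameter counting


def count_parameters(spec: UNetSpec) -> int:
    """Analytic trainable-parameter count of the architecture.

    Sums k^2*c_in*c_out + c_out per convolution, 2^2*c_in*c_out + c_out
    per up-convolution and c_in*c_out + c_out for the final 1x1 head;
    equals the built model's actual parameter count.
    """

    def conv(cin: int, cout: int, k: int) -> int:
        return k * k * cin * cout + cout

    k = spec.kernel_size
    feats = [spec.base_features * 2**i for i in range(spec.n_encoding_stages)]
    out_channels = N_CLASSES if spec.head_mode == "multiclass_4" else 1

    def one_net() -> int:
        total, cin = 0, 1
        for f in feats:
            for _ in range(spec.convs_per_stage):
                total += conv(cin, f, k)
                cin = f
        for i in range(spec.n_encoding_stages - 2, -1, -1):
            f = feats[i]
            total += 4 * cin * f + f  # 2x2 up-convolution
            cin = 2 * f
            for _ in range(spec.convs_per_stage):
                total += conv(cin, f, k)
                cin = f
        return total + conv(cin, out_channels, 1)

    n_nets = 1 if spec.head_mode == "multiclass_4" else len(FOREGROUND_CLASSES)
    return n_nets * one_net()


def _build_nets(spec: UNetSpec) -> list[UNet2D]:
    out_ch = N_CLASSES if spec.head_mode == "multiclass_4" else 1
    n_nets = 1 if spec.head_mode == "multiclass_4" else len(FOREGROUND_CLASSES)
    return [
        UNet2D(
            n_stages=spec.n_encoding_stages,
            convs_per_stage=spec.convs_per_stage,
            base_features=spec.base_features,
            kernel_size=spec.kernel_size,
            out_channels=out_ch,
            seed=spec.seed + i,
        )
        for i in range(n_nets)
    ]


# ---------------------------------------------------------------------------
# model


@dataclass
class SegmentationModel:
    """Trained network(s) plus the normalization statistics used."""

    spec: UNetSpec
    nets: list[UNet2D]
    norm_mean: float
    norm_sd: float
    loss_history: list[float] = field(default_factory=list)

    def n_params(self) -> int:
        return sum(n.n_params() for n in self.nets)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, net in enumerate(self.nets):
            for j, arr in enumerate(net.state_arrays()):
                arrays[f"net{i}_p{j}"] = arr
        np.savez(path, **arrays)
        echo = {
            "spec": self.spec.__dict__,
            "norm_mean": self.norm_mean,
            "norm_sd": self.norm_sd,
            "loss_history": self.loss_history,
            "n_params": self.n_params(),
        }
        path.with_suffix(".json").write_text(json.dumps(echo, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        path = Path(path)
        echo = json.loads(path.with_suffix(".json").read_text())
        spec = UNetSpec(**echo["spec"])
        nets = _build_nets(spec)
        data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
        for i, net in enumerate(nets):
            arrays = []
            j = 0
            while f"net{i}_p{j}" in data:
                arrays.append(data[f"net{i}_p{j}"])
                j += 1
            net.load_state(arrays)
        return cls(
            spec=spec,
            nets=nets,
            norm_mean=echo["norm_mean"],
            norm_sd=echo["norm_sd"],
            loss_history=list(echo["loss_history"]),
        )


# ---------------------------------------------------------------------------
# training


def _patch_arrays(patches: TrainingPatchSet) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.grey for p in patches.pairs]).astype(np.float32)
    Y = np.stack([p.labels for p in patches.pairs]).astype(np.int64)
    return X, Y


def class_weights_from_labels(Y: np.ndarray) -> np.ndarray:
    """Inverse-frequency class weights, mean-normalized.

    The background dominates scaffold volumes; without weighting the
    loss barely sees the thin degraded layers. Absent classes trigger a
    warning and get weight 0.
    """
    counts = np.bincount(Y.ravel(), minlength=N_CLASSES).astype(np.float64)
    w = np.zeros(N_CLASSES)
    present = counts > 0
    if not present.all():
        missing = [int(c) for c in np.flatnonzero(~present)]
        warnings.warn(f"classes absent from training labels: {missing}", stacklevel=3)
    w[present] = counts[present].sum() / counts[present]
    if w.sum() > 0:
        w *= present.sum() / w.sum() * 1.0
    return w.astype(np.float32)


def train_unet(patches: TrainingPatchSet, spec: UNetSpec) -> SegmentationModel:
    """Train on a patch set; deterministic for a fixed spec seed.

    Normalization is a per-training-set z-score whose statistics are
    stored in the model and reapplied at inference.
    """
    if spec.epochs < 1:
        raise ValueError("epochs must be >= 1")
    if len(patches) == 0:
        raise ValueError("empty patch set")
    tile = 2 ** (spec.n_encoding_stages - 1)
    if patches.patch_size % tile:
        raise ValueError(f"patch_size must be a multiple of {tile}")
    X, Y = _patch_arrays(patches)
    mean, sd = float(X.mean()), float(X.std())
    if sd == 0:
        sd = 1.0
    Xn = (X - mean) / sd
    Xn = Xn[:, None]  # (N, 1, p, p)
    weights = class_weights_from_labels(Y)

    nets = _build_nets(spec)
    history: list[float] = []
    rng = np.random.default_rng(spec.seed)
    optims = [Adam(net, lr=spec.learning_rate) for net in nets]
    n = Xn.shape[0]
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for k0 in range(0, n, spec.batch_size):
            sel = order[k0 : k0 + spec.batch_size]
            xb, yb = Xn[sel], Y[sel]
            batch_loss = 0.0
            for ci, (net, opt) in enumerate(zip(nets, optims)):
                net.zero_grad()
                logits = net.forward(xb, train=True)
                if spec.head_mode == "multiclass_4":
                    loss, dl = softmax_cross_entropy(logits, yb, weights)
                else:
                    cls = FOREGROUND_CLASSES[ci]
                    tgt = (yb == cls).astype(np.int64)
                    pos = max(tgt.mean(), 1e-4)
                    loss, dl = sigmoid_bce(logits, tgt, pos_weight=(1 - pos) / pos)
                net.backward(dl)
                opt.step()
                batch_loss += loss
            total += batch_loss * len(sel)
            seen += len(sel)
        history.append(total / seen)
    return SegmentationModel(
        spec=spec, nets=nets, norm_mean=mean, norm_sd=sd, loss_history=history
    )


# ---------------------------------------------------------------------------
# inference


def _net_probs(model: SegmentationModel, batch: np.ndarray) -> np.ndarray:
    """Class probabilities (B, 4, H, W) for a normalized batch."""
    if model.spec.head_mode == "multiclass_4":
        logits = model.nets[0].forward(batch, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
    B, _, H, W = batch.shape
    probs = np.empty((B, N_CLASSES, H, W), dtype=np.float32)
    for ci, net in enumerate(model.nets):
        logits = net.forward(batch, train=False)[:, 0]
        probs[:, FOREGROUND_CLASSES[ci]] = 1.0 / (1.0 + np.exp(-logits))
    fg = probs[:, list(FOREGROUND_CLASSES)]
    probs[:, 0] = np.clip(1.0 - fg.max(axis=1), 0.0, 1.0)
    return probs


def predict_volume(
    model: SegmentationModel, grey: GreyVolume, batch_size: int = 8
) -> LabelVolume:
    """Fuse per-plane 2D predictions into a 3D label volume.

    Every slice of each orthogonal plane family is pushed through the
    network; the three class-probability fields are averaged per voxel
    and the argmax taken. Slices are edge-padded to the network's tile
    multiple and cropped back.
    """
    tile = 2 ** (model.spec.n_encoding_stages - 1)
    if min(grey.shape) < tile:
        raise ValueError(
            f"volume {grey.shape} smaller than the network's minimum tile {tile}"
        )
    vol = (grey.intensities.astype(np.float32) - model.norm_mean) / model.norm_sd
    acc = np.zeros((N_CLASSES,) + grey.shape, dtype=np.float32)
    for plane in PLANES:
        ax = PLANE_AXIS[plane]
        stack = np.moveaxis(vol, ax, 0)
        n0, h, w = stack.shape
        ph = (-h) % tile
        pw = (-w) % tile
        padded = np.pad(stack, ((0, 0), (0, ph), (0, pw)), mode="edge")
        probs = np.empty((n0, N_CLASSES, h, w), dtype=np.float32)
        for k0 in range(0, n0, batch_size):
            batch = padded[k0 : k0 + batch_size, None]
            p = _net_probs(model, batch)
            probs[k0 : k0 + batch.shape[0]] = p[:, :, :h, :w]
        acc += np.moveaxis(np.moveaxis(probs, 1, 0), 1, ax + 1)
    labels = acc.argmax(axis=0).astype(np.uint8)
    return LabelVolume(labels=labels, voxel_size_um=grey.voxel_size_um)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_segmentation(
    pred: LabelVolume, truth: LabelVolume
) -> dict[int, dict[str, float]]:
    """Per-class Dice and IoU; a class absent from both scores 1.0."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must be congruent")
    scores: dict[int, dict[str, float]] = {}
    p, t = pred.labels, truth.labels
    for c in VALID_LABELS:
        pm = p == c
        tm = t == c
        np_, nt = int(pm.sum()), int(tm.sum())
        inter = int((pm & tm).sum())
        if np_ + nt == 0:
            dice, iou = 1.0, 1.0
        else:
            dice = 2.0 * inter / (np_ + nt)
            union = np_ + nt - inter
            iou = inter / union if union else 1.0
        scores[c] = {"dice": dice, "iou": iou}
    return scores
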