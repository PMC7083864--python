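"""Per-patch cell segmentation with a geometry-constrained stacked U-net.

The network is two U-nets in series.  The encoder convolutions of the first
are constrained to linear combinations of a fixed family of directional
kernels (one low-pass plus oriented band-passes from the filter bank), so
only the combination coefficients are learned; the second U-net receives
the channel-concatenation of the input patch and the first stage's output.
Training minimizes mean absolute error.

Optimizer settings (Adam, lr 1e-3, batch 8) and the channel/depth layout
are package defaults, not values from any reference implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .filters import DirectionalFilterBank, build_filter_bank
from .nn import Adam, ConstrainedConv2d, StackedUNet, UNet, mae_loss

__all__ = [
    "GESUNetSpec",
    "TrainingSet",
    "TrainingHistory",
    "constrained_conv_layer",
    "basis_from_bank",
    "build_gesunet",
    "augment",
    "train",
    "ablation_histories",
    "segment_patch",
    "save_model",
    "load_model",
    "desk_spec",
    "paper_spec",
]

MODEL_FORMAT = "astroseg-stacked-unet-v1"


@dataclass
class GESUNetSpec:
    """Architecture hyper-parameters of the stacked network."""

    patch_size: int = 128
    depth: int = 4
    base_channels: int = 16
    kernel_size: int = 3
    #: directional basis of the first encoder: n_orientations + 1 low-pass
    n_basis: int = 9
    basis_kernel_size: int = 7
    #: "none" (random init) or a path to an .npz of transferred encoder
    #: weights for the second U-net; no download happens at build time
    transfer_encoder: str = "none"
    loss: str = "mae"

    def __post_init__(self) -> None:
        if self.patch_size % (2 ** self.depth):
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^depth={2 ** self.depth}"
            )
        if self.n_basis < 2:
            raise ValueError("n_basis must be >= 2")
        if self.loss != "mae":
            raise ValueError(f"unsupported loss {self.loss!r}")


def paper_spec() -> GESUNetSpec:
    """Full-size preset: 128x128 patches, depth 4."""
    return GESUNetSpec()


def desk_spec() -> GESUNetSpec:
    """Reduced preset that trains in CPU-minutes: 64x64 patches, depth 3."""
    return GESUNetSpec(patch_size=64, depth=3, base_channels=8,
                       n_basis=9, basis_kernel_size=5)


@dataclass
class TrainingSet:
    """Paired (image patch in [0,1], binary mask) samples."""

    patches: list[tuple[np.ndarray, np.ndarray]]
    augmentation_factor: int = 0

    def __post_init__(self) -> None:
        for img, mask in self.patches:
            if img.shape != mask.shape:
                raise ValueError(
                    f"patch/mask shape mismatch: {img.shape} vs {mask.shape}"
                )
            vals = np.unique(mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("masks must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.patches)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.stack([p for p, _ in self.patches])[:, None].astype(np.float32)
        y = np.stack([m for _, m in self.patches])[:, None].astype(np.float32)
        return x, y


@dataclass
class TrainingHistory:
    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)


def basis_from_bank(bank: DirectionalFilterBank) -> np.ndarray:
    """Finest-scale directional kernels plus the low-pass, as (B, k, k)."""
    kernels = list(bank.kernels[0])
    if bank.lowpass.shape == kernels[0].shape:
        kernels.append(bank.lowpass)
    return np.stack(kernels).astype(np.float32)


def default_basis(spec: GESUNetSpec) -> np.ndarray:
    bank = build_filter_bank(
        n_scales=1,
        n_orientations=spec.n_basis - 1,
        base_kernel_size=spec.basis_kernel_size,
    )
    return basis_from_bank(bank)


def constrained_conv_layer(x: np.ndarray, coefficients: np.ndarray,
                           basis: np.ndarray,
                           bias: np.ndarray | None = None) -> np.ndarray:
    """Functional form of the basis-constrained convolution.

    ``x`` is (N, C_in, H, W); ``coefficients`` is (C_out, C_in, n_basis);
    ``basis`` is (n_basis, k, k).  Output channel c is
    ``sum_b coefficients[c, :, b] * (x (*) basis_b)``.
    """
    coefficients = np.asarray(coefficients, dtype=np.float32)
    basis = np.asarray(basis, dtype=np.float32)
    if coefficients.ndim != 3 or coefficients.shape[2] != basis.shape[0]:
        raise ValueError(
            f"coefficients shape {coefficients.shape} incompatible with "
            f"basis {basis.shape}"
        )
    layer = ConstrainedConv2d(coefficients.shape[1], coefficients.shape[0], basis)
    layer.params["coeff"] = coefficients
    if bias is not None:
        layer.params["b"] = np.asarray(bias, dtype=np.float32)
    else:
        layer.params["b"] = np.zeros(coefficients.shape[0], dtype=np.float32)
    return layer.forward(np.asarray(x, dtype=np.float32))


def build_gesunet(spec: GESUNetSpec, seed: int = 0,
                  basis: np.ndarray | None = None) -> StackedUNet:
    """Instantiate the stacked network described by ``spec``."""
    rng = np.random.default_rng(seed)
    if basis is None:
        basis = default_basis(spec)
    unet1 = UNet(in_channels=1, depth=spec.depth,
                 base_channels=spec.base_channels,
                 kernel_size=spec.kernel_size, basis=basis, rng=rng)
    unet2 = UNet(in_channels=2, depth=spec.depth,
                 base_channels=spec.base_channels,
                 kernel_size=spec.kernel_size, basis=None, rng=rng)
    model = StackedUNet(unet1, unet2)
    model.spec = spec
    if spec.transfer_encoder not in ("none",):
        _load_transferred_encoder(unet2, spec.transfer_encoder)
    return model


def _load_transferred_encoder(unet: UNet, weights_path: str) -> None:
    """Initialize encoder weights of ``unet`` from a saved .npz.

    Offline substitute for downloading a pretrained classification
    backbone: the archive must contain arrays ``enc{i}_conv{j}_w/b`` whose
    shapes match.  Missing or mismatched entries are left at random init.
    """
    try:
        data = np.load(weights_path)
    except OSError as exc:
        raise ValueError(
            f"transfer_encoder weights not readable: {weights_path!r}; "
            "pretrained transfer needs a local weights file (no download "
            "is attempted)"
        ) from exc
    for i, block in enumerate(unet.enc_blocks):
        convs = [l for l in block if l.params]
        for j, conv in enumerate(convs):
            wk, bk = f"enc{i}_conv{j}_w", f"enc{i}_conv{j}_b"
            if wk in data and data[wk].shape == conv.params["w"].shape:
                conv.params["w"] = data[wk].astype(np.float32)
            if bk in data and data[bk].shape == conv.params["b"].shape:
                conv.params["b"] = data[bk].astype(np.float32)


# ---------------------------------------------------------------------------
# data augmentation


def rigid_transform(image: np.ndarray, mask: np.ndarray, angle_deg: float,
                    shift: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Apply the same rotation + translation to an image/mask pair.

    Multiples of 90 degrees with integer shifts take an exact path
    (area-preserving); arbitrary angles use linear interpolation for the
    image and nearest-neighbour for the mask.
    """
    if angle_deg % 90 == 0:
        k = int(angle_deg // 90) % 4
        img_t = np.rot90(image, k)
        mask_t = np.rot90(mask, k)
    else:
        img_t = ndimage.rotate(image, angle_deg, reshape=False, order=1,
                               mode="constant", cval=0.0)
        mask_t = ndimage.rotate(mask.astype(float), angle_deg, reshape=False,
                                order=0, mode="constant", cval=0.0)
    dr, dc = int(round(shift[0])), int(round(shift[1]))
    img_t = _integer_shift(img_t, dr, dc)
    mask_t = _integer_shift(mask_t, dr, dc)
    return np.clip(img_t, 0.0, 1.0), (mask_t > 0.5).astype(mask.dtype)


def _integer_shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(a)
    h, w = a.shape
    r0, r1 = max(dr, 0), min(h + dr, h)
    c0, c1 = max(dc, 0), min(w + dc, w)
    out[r0:r1, c0:c1] = a[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def augment(training_set: TrainingSet, k: int, seed: int = 0) -> TrainingSet:
    """Add ``k`` rigid-transform variants of every pair.

    Output size is ``(k + 1) * len(training_set)``: the originals followed
    by rotated (uniform in [0, 360)) and translated (within +-10% of the
    patch size) copies.  Deterministic given ``seed``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    pairs = list(training_set.patches)
    for img, mask in training_set.patches:
        max_shift = max(1, int(0.1 * img.shape[0]))
        for _ in range(k):
            angle = rng.uniform(0.0, 360.0)
            shift = (int(rng.integers(-max_shift, max_shift + 1)),
                     int(rng.integers(-max_shift, max_shift + 1)))
            pairs.append(rigid_transform(img, mask, angle, shift))
    return TrainingSet(patches=pairs, augmentation_factor=k)


# ---------------------------------------------------------------------------
# training and inference


def _dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = float(np.sum((pred > 0) & (truth > 0)))
    denom = float(np.sum(pred > 0) + np.sum(truth > 0))
    return 2.0 * inter / denom if denom else 1.0


def train(model: "StackedUNet | UNet", training_set: TrainingSet,
          epochs: int = 100,
          validation_fraction: float = 0.15, seed: int = 0,
          lr: float = 1e-3, batch_size: int = 8,
          early_stop_dice: float | None = None,
          prob_threshold: float = 0.5,
          aux_weight: float = 0.3) -> TrainingHistory:
    """Fit the network with Adam on the MAE objective.

    The reported loss is the MAE of the final (second-stage) output; an
    auxiliary MAE on the first U-net's output, weighted by ``aux_weight``,
    supervises the first stage directly so the stack cannot stall on a
    collapsed second stage.  Returns per-epoch train/validation MAE (and
    validation Dice when a validation split exists).  ``early_stop_dice``
    stops training once the validation Dice reaches the given value.
    """
    if len(training_set) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(seed)
    x, y = training_set.arrays()
    n = x.shape[0]
    order = rng.permutation(n)
    n_val = int(round(validation_fraction * n))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise ValueError("validation fraction leaves no training data")
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    optimizer = Adam(model.layers(), lr=lr)
    history = TrainingHistory()
    for _epoch in range(epochs):
        perm = rng.permutation(xt.shape[0])
        losses = []
        for start in range(0, xt.shape[0], batch_size):
            idx = perm[start:start + batch_size]
            optimizer.zero_grad()
            pred = model.forward(xt[idx])
            loss, grad = mae_loss(pred, yt[idx])
            if isinstance(model, StackedUNet) and aux_weight > 0:
                _, aux_grad = mae_loss(model.stage1_output, yt[idx])
                model.backward(grad, dstage1=aux_weight * aux_grad)
            else:
                model.backward(grad)
            optimizer.step()
            losses.append(loss)
        history.train_mae.append(float(np.mean(losses)))
        if xv.shape[0]:
            val_losses, dices = [], []
            for start in range(0, xv.shape[0], batch_size):
                pred = model.forward(xv[start:start + batch_size])
                loss, _ = mae_loss(pred, yv[start:start + batch_size])
                val_losses.append(loss * pred.shape[0])
                for p, t in zip(pred, yv[start:start + batch_size]):
                    dices.append(_dice(p[0] >= prob_threshold, t[0]))
            history.val_mae.append(float(np.sum(val_losses) / xv.shape[0]))
            history.val_dice.append(float(np.mean(dices)))
            if early_stop_dice is not None and history.val_dice[-1] >= early_stop_dice:
                break
    return history


def segment_patch(model: StackedUNet, patch: np.ndarray,
                  prob_threshold: float = 0.5) -> np.ndarray:
    """Binary mask for one patch: thresholded network probability."""
    patch = np.asarray(patch, dtype=np.float32)
    spec = getattr(model, "spec", None)
    if spec is not None and patch.shape != (spec.patch_size, spec.patch_size):
        raise ValueError(
            f"patch shape {patch.shape} does not match spec "
            f"({spec.patch_size}, {spec.patch_size})"
        )
    prob = model.forward(patch[None, None])[0, 0]
    return (prob >= prob_threshold).astype(np.uint8)


def ablation_histories(training_set: TrainingSet, spec: GESUNetSpec,
                       epochs: int = 20, seed: int = 0,
                       **train_kwargs) -> dict[str, TrainingHistory]:
    """Training curves for the stacked network and its two single-U-net
    ablations on the same data.

    Returns histories keyed "stacked", "constrained_only" (first U-net
    with the fixed directional basis, alone) and "free_only" (second-style
    U-net with free encoder convolutions, alone).  Useful for qualitative
    comparison of convergence behaviour; no ordering is guaranteed.
    """
    basis = default_basis(spec)
    out: dict[str, TrainingHistory] = {}
    out["stacked"] = train(build_gesunet(spec, seed=seed, basis=basis),
                           training_set, epochs=epochs, seed=seed,
                           **train_kwargs)
    rng = np.random.default_rng(seed)
    unet1 = UNet(in_channels=1, depth=spec.depth,
                 base_channels=spec.base_channels,
                 kernel_size=spec.kernel_size, basis=basis, rng=rng)
    out["constrained_only"] = train(unet1, training_set, epochs=epochs,
                                    seed=seed, **train_kwargs)
    rng = np.random.default_rng(seed + 1)
    unet2 = UNet(in_channels=1, depth=spec.depth,
                 base_channels=spec.base_channels,
                 kernel_size=spec.kernel_size, basis=None, rng=rng)
    out["free_only"] = train(unet2, training_set, epochs=epochs, seed=seed,
                             **train_kwargs)
    return out


# ---------------------------------------------------------------------------
# serialization


def save_model(model: StackedUNet, path: str) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers()):
        for key, value in layer.params.items():
            arrays[f"layer{i}_{key}"] = value
        if isinstance(layer, ConstrainedConv2d):
            arrays[f"layer{i}_basis"] = layer.basis
    meta = {"format": MODEL_FORMAT, "spec": asdict(model.spec)}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> StackedUNet:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("format") != MODEL_FORMAT:
        raise ValueError(f"unrecognized model format in {path!r}")
    spec = GESUNetSpec(**meta["spec"])
    # rebuild with the stored basis so constrained layers match exactly
    basis = None
    for key in data.files:
        if key.endswith("_basis"):
            basis = data[key]
            break
    model = build_gesunet(spec, basis=basis)
    for i, layer in enumerate(model.layers()):
        for key in layer.params:
            stored = data[f"layer{i}_{key}"]
            if stored.shape != layer.params[key].shape:
                raise ValueError(f"shape mismatch for layer{i}_{key} in {path!r}")
            layer.params[key] = stored.astype(np.float32)
        layer.grads = {k: np.zeros_like(v) for k, v in layer.params.items()}
    return model
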