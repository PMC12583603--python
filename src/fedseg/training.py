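"""Training loop: preprocessing, patch sampling, loss and optimizer.

Preprocessing follows the plan: crop to the nonzero bounding box,
resample to the plan's target spacing (linear for images, nearest for
masks), then z-score normalize per case. Training samples random patches
with foreground oversampling and optimizes an equally weighted
Dice + cross-entropy loss with Nesterov-momentum SGD under a polynomial
learning-rate decay computed from the *global* epoch index, so federated
clients stay on a common schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from fedseg import nn
from fedseg.fingerprint import nonzero_bounding_box
from fedseg.model import ModelState, UNet2D
from fedseg.planner import TrainingPlan


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters (upstream-style defaults, all overridable)."""

    lr: float = 0.01
    momentum: float = 0.99
    nesterov: bool = True
    weight_decay: float = 3e-5
    lr_power: float = 0.9
    total_epochs: int = 1000
    fg_oversample: float = 1.0 / 3.0
    iters_per_epoch: int | None = None  # None -> ceil(n_cases / batch)
    num_classes: int = 2

    def lr_at(self, epoch: int) -> float:
        """Polynomial decay over the full planned training length."""
        frac = min(epoch, self.total_epochs - 1) / max(1, self.total_epochs)
        return self.lr * (1.0 - frac) ** self.lr_power


def preprocess_case(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, ...],
    plan: TrainingPlan,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop, resample to target spacing, z-score normalize."""
    box = nonzero_bounding_box(image)
    image = image[box]
    mask = mask[box]
    zoom = [s / t for s, t in zip(spacing, plan.target_spacing)]
    if any(abs(z - 1.0) > 1e-6 for z in zoom):
        image = ndimage.zoom(image.astype(np.float32), zoom, order=1)
        mask = ndimage.zoom(mask.astype(np.uint8), zoom, order=0)
    image = image.astype(np.float32)
    sd = float(image.std())
    image = (image - float(image.mean())) / (sd if sd > 1e-8 else 1.0)
    return image, np.ascontiguousarray(mask.astype(np.int64))


def sample_patch(
    rng: np.random.Generator,
    image: np.ndarray,
    mask: np.ndarray,
    patch_size: tuple[int, ...],
    force_fg: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Random patch of ``patch_size``; optionally centered on a foreground
    voxel. Cases smaller than the patch are zero-padded symmetrically."""
    pads = [max(0, p - s) for p, s in zip(patch_size, image.shape)]
    if any(pads):
        pad_spec = [(pd // 2, pd - pd // 2) for pd in pads]
        image = np.pad(image, pad_spec)
        mask = np.pad(mask, pad_spec)
    lows = []
    if force_fg and mask.any():
        fg = np.argwhere(mask > 0)
        center = fg[rng.integers(len(fg))]
        for c, p, s in zip(center, patch_size, image.shape):
            lo = int(np.clip(c - p // 2, 0, s - p))
            lows.append(lo)
    else:
        for p, s in zip(patch_size, image.shape):
            lows.append(int(rng.integers(0, s - p + 1)))
    sl = tuple(slice(lo, lo + p) for lo, p in zip(lows, patch_size))
    return image[sl], mask[sl]


def sgd_step(
    params: dict,
    grads: dict,
    buffers: dict,
    *,
    lr: float,
    momentum: float,
    nesterov: bool,
    weight_decay: float,
) -> None:
    """In-place Nesterov-momentum SGD update (torch-style formulation)."""
    for name, w in params.items():
        g = grads[name].astype(np.float32)
        if weight_decay and not name.endswith("bias") and "norm" not in name:
            g = g + weight_decay * w
        buf = buffers.get(name)
        if buf is None:
            buf = g.copy()
        else:
            buf = momentum * buf + g
        buffers[name] = buf
        d = g + momentum * buf if nesterov else buf
        w -= lr * d


def train_one_epoch(
    state: ModelState,
    cases: list[tuple[np.ndarray, np.ndarray]],
    plan: TrainingPlan,
    hp: Hyperparams,
    rng: np.random.Generator,
    *,
    epoch: int | None = None,
    buffers: dict | None = None,
) -> tuple[ModelState, list[float], dict]:
    """One epoch over preprocessed ``(image, mask)`` cases.

    Returns the updated state, the per-iteration loss trace, and the
    optimizer momentum buffers (kept local to the client; never part of
    the exchanged state).
    """
    if not cases:
        raise ValueError("no cases")
    net = UNet2D(plan, num_classes=hp.num_classes)
    state = state.copy()
    buffers = {} if buffers is None else buffers
    epoch = state.meta.get("epoch", 0) if epoch is None else epoch
    lr = hp.lr_at(epoch)
    batch = plan.batch_size
    iters = hp.iters_per_epoch or int(np.ceil(len(cases) / batch))
    losses: list[float] = []
    for _ in range(iters):
        xs, ys = [], []
        for _ in range(batch):
            idx = int(rng.integers(len(cases)))
            force_fg = bool(rng.random() < hp.fg_oversample)
            img, msk = sample_patch(rng, *cases[idx], plan.patch_size, force_fg)
            xs.append(img)
            ys.append(msk)
        x = np.stack(xs)[:, None]
        y = np.stack(ys)
        logits, tape = net.forward(state.params, x, want_tape=True)
        loss, dlogits = nn.dice_ce_loss_and_grad(logits, y)
        if not np.isfinite(loss):
            raise RuntimeError("diverged: non-finite loss")
        grads = net.backward(dlogits, tape)
        if lr != 0.0:
            sgd_step(
                state.params,
                grads,
                buffers,
                lr=lr,
                momentum=hp.momentum,
                nesterov=hp.nesterov,
                weight_decay=hp.weight_decay,
            )
        losses.append(float(loss))
    state.meta["epoch"] = epoch + 1
    return state, losses, buffers


def predict(
    state: ModelState,
    plan: TrainingPlan,
    image: np.ndarray,
    spacing: tuple[float, ...],
    *,
    num_classes: int = 2,
) -> np.ndarray:
    """Predict a label mask on the native grid of ``image``.

    The image is resampled to the plan's target spacing, normalized and
    segmented at full size; the class *probabilities* are then resampled
    back to the native grid (linear) before the argmax, so label maps do
    not suffer nearest-neighbor quantization when the plan's spacing is
    coarser than the native one.
    """
    net = UNet2D(plan, num_classes=num_classes)
    native_shape = image.shape
    zoom = [s / t for s, t in zip(spacing, plan.target_spacing)]
    img = image.astype(np.float32)
    if any(abs(z - 1.0) > 1e-6 for z in zoom):
        img = ndimage.zoom(img, zoom, order=1)
    sd = float(img.std())
    img = (img - float(img.mean())) / (sd if sd > 1e-8 else 1.0)
    logits = net.predict_logits(state.params, img)
    probs = nn.softmax(logits[None])[0]
    if probs.shape[1:] != native_shape:
        factors = [n / c for n, c in zip(native_shape, probs.shape[1:])]
        chans = []
        for c in range(probs.shape[0]):
            pc = ndimage.zoom(probs[c], factors, order=1)
            pc = pc[tuple(slice(0, n) for n in native_shape)]
            pads = [(0, n - s) for n, s in zip(native_shape, pc.shape)]
            if any(p[1] for p in pads):
                pc = np.pad(pc, pads, mode="edge")
            chans.append(pc)
        probs = np.stack(chans)
    return np.argmax(probs, axis=0).astype(np.uint8)
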