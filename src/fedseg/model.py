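"""Dynamic 2D U-Net built from a training plan, with a canonical layer
naming schema.

The naming schema is the substrate for asymmetric federation: layers are
matched across clients by *name identifier* and *parameter shape*, so
names must be stable across rebuilds and must align semantically between
architectures of different depths. Two conventions matter:

* ``encoder.stages.<i>`` counts from the input inward, so the shallow
  encoder stages of a deeper and a shallower network share names and
  shapes.
* ``decoder.stages.<d>`` counts from the bottleneck outward
  (``decoder.stages.0`` is the deepest), so decoder layers whose channel
  counts coincide under the capped doubling schedule also shape-match
  across depths.

Parameters live in a flat ordered mapping (:class:`ModelState`), the unit
of federation exchange.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from fedseg import nn
from fedseg.planner import TrainingPlan

KERNEL = 3  # conv kernel per axis; pooling/stride is 2


@dataclass
class ModelState:
    """Ordered map layer-identifier -> parameter array, plus metadata."""

    params: "OrderedDict[str, np.ndarray]"
    meta: dict = field(default_factory=dict)

    def copy(self) -> "ModelState":
        return ModelState(
            params=OrderedDict((k, v.copy()) for k, v in self.params.items()),
            meta=dict(self.meta),
        )

    def shapes(self) -> "OrderedDict[str, tuple[int, ...]]":
        return OrderedDict((k, tuple(v.shape)) for k, v in self.params.items())

    def allclose(self, other: "ModelState", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if list(self.params) != list(other.params):
            return False
        return all(
            np.allclose(v, other.params[k], rtol=rtol, atol=atol)
            for k, v in self.params.items()
        )


def encoder_stride(plan: TrainingPlan, stage: int) -> tuple[int, ...]:
    """Downsampling stride applied on entry to encoder ``stage`` (>=1).

    Axis ``a`` is halved in stages ``1..n_poolings_per_axis[a]``; axes
    with fewer poolings stop halving early, which keeps anisotropic
    patches above the minimum bottleneck extent.
    """
    return tuple(2 if p >= stage else 1 for p in plan.n_poolings_per_axis)


def architecture_layout(
    plan: TrainingPlan, in_channels: int = 1, num_classes: int = 2
) -> "OrderedDict[str, tuple[int, ...]]":
    """Ordered layer-identifier -> parameter-shape map for a plan.

    Every encoder stage is two conv->instance-norm->leaky-ReLU blocks
    (the first conv of stages >= 1 downsamples by stride 2); the decoder
    mirrors the encoder with kernel-2 transposed convolutions and skip
    concatenation; a 1x1 convolution forms the segmentation head.
    """
    if plan.dimensionality != 2:
        raise NotImplementedError("only 2D networks are implemented")
    if plan.n_stages < 2:
        raise ValueError("degenerate plan: n_stages must be >= 2")
    feats = plan.features_per_stage
    n = plan.n_stages
    layout: "OrderedDict[str, tuple[int, ...]]" = OrderedDict()

    def conv_block(prefix: str, cin: int, cout: int) -> None:
        layout[f"{prefix}.conv.weight"] = (cout, cin, KERNEL, KERNEL)
        layout[f"{prefix}.conv.bias"] = (cout,)
        layout[f"{prefix}.norm.weight"] = (cout,)
        layout[f"{prefix}.norm.bias"] = (cout,)

    cin = in_channels
    for i in range(n):
        conv_block(f"encoder.stages.{i}.convs.0", cin, feats[i])
        conv_block(f"encoder.stages.{i}.convs.1", feats[i], feats[i])
        cin = feats[i]

    for d in range(n - 1):
        s = n - 2 - d  # skip-connection stage this decoder stage restores
        k = encoder_stride(plan, s + 1)
        layout[f"decoder.stages.{d}.upconv.weight"] = (feats[s + 1], feats[s], *k)
        layout[f"decoder.stages.{d}.upconv.bias"] = (feats[s],)
        conv_block(f"decoder.stages.{d}.convs.0", 2 * feats[s], feats[s])
        conv_block(f"decoder.stages.{d}.convs.1", feats[s], feats[s])

    layout["head.weight"] = (num_classes, feats[0], 1, 1)
    layout["head.bias"] = (num_classes,)
    return layout


def init_state(
    layout: "OrderedDict[str, tuple[int, ...]]",
    seed: int,
    *,
    plan_hash: str = "",
) -> ModelState:
    """He-initialized parameters, deterministic in ``seed`` and layout order."""
    rng = np.random.default_rng(seed)
    params: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for name, shape in layout.items():
        if name.endswith("norm.weight"):
            params[name] = np.ones(shape, dtype=np.float32)
        elif name.endswith("bias") or name.endswith("norm.bias"):
            params[name] = np.zeros(shape, dtype=np.float32)
        else:  # conv / upconv weights: He normal on fan-in
            fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else int(shape[0])
            w = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
            params[name] = w.astype(np.float32)
    return ModelState(params=params, meta={"plan_hash": plan_hash, "epoch": 0})


class UNet2D:
    """Functional U-Net: parameters are read from a state dict each call,
    so federated updates to the state take effect without rebuilding."""

    def __init__(self, plan: TrainingPlan, in_channels: int = 1, num_classes: int = 2):
        self.plan = plan
        self.in_channels = in_channels
        self.num_classes = num_classes
        self.layout = architecture_layout(plan, in_channels, num_classes)

    def init_state(self, seed: int) -> ModelState:
        return init_state(self.layout, seed, plan_hash=self.plan.plan_hash)

    # ------------------------------------------------------------ forward

    def _conv_block_forward(self, params, prefix, x, stride):
        y, c1 = nn.conv2d_forward(
            x, params[f"{prefix}.conv.weight"], params[f"{prefix}.conv.bias"], stride
        )
        y, c2 = nn.instnorm_forward(
            y, params[f"{prefix}.norm.weight"], params[f"{prefix}.norm.bias"]
        )
        y, c3 = nn.lrelu_forward(y)
        return y, (prefix, c1, c2, c3)

    def _conv_block_backward(self, dy, cache, grads):
        prefix, c1, c2, c3 = cache
        dy = nn.lrelu_backward(dy, c3)
        dy, dg, dbn = nn.instnorm_backward(dy, c2)
        grads[f"{prefix}.norm.weight"] = dg
        grads[f"{prefix}.norm.bias"] = dbn
        dx, dw, db = nn.conv2d_backward(dy, c1)
        grads[f"{prefix}.conv.weight"] = dw
        grads[f"{prefix}.conv.bias"] = db
        return dx

    def forward(self, params: dict, x: np.ndarray, *, want_tape: bool = False):
        """Compute logits for ``x`` of shape (N, C, H, W).

        Spatial extents must be divisible by ``2^poolings`` per axis.
        Returns ``logits`` or ``(logits, tape)`` when a backward pass is
        intended.
        """
        plan = self.plan
        n_stages = plan.n_stages
        tape: list = []
        skips: list[np.ndarray] = []
        h = x.astype(np.float32, copy=False)
        enc_caches = []
        for i in range(n_stages):
            stride = (1, 1) if i == 0 else encoder_stride(plan, i)
            h, cb0 = self._conv_block_forward(params, f"encoder.stages.{i}.convs.0", h, stride)
            h, cb1 = self._conv_block_forward(params, f"encoder.stages.{i}.convs.1", h, (1, 1))
            enc_caches.append((cb0, cb1))
            skips.append(h)

        dec_caches = []
        for d in range(n_stages - 1):
            s = n_stages - 2 - d
            k = encoder_stride(plan, s + 1)
            up, cup = nn.convtranspose2d_forward(
                h,
                params[f"decoder.stages.{d}.upconv.weight"],
                params[f"decoder.stages.{d}.upconv.bias"],
                k,
            )
            h = np.concatenate([skips[s], up], axis=1)
            split = skips[s].shape[1]
            h, cb0 = self._conv_block_forward(params, f"decoder.stages.{d}.convs.0", h, (1, 1))
            h, cb1 = self._conv_block_forward(params, f"decoder.stages.{d}.convs.1", h, (1, 1))
            dec_caches.append((d, cup, split, cb0, cb1))

        logits, chead = nn.conv2d_forward(h, params["head.weight"], params["head.bias"], (1, 1))
        if not want_tape:
            return logits
        tape = (enc_caches, dec_caches, chead)
        return logits, tape

    # ----------------------------------------------------------- backward

    def backward(self, dlogits: np.ndarray, tape) -> dict:
        """Gradients w.r.t. every parameter, keyed by layer identifier."""
        enc_caches, dec_caches, chead = tape
        grads: dict[str, np.ndarray] = {}
        dh, dwh, dbh = nn.conv2d_backward(dlogits, chead)
        grads["head.weight"] = dwh
        grads["head.bias"] = dbh

        dskips: dict[int, np.ndarray] = {}
        n_stages = self.plan.n_stages
        for d, cup, split, cb0, cb1 in reversed(dec_caches):
            s = n_stages - 2 - d
            dh = self._conv_block_backward(dh, cb1, grads)
            dh = self._conv_block_backward(dh, cb0, grads)
            dskip, dup = dh[:, :split], dh[:, split:]
            if s in dskips:
                dskips[s] += dskip
            else:
                dskips[s] = dskip.copy()
            dh, dwu, dbu = nn.convtranspose2d_backward(dup, cup)
            grads[f"decoder.stages.{d}.upconv.weight"] = dwu
            grads[f"decoder.stages.{d}.upconv.bias"] = dbu

        for i in reversed(range(n_stages)):
            if i in dskips:  # skip-connection gradient joins here
                dh = dh + dskips[i]
            cb0, cb1 = enc_caches[i]
            dh = self._conv_block_backward(dh, cb1, grads)
            dh = self._conv_block_backward(dh, cb0, grads)
        return grads

    # ---------------------------------------------------------- inference

    def predict_logits(self, params: dict, image: np.ndarray) -> np.ndarray:
        """Full-image logits for a single-channel 2D image (H, W); pads to
        the divisibility the pooling depth requires and crops back."""
        h, w = image.shape
        div = tuple(2**p for p in self.plan.n_poolings_per_axis)
        ph = (-h) % div[0]
        pw = (-w) % div[1]
        x = np.pad(image, ((0, ph), (0, pw)), mode="edge")[None, None].astype(np.float32)
        logits = self.forward(params, x)
        return logits[0, :, :h, :w]
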