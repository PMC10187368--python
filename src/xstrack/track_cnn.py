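"""CADE: CNN-based analysis for displacement estimation.

An encoder-decoder optical-flow network (a full-resolution StrainNet-f /
FlowNetS-style architecture) maps a reference/sample speckle image pair,
stacked as two channels, to a dense 2-channel sub-pixel displacement field.
The encoder has ten convolutional feature layers (7x7, 5x5, 5x5 and seven 3x3
kernels) with four stride-2 down-samplings; the decoder has four stride-2
up-samplings built from eight transposed convolutions (four feature deconvs
and four flow up-samplers) and five 3x3 prediction convolutions emitting
displacement estimates at five scales, coarsest to full resolution.  Training
minimizes the multiscale endpoint-error (EPE) loss with Adam.

The network, its automatic differentiation and the training loop are
implemented directly on numpy: convolutions run as im2col matrix products and
gradients flow through a small reverse-mode tape.  Network outputs are scaled
by ``div_flow`` (internally the net regresses flow / div_flow), the FlowNet
convention for sub-pixel targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .deform import DisplacementField
from .wave_optics import SpeckleImage

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "EpeValue",
    "SCALED_NETWORK",
    "SCALED_TRAIN",
    "FULL_NETWORK",
    "FULL_TRAIN",
    "CadeNet",
    "build_network",
    "epe",
    "multiscale_loss",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

_EPE_EPS = 1e-8


# ----------------------------------------------------------------------------
# reverse-mode autodiff tape


class Var:
    """A node in the computation graph: numpy data plus accumulated gradient."""

    __slots__ = ("data", "grad", "_backward", "_prev")

    def __init__(self, data, prev=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._prev = tuple(prev)
        self._backward = backward

    def zero_grad(self):
        self.grad = None

    def backward(self):
        order: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accum(var: Var, g: NDArray) -> None:
    if var.grad is None:
        var.grad = g.copy()
    else:
        var.grad += g


def _im2col(xp: NDArray, kh: int, kw: int, stride: int) -> NDArray:
    """(N, C, Hp, Wp) -> (N, oh*ow, C*kh*kw) patch matrix."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]
    n, c, oh, ow = view.shape[:4]
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw), oh, ow


def _col2im(dcols: NDArray, pshape, kh: int, kw: int, stride: int, oh: int, ow: int) -> NDArray:
    n, c, hp, wp = pshape
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dxp = np.zeros(pshape, dtype=np.float64)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += d[:, :, i, j]
    return dxp


def conv2d(x: Var, w: Var, b: Var, stride: int = 1, pad: int | None = None) -> Var:
    """2D convolution (cross-correlation); weight shape (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = w.data.shape
    if pad is None:
        pad = kh // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(cout, -1)
    y = cols @ wmat.T + b.data
    n = x.data.shape[0]
    out_data = y.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
    pshape = xp.shape

    def backward(gout):
        gm = gout.transpose(0, 2, 3, 1).reshape(n, oh * ow, cout)
        _accum(b, gm.sum(axis=(0, 1)))
        dw = np.einsum("npo,npk->ok", gm, cols)
        _accum(w, dw.reshape(w.data.shape))
        dcols = gm @ wmat
        dxp = _col2im(dcols, pshape, kh, kw, stride, oh, ow)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        _accum(x, dxp)

    return Var(out_data, (x, w, b), backward)


def conv_transpose2d(x: Var, w: Var, b: Var) -> Var:
    """Transposed convolution, kernel 4, stride 2, padding 1 (exact 2x upsampling).

    Weight shape (Cin, Cout, 4, 4).  Implemented as zero-stuffing followed by
    an ordinary convolution with the spatially flipped, channel-swapped kernel.
    """
    cin, cout, kh, kw = w.data.shape
    n, c, h, wid = x.data.shape
    # dilate by stride 2, pad by k - 1 - p = 2
    xd = np.zeros((n, c, 2 * h - 1 + 4, 2 * wid - 1 + 4), dtype=np.float64)
    xd[:, :, 2 : 2 + 2 * h - 1 : 2, 2 : 2 + 2 * wid - 1 : 2] = x.data
    wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cout, Cin, 4, 4)
    cols, oh, ow = _im2col(xd, kh, kw, 1)
    wmat = wflip.reshape(cout, -1)
    y = cols @ wmat.T + b.data
    out_data = y.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)  # (N, Cout, 2h, 2w)
    pshape = xd.shape

    def backward(gout):
        gm = gout.transpose(0, 2, 3, 1).reshape(n, oh * ow, cout)
        _accum(b, gm.sum(axis=(0, 1)))
        dwflip = np.einsum("npo,npk->ok", gm, cols).reshape(wflip.shape)
        _accum(w, dwflip.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dcols = gm @ wmat
        dxd = _col2im(dcols, pshape, kh, kw, 1, oh, ow)
        _accum(x, dxd[:, :, 2 : 2 + 2 * h - 1 : 2, 2 : 2 + 2 * wid - 1 : 2])

    return Var(out_data, (x, w, b), backward)


def leaky_relu(x: Var, slope: float = 0.1) -> Var:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)

    def backward(gout):
        _accum(x, np.where(mask, gout, slope * gout))

    return Var(out, (x,), backward)


def concat(xs: list[Var]) -> Var:
    out = np.concatenate([v.data for v in xs], axis=1)
    sizes = [v.data.shape[1] for v in xs]

    def backward(gout):
        start = 0
        for v, s in zip(xs, sizes):
            _accum(v, gout[:, start : start + s])
            start += s

    return Var(out, tuple(xs), backward)


def epe_var(pred: Var, target: NDArray) -> Var:
    """Mean endpoint error between a (N, 2, h, w) prediction node and a target."""
    diff = pred.data - target
    r = np.sqrt(diff[:, 0] ** 2 + diff[:, 1] ** 2 + _EPE_EPS)
    out = r.mean()

    def backward(gout):
        g = diff / r[:, None] / r.size
        _accum(pred, g * gout)

    return Var(out, (pred,), backward)


def weighted_sum(terms: list[Var], weights: list[float]) -> Var:
    out = sum(w * t.data for t, w in zip(terms, weights))

    def backward(gout):
        for t, w in zip(terms, weights):
            _accum(t, np.asarray(gout) * w)

    return Var(out, tuple(terms), backward)


# ----------------------------------------------------------------------------
# architecture


@dataclass
class NetworkConfig:
    """Architecture settings.

    ``base_width`` scales every channel width (64 reproduces the published
    StrainNet-f widths; smaller values give the desk-scale training mode).
    Kernel sizes/strides define the ten feature-extraction layers with their
    four stride-2 down-samplings; the prediction head (five 3x3 prediction
    convolutions, eight 4x4 transposed convolutions, four up-samplings) is
    fixed.  ``div_flow`` is the constant output/target flow scaling.
    """

    base_width: int = 64
    feature_kernels: tuple[int, ...] = (7, 5, 5, 3, 3, 3, 3, 3, 3, 3)
    feature_strides: tuple[int, ...] = (2, 2, 2, 1, 2, 1, 1, 1, 1, 1)
    n_downsamplings: int = 4
    n_upsamplings: int = 4
    input_channels: int = 2
    output_channels: int = 2
    div_flow: float = 2.0
    leaky_slope: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.feature_kernels) != len(self.feature_strides):
            raise ValueError("feature_kernels and feature_strides length mismatch")
        if sum(s == 2 for s in self.feature_strides) != self.n_downsamplings:
            raise ValueError("feature_strides must contain exactly n_downsamplings stride-2 layers")
        if self.n_upsamplings != self.n_downsamplings:
            raise ValueError("full-resolution output requires equal down/up-sampling counts")

    def width(self, w64: int) -> int:
        return max(2, int(w64 * self.base_width // 64))


# published StrainNet-f / FlowNetS channel widths for the ten feature layers
_FEATURE_WIDTHS64 = (64, 128, 256, 256, 512, 512, 512, 512, 1024, 1024)
_DECONV_WIDTHS64 = (128, 64, 32, 16)

SCALED_NETWORK = NetworkConfig(base_width=8)
FULL_NETWORK = NetworkConfig(base_width=64)


class CadeNet:
    """Encoder-decoder displacement network with multi-scale predictions."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.params: list[Var] = []
        self.param_names: list[str] = []
        self._rng = np.random.default_rng(config.seed)
        c = config
        widths = [c.width(w) for w in _FEATURE_WIDTHS64]
        self.feature_defs = []
        cin = c.input_channels
        for i, (k, s, w) in enumerate(zip(c.feature_kernels, c.feature_strides, widths)):
            self.feature_defs.append(
                (self._conv_param(f"conv{i}", w, cin, k), s)
            )
            cin = w
        dw = [c.width(w) for w in _DECONV_WIDTHS64]
        skip = {0: widths[3], 1: widths[1], 2: widths[0], 3: 0}  # encoder skips per level
        self.deconv_defs = []
        self.upflow_defs = []
        self.pred_defs = []
        feat_in = widths[-1]
        self.pred_defs.append(self._conv_param("pred4", c.output_channels, feat_in, 3))
        for lvl in range(4):
            self.deconv_defs.append(self._deconv_param(f"deconv{3 - lvl}", feat_in, dw[lvl]))
            self.upflow_defs.append(
                self._deconv_param(f"upflow{4 - lvl}", c.output_channels, c.output_channels)
            )
            feat_in = skip[lvl] + dw[lvl] + c.output_channels
            self.pred_defs.append(self._conv_param(f"pred{3 - lvl}", c.output_channels, feat_in, 3))

    # -- parameter helpers
    def _register(self, name: str, data: NDArray) -> Var:
        v = Var(data)
        self.params.append(v)
        self.param_names.append(name)
        return v

    def _conv_param(self, name: str, cout: int, cin: int, k: int):
        fan_in = cin * k * k
        w = self._rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
        return (
            self._register(f"{name}.weight", w),
            self._register(f"{name}.bias", np.zeros(cout)),
        )

    def _deconv_param(self, name: str, cin: int, cout: int):
        fan_in = cin * 16
        w = self._rng.standard_normal((cin, cout, 4, 4)) * np.sqrt(2.0 / fan_in)
        return (
            self._register(f"{name}.weight", w),
            self._register(f"{name}.bias", np.zeros(cout)),
        )

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def forward(self, x: NDArray) -> list[Var]:
        """Input (N, 2, H, W) with H, W divisible by 16; returns predictions
        coarsest (1/16) to finest (full resolution) in internal (flow /
        div_flow) units."""
        cfg = self.config
        h, w = x.shape[2:]
        if h % 16 or w % 16:
            raise ValueError("input height/width must be divisible by 16")
        v = Var(x)
        skips: dict[int, Var] = {}
        down = 0
        for i, ((wv, bv), s) in enumerate(self.feature_defs):
            v = leaky_relu(conv2d(v, wv, bv, stride=s), cfg.leaky_slope)
            if s == 2:
                down += 1
            # record the deepest feature at 1/8, 1/4 and 1/2 resolution
            if i in (0, 1, 3):
                skips[i] = v
        preds: list[Var] = []
        wv, bv = self.pred_defs[0]
        preds.append(conv2d(v, wv, bv))
        skip_order = [skips.get(3), skips.get(1), skips.get(0), None]
        feat = v
        for lvl in range(4):
            dwv, dbv = self.deconv_defs[lvl]
            upwv, upbv = self.upflow_defs[lvl]
            up_feat = leaky_relu(conv_transpose2d(feat, dwv, dbv), cfg.leaky_slope)
            up_flow = conv_transpose2d(preds[-1], upwv, upbv)
            parts = [s for s in (skip_order[lvl],) if s is not None] + [up_feat, up_flow]
            feat = concat(parts)
            pwv, pbv = self.pred_defs[lvl + 1]
            preds.append(conv2d(feat, pwv, pbv))
        return preds

    def state_dict(self) -> dict[str, NDArray]:
        return {n: p.data for n, p in zip(self.param_names, self.params)}

    def load_state_dict(self, state: dict[str, NDArray]) -> None:
        for n, p in zip(self.param_names, self.params):
            if state[n].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data = np.asarray(state[n], dtype=np.float64)


def build_network(config: NetworkConfig | None = None) -> CadeNet:
    """Construct the displacement network; deterministic for a given config."""
    return CadeNet(config or NetworkConfig())


# ----------------------------------------------------------------------------
# metrics


@dataclass
class EpeValue:
    value: float
    n_pixels: int

    def __float__(self) -> float:
        return self.value


def _disp_array(d) -> NDArray:
    if isinstance(d, DisplacementField):
        return d.as_array()
    return np.asarray(d, dtype=np.float64)


def epe(prediction, truth) -> EpeValue:
    """Mean endpoint error: average Euclidean norm of the per-pixel error vector."""
    p = _disp_array(prediction)
    t = _disp_array(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    d = p - t
    r = np.sqrt(d[..., 0, :, :] ** 2 + d[..., 1, :, :] ** 2)
    return EpeValue(float(r.mean()), int(r.size))


def _avg_pool(a: NDArray, factor: int) -> NDArray:
    if factor == 1:
        return a
    s = a.shape
    return a.reshape(s[:-2] + (s[-2] // factor, factor, s[-1] // factor, factor)).mean(
        axis=(-3, -1)
    )


def multiscale_loss(predictions_per_scale, truth, weights) -> float:
    """Weighted sum of per-scale mean EPE, coarsest prediction first.

    The truth field (pixel units, shape (..., 2, H, W)) is average-pooled to
    each prediction's resolution; predictions are given in pixel units.
    """
    preds = [np.asarray(p, dtype=np.float64) for p in predictions_per_scale]
    if len(preds) != len(weights):
        raise ValueError("one prediction per weight required")
    t = _disp_array(truth)
    total = 0.0
    for p, w in zip(preds, weights):
        factor = t.shape[-1] // p.shape[-1]
        total += w * epe(p, _avg_pool(t, factor)).value
    return float(total)


# ----------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Adam training hyperparameters (defaults follow the published recipe)."""

    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 350
    weight_decay: float = 0.0004
    bias_decay: float = 0.0
    momentum: float = 0.9  # Adam beta1
    beta: float = 0.999  # Adam beta2
    milestones: tuple[int, ...] = (40, 80, 120, 160, 200, 240)
    milestone_factor: float = 0.5
    multiscale_weights: tuple[float, ...] = (0.005, 0.01, 0.02, 0.08, 0.32)
    workers: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ValueError("milestones must be strictly increasing")
        if len(self.multiscale_weights) != 5:
            raise ValueError("multiscale_weights must have one weight per loss scale (5)")


# desk-scale training mode: small batches give several Adam updates per epoch,
# which converges far faster per unit compute on tiny datasets
SCALED_TRAIN = TrainConfig(epochs=300, batch_size=2, milestones=(220, 270), seed=0)
FULL_TRAIN = TrainConfig()


def normalize_image(a: NDArray) -> NDArray:
    """Per-image standardization to zero mean, unit variance."""
    std = a.std()
    return (a - a.mean()) / (std if std > 0 else 1.0)


def _prepare_inputs(refs: NDArray, sams: NDArray) -> NDArray:
    x = np.stack(
        [np.stack([normalize_image(r), normalize_image(s)]) for r, s in zip(refs, sams)]
    )
    return x


def train(
    model: CadeNet,
    dataset: dict,
    config: TrainConfig | None = None,
    test_dataset: dict | None = None,
    verbose: bool = False,
):
    """Optimize the multiscale EPE loss with Adam.

    ``dataset`` maps "reference"/"sample" to (N, H, W) arrays and
    "displacement" to (N, 2, H, W) ground truth in pixel units.  The learning
    rate is multiplied by ``milestone_factor`` at each milestone epoch;
    weights (not biases) receive L2 decay.  Returns ``(model, history)`` with
    a per-epoch DataFrame of train/test EPE (full-resolution, pixel units).
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    x = _prepare_inputs(dataset["reference"], dataset["sample"])
    t = np.asarray(dataset["displacement"], dtype=np.float64)
    n = x.shape[0]
    div = model.config.div_flow
    scales = [16, 8, 4, 2, 1]
    targets = [_avg_pool(t, f) / div for f in scales]

    m_state = [np.zeros_like(p.data) for p in model.params]
    v_state = [np.zeros_like(p.data) for p in model.params]
    step = 0
    lr = config.learning_rate
    history = []
    for epoch in range(config.epochs):
        if epoch in config.milestones:
            lr *= config.milestone_factor
        order = rng.permutation(n)
        epoch_epe = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            for p in model.params:
                p.zero_grad()
            preds = model.forward(x[idx])
            terms = [epe_var(p, tg[idx]) for p, tg in zip(preds, targets)]
            loss = weighted_sum(terms, list(config.multiscale_weights))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}; "
                    "reduce the learning rate or check the data"
                )
            loss.backward()
            step += 1
            b1, b2 = config.momentum, config.beta
            for i, (p, name) in enumerate(zip(model.params, model.param_names)):
                g = p.grad if p.grad is not None else np.zeros_like(p.data)
                decay = config.bias_decay if name.endswith("bias") else config.weight_decay
                if decay:
                    g = g + decay * p.data
                m_state[i] = b1 * m_state[i] + (1 - b1) * g
                v_state[i] = b2 * v_state[i] + (1 - b2) * g * g
                mhat = m_state[i] / (1 - b1**step)
                vhat = v_state[i] / (1 - b2**step)
                p.data -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            # full-resolution EPE in pixel units
            epoch_epe += epe(preds[-1].data * div, t[idx]).value
            n_batches += 1
        row = {"epoch": epoch, "train_epe": epoch_epe / n_batches, "lr": lr}
        if test_dataset is not None:
            row["test_epe"] = evaluate_epe(model, test_dataset)
        history.append(row)
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch}: train EPE {row['train_epe']:.4f}")
    return model, pd.DataFrame(history)


def evaluate_epe(model: CadeNet, dataset: dict) -> float:
    x = _prepare_inputs(dataset["reference"], dataset["sample"])
    t = np.asarray(dataset["displacement"], dtype=np.float64)
    preds = model.forward(x)
    return epe(preds[-1].data * model.config.div_flow, t).value


def predict(model: CadeNet, reference, sample) -> DisplacementField:
    """Dense displacement prediction for one reference/sample pair.

    Images are standardized per image; shapes not divisible by 16 are
    reflect-padded internally and the output cropped back.
    """
    ref = reference.data if isinstance(reference, SpeckleImage) else np.asarray(reference)
    sam = sample.data if isinstance(sample, SpeckleImage) else np.asarray(sample)
    if ref.shape != sam.shape:
        raise ValueError("reference and sample must have the same shape")
    h, w = ref.shape
    ph = (-h) % 16
    pw = (-w) % 16
    x = _prepare_inputs(ref[None], sam[None])
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    preds = model.forward(x)
    out = preds[-1].data[0] * model.config.div_flow
    out = out[:, :h, :w]
    return DisplacementField(out[0], out[1])


# ----------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: CadeNet, path: str | Path, train_config: TrainConfig | None = None,
                    extra: dict | None = None) -> None:
    path = Path(path)
    meta = {
        "network_config": dataclasses_asdict(model.config),
        "train_config": dataclasses_asdict(train_config) if train_config else None,
        "normalization": "per-image zero mean, unit variance",
        "extra": extra or {},
    }
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> CadeNet:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path,
                 allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        nc = meta["network_config"]
        nc["feature_kernels"] = tuple(nc["feature_kernels"])
        nc["feature_strides"] = tuple(nc["feature_strides"])
        model = CadeNet(NetworkConfig(**nc))
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model


def dataclasses_asdict(cfg) -> dict:
    import dataclasses as _dc

    d = _dc.asdict(cfg)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
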