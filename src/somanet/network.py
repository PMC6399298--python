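"""The residual CNN, its multi-task heads and training loss.

Nine convolutional layers in a compact residual arrangement: an initial
1x3 convolution (64 channels) with batch normalization and width-only
max-pooling, then four shortcut blocks, each a 3x3 convolution + batch
normalization + 5x5 convolution whose output is added to the block input.
Batch normalization and max-pooling sit between the blocks.  Pooling acts
only on the 32-column axis (kernel 3, stride 2, schedule 32->16->8->4->2),
leaving the 5 base rows intact, so the final feature map is 64 x 5 x 2 =
640, fed to a fully connected layer of size 240 and three heads: a 4-way
mutation-type softmax (non-somatic, SNV, insertion, deletion), a 4-way
length-class softmax (0, 1, 2, >=3) and a scalar position regressor
(candidate column / 32) trained with a smooth-L1 loss.  The default
stand-alone configuration has well under 900K trainable parameters.

Implemented directly on NumPy with explicit forward and backward passes.
Convolutions use a shift-and-add decomposition (one channel-axis GEMM per
kernel offset), which is efficient for these small 5 x W feature maps;
activations are kept in NHWC layout internally.  Initialization is
variance-scaled for rectified-linear units and deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

POOL_SCHEDULE = (32, 16, 8, 4, 2)
N_TYPE_CLASSES = 4    # non-somatic, SNV, INS, DEL
N_LENGTH_CLASSES = 4  # 0, 1, 2, >=3
POSITION_SCALE = 32.0


@dataclass(frozen=True)
class NetConfig:
    in_channels: int = 26
    conv_width: int = 64
    fc_size: int = 240
    n_blocks: int = 4
    n_rows: int = 5
    n_cols: int = 32

    def validate(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.final_width < 2:
            raise ValueError(
                f"pooling schedule incompatible with {self.n_cols} columns: "
                f"width collapses below 2 after {self.n_blocks} pools")

    @property
    def n_conv_layers(self) -> int:
        return 1 + 2 * self.n_blocks

    @property
    def final_width(self) -> int:
        w = self.n_cols
        for _ in range(self.n_blocks):
            w = (w + 2 - 3) // 2 + 1
        return w

    @property
    def flat_size(self) -> int:
        return self.conv_width * self.n_rows * self.final_width


def count_parameters_analytic(config: NetConfig) -> int:
    """Closed-form trainable-parameter count of the architecture."""
    c = config.conv_width
    n = 0
    n += config.in_channels * c * 1 * 3 + c          # initial 1x3 conv
    n += 2 * c                                        # bn after initial conv
    per_block = (c * c * 9 + c) + 2 * c + (c * c * 25 + c)
    n += config.n_blocks * per_block                  # 3x3 conv + bn + 5x5 conv
    n += (config.n_blocks - 1) * 2 * c                # inter-block bn
    n += config.flat_size * config.fc_size + config.fc_size
    n += config.fc_size * N_TYPE_CLASSES + N_TYPE_CLASSES
    n += config.fc_size * N_LENGTH_CLASSES + N_LENGTH_CLASSES
    n += config.fc_size * 1 + 1
    return n


# ---------------------------------------------------------------------------
# layers (activations in NHWC)

class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


class Conv2d:
    """Stride-1 'same' convolution via shift-and-add channel GEMMs."""

    def __init__(self, name: str, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator, dtype=np.float32):
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kh, kw))
        self.W = Param(f"{name}.W", W.astype(dtype))
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype=dtype))
        self.kernel = kernel
        self.pad = ((kh - 1) // 2, (kw - 1) // 2)
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, cin = x.shape
        kh, kw = self.kernel
        ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        out_ch = self.W.value.shape[0]
        acc = np.zeros((n * h * w, out_ch), dtype=x.dtype)
        for di in range(kh):
            for dj in range(kw):
                sl = xp[:, di:di + h, dj:dj + w, :].reshape(-1, cin)
                acc += sl @ self.W.value[:, :, di, dj].T
        acc += self.b.value
        if training:
            self._cache = (xp, (n, h, w, cin))
        return acc.reshape(n, h, w, out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (n, h, w, cin) = self._cache
        kh, kw = self.kernel
        ph, pw = self.pad
        out_ch = self.W.value.shape[0]
        dy_flat = dy.reshape(-1, out_ch)
        self.b.grad += dy_flat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                sl = xp[:, di:di + h, dj:dj + w, :].reshape(-1, cin)
                self.W.grad[:, :, di, dj] += dy_flat.T @ sl
                dxp[:, di:di + h, dj:dj + w, :] += (dy_flat @ self.W.value[:, :, di, dj]
                                                    ).reshape(n, h, w, cin)
        self._cache = None
        return dxp[:, ph:ph + h, pw:pw + w, :]


class BatchNorm2d:
    def __init__(self, name: str, ch: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(ch, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(ch, dtype=dtype))
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2), dtype=np.float64)
            var = x.var(axis=(0, 1, 2), dtype=np.float64)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)) * inv
        y = self.gamma.value * xhat + self.beta.value
        if training:
            self._cache = (xhat, inv, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[1] * shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        dx = (inv / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2), keepdims=True)
        )
        self._cache = None
        return dx.astype(dy.dtype)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPoolW:
    """Width-only max pooling on NHWC input: kernel 3, stride 2, padding 1."""

    def __init__(self):
        self._cache = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (0, 0)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=2)[:, :, ::2]
        arg = win.argmax(axis=4)  # (N, H, Wo, C)
        y = np.take_along_axis(win, arg[..., None], axis=4)[..., 0]
        if training:
            self._cache = (arg, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, (n, h, w, c) = self._cache
        wo = dy.shape[2]
        src_w = 2 * np.arange(wo)[None, None, :, None] + arg - 1  # unpadded coords
        base = (np.arange(n)[:, None, None, None] * h * w * c
                + np.arange(h)[None, :, None, None] * w * c
                + np.arange(c)[None, None, None, :])
        flat_idx = (base + src_w * c).ravel()
        dx = np.bincount(flat_idx, weights=dy.ravel().astype(np.float64),
                         minlength=n * h * w * c)
        self._cache = None
        return dx.reshape(n, h, w, c).astype(dy.dtype)


class Linear:
    def __init__(self, name: str, in_f: int, out_f: int, rng: np.random.Generator,
                 dtype=np.float32):
        W = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(out_f, in_f))
        self.W = Param(f"{name}.W", W.astype(dtype))
        self.b = Param(f"{name}.b", np.zeros(out_f, dtype=dtype))
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._cache = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        self._cache = None
        return dy @ self.W.value


class _Block:
    """Shortcut block: out = relu(x + conv5x5(relu(bn(conv3x3(x)))))."""

    def __init__(self, name: str, ch: int, rng, dtype):
        self.conv3 = Conv2d(f"{name}.conv3", ch, ch, (3, 3), rng, dtype)
        self.bn = BatchNorm2d(f"{name}.bn", ch, dtype)
        self.relu1 = ReLU()
        self.conv5 = Conv2d(f"{name}.conv5", ch, ch, (5, 5), rng, dtype)
        self.relu2 = ReLU()

    def parameters(self):
        return self.conv3.parameters() + self.bn.parameters() + self.conv5.parameters()

    def layers(self):
        return [self.conv3, self.bn, self.conv5]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = self.conv3.forward(x, training)
        y = self.bn.forward(y, training)
        y = self.relu1.forward(y, training)
        y = self.conv5.forward(y, training)
        return self.relu2.forward(x + y, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        db = self.conv5.backward(d)
        db = self.relu1.backward(db)
        db = self.bn.backward(db)
        db = self.conv3.backward(db)
        return d + db


@dataclass
class NetworkOutput:
    """Batched multi-task outputs."""

    type_logits: np.ndarray    # (n, 4)
    length_logits: np.ndarray  # (n, 4)
    position: np.ndarray       # (n,)

    @property
    def type_probs(self) -> np.ndarray:
        return softmax(self.type_logits)

    @property
    def length_probs(self) -> np.ndarray:
        return softmax(self.length_logits)

    @property
    def somatic_prob(self) -> np.ndarray:
        return 1.0 - self.type_probs[:, 0]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SomaticNet:
    """The residual CNN over candidate matrices.

    ``forward`` accepts batches shaped (n, channels, 5, 32) as produced by
    the featurizer; layout conversion is internal.
    """

    def __init__(self, config: NetConfig | None = None, seed: int = 0,
                 registry_hash: str = "", dtype=np.float32):
        self.config = config or NetConfig()
        self.config.validate()
        self.registry_hash = registry_hash
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        cfg = self.config
        c = cfg.conv_width
        self.conv1 = Conv2d("conv1", cfg.in_channels, c, (1, 3), rng, dtype)
        self.bn1 = BatchNorm2d("bn1", c, dtype)
        self.relu1 = ReLU()
        self.pool1 = MaxPoolW()
        self.blocks = [_Block(f"block{i}", c, rng, dtype) for i in range(cfg.n_blocks)]
        self.inter_bn = [BatchNorm2d(f"inter_bn{i}", c, dtype) for i in range(cfg.n_blocks - 1)]
        self.inter_pool = [MaxPoolW() for _ in range(cfg.n_blocks - 1)]
        self.fc = Linear("fc", cfg.flat_size, cfg.fc_size, rng, dtype)
        self.fc_relu = ReLU()
        self.head_type = Linear("head_type", cfg.fc_size, N_TYPE_CLASSES, rng, dtype)
        self.head_length = Linear("head_length", cfg.fc_size, N_LENGTH_CLASSES, rng, dtype)
        self.head_position = Linear("head_position", cfg.fc_size, 1, rng, dtype)
        self._flat_shape = None

    # -- plumbing ----------------------------------------------------------

    def _modules(self):
        mods = [self.conv1, self.bn1]
        for b in self.blocks:
            mods.extend(b.layers())
        mods.extend(self.inter_bn)
        mods.extend([self.fc, self.head_type, self.head_length, self.head_position])
        return mods

    def parameters(self) -> list[Param]:
        out = []
        for m in self._modules():
            out.extend(m.parameters())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    @property
    def n_conv_layers(self) -> int:
        return 1 + sum(1 for b in self.blocks for _ in (b.conv3, b.conv5))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    def state_dict(self) -> dict:
        state = {p.name: p.value.copy() for p in self.parameters()}
        for m in self._modules():
            if isinstance(m, BatchNorm2d):
                prefix = m.gamma.name[: -len(".gamma")]
                state[f"{prefix}.running_mean"] = m.running_mean.copy()
                state[f"{prefix}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for m in self._modules():
            if isinstance(m, BatchNorm2d):
                prefix = m.gamma.name[: -len(".gamma")]
                m.running_mean[...] = state[f"{prefix}.running_mean"]
                m.running_var[...] = state[f"{prefix}.running_var"]

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> NetworkOutput:
        cfg = self.config
        if x.ndim != 4 or x.shape[1:] != (cfg.in_channels, cfg.n_rows, cfg.n_cols):
            raise ValueError(
                f"input shape mismatch: expected (n, {cfg.in_channels}, "
                f"{cfg.n_rows}, {cfg.n_cols}), got {tuple(x.shape)}")
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=self.dtype)  # NHWC
        h = self.conv1.forward(h, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.pool1.forward(h, training)
        for i, block in enumerate(self.blocks):
            h = block.forward(h, training)
            if i < len(self.inter_bn):
                h = self.inter_bn[i].forward(h, training)
                h = self.inter_pool[i].forward(h, training)
        self._flat_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        feat = self.fc_relu.forward(self.fc.forward(flat, training), training)
        return NetworkOutput(
            self.head_type.forward(feat, training),
            self.head_length.forward(feat, training),
            self.head_position.forward(feat, training)[:, 0],
        )

    def backward(self, d_type: np.ndarray, d_length: np.ndarray, d_position: np.ndarray) -> None:
        dfeat = (self.head_type.backward(d_type)
                 + self.head_length.backward(d_length)
                 + self.head_position.backward(d_position[:, None]))
        dflat = self.fc.backward(self.fc_relu.backward(dfeat))
        dh = dflat.reshape(self._flat_shape)
        for i in range(len(self.blocks) - 1, -1, -1):
            if i < len(self.inter_bn):
                dh = self.inter_bn[i].backward(self.inter_pool[i].backward(dh))
            dh = self.blocks[i].backward(dh)
        dh = self.pool1.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        self.conv1.backward(dh)


# ---------------------------------------------------------------------------
# loss

def smooth_l1(delta: np.ndarray, transition: float = 1.0) -> np.ndarray:
    a = np.abs(delta)
    return np.where(a < transition, 0.5 * delta ** 2 / transition, a - 0.5 * transition)


def multitask_loss(out: NetworkOutput, type_y: np.ndarray, length_y: np.ndarray,
                   column_y: np.ndarray,
                   type_weights: Sequence[float] | None = None,
                   length_weights: Sequence[float] | None = None,
                   ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted cross-entropy on both classifiers plus smooth-L1 on the
    position; returns (loss, d_type_logits, d_length_logits, d_position).

    Each record's cross-entropy term is scaled by the weight of its true
    class and averaged over the batch, so uniform unit weights reduce
    exactly to the unweighted mean cross-entropy, and doubling the weight
    of a class doubles that class's contribution.
    """
    n = out.type_logits.shape[0]
    tw = np.ones(N_TYPE_CLASSES) if type_weights is None else np.asarray(type_weights, dtype=float)
    lw = np.ones(N_LENGTH_CLASSES) if length_weights is None else np.asarray(length_weights, dtype=float)
    if np.any(tw <= 0) or np.any(lw <= 0):
        raise ValueError("class weights must be positive")

    def ce(logits, y, w):
        p = softmax(logits.astype(np.float64))
        logp = np.log(np.maximum(p[np.arange(n), y], 1e-300))
        wy = w[y]
        loss = float(-(wy * logp).mean())
        dlogits = p
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= wy[:, None] / n
        return loss, dlogits.astype(logits.dtype)

    loss_t, d_t = ce(out.type_logits, type_y, tw)
    loss_l, d_l = ce(out.length_logits, length_y, lw)
    delta = out.position.astype(np.float64) - column_y
    loss_p = float(smooth_l1(delta).mean())
    d_p = (np.clip(delta, -1.0, 1.0) / n).astype(out.position.dtype)
    return loss_t + loss_l + loss_p, d_t, d_l, d_p


class SGD:
    """Plain SGD with classical momentum."""

    def __init__(self, params: list[Param], momentum: float = 0.9):
        self.params = params
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= lr * p.grad
            p.value += v


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(path: str, model: SomaticNet, meta: dict | None = None) -> None:
    state = model.state_dict()
    payload = {f"param/{k}": v for k, v in state.items()}
    payload["config"] = np.array(json.dumps(asdict(model.config)))
    payload["registry_hash"] = np.array(model.registry_hash)
    payload["meta"] = np.array(json.dumps(meta or {}))
    np.savez(path, **payload)


def load_checkpoint(path: str) -> tuple[SomaticNet, dict]:
    with np.load(path, allow_pickle=False) as z:
        config = NetConfig(**json.loads(str(z["config"])))
        registry_hash = str(z["registry_hash"])
        meta = json.loads(str(z["meta"]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model = SomaticNet(config, registry_hash=registry_hash)
    model.load_state_dict(state)
    return model, meta
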