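"""A NumPy R(2+1)D-18 video classifier with training support.

The architecture is the 18-layer residual video network in which every
3D convolution is factorized into a spatial (1x3x3) convolution, batch
normalization and a ReLU, followed by a temporal (3x1x1) convolution.
The factorization inserts an extra rectification inside each
convolution, doubling the nonlinearity count of the equivalent
non-factorized layout.  Unlike the original factorized design, the
intermediate channel count of each (2+1)D unit equals the unit's
output channels rather than the parameter-matching formula, so the
model has strictly fewer parameters than its full-3D counterpart.

Everything — convolutions (im2col + BLAS matmul), batch norm, the
backward pass and the Adam optimizer — is implemented on NumPy arrays,
which is ample for the desk-scale clip sizes this package targets.
Checkpoints are ``.npz`` weight archives with a JSON sidecar holding
the :class:`NetworkSpec`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import VideoClip

Triple = tuple[int, int, int]


@dataclass(frozen=True)
class NetworkSpec:
    widths: tuple[int, ...] = (64, 64, 128, 256, 512)  # stem + 4 stages
    input_shape: Triple = (32, 128, 128)               # T, H, W
    head: str = "softmax"                              # softmax | sigmoid
    n_outputs: int = 2
    tiny: bool = False

    def __post_init__(self) -> None:
        if self.head not in ("softmax", "sigmoid"):
            raise ValueError("head must be 'softmax' or 'sigmoid'")
        if self.n_outputs < 2:
            raise ValueError("need n_outputs >= 2")
        if len(self.widths) != 5:
            raise ValueError("widths = (stem, stage1..stage4)")

    @classmethod
    def default(cls, n_outputs: int, head: str) -> "NetworkSpec":
        return cls(n_outputs=n_outputs, head=head)

    @classmethod
    def make_tiny(cls, n_outputs: int, head: str,
                  input_shape: Triple = (16, 32, 32)) -> "NetworkSpec":
        """Desk-scale variant: reduced widths 8/8/16/32/64, 16x32x32 input."""
        return cls(widths=(8, 8, 16, 32, 64), input_shape=input_shape,
                   head=head, n_outputs=n_outputs, tiny=True)


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


# ---------------------------------------------------------------------------
# layers

class Conv3d:
    """3D convolution with odd kernels and 'same' padding.

    Two equivalent execution strategies: im2col + one big matmul, and a
    sum over kernel offsets of channel-mixing tensordots on strided
    views of the padded input.  The offset sum avoids the large im2col
    gather and is faster for multi-channel inputs with the small
    factorized kernels used here; im2col wins for the single-channel
    stem with its large spatial kernel.
    """

    def __init__(self, cin: int, cout: int, kernel: Triple, stride: Triple,
                 rng: np.random.Generator, name: str = "conv"):
        self.kernel, self.stride = kernel, stride
        self.cin, self.cout = cin, cout
        fan_in = cin * int(np.prod(kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(cout, cin, *kernel)).astype(np.float32)
        self.w = Param(w, name + ".w")
        self.use_offset_sum = cin >= 2
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w]

    def _pad(self) -> Triple:
        return tuple((k - 1) // 2 for k in self.kernel)  # type: ignore[return-value]

    def _out_shape(self, t: int, h: int, w: int) -> Triple:
        (kt, kh, kw), (st, sh, sw) = self.kernel, self.stride
        pt, ph, pw = self._pad()
        return ((t + 2 * pt - kt) // st + 1, (h + 2 * ph - kh) // sh + 1,
                (w + 2 * pw - kw) // sw + 1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pt, ph, pw = self._pad()
        n, cin = x.shape[:2]
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        to, ho, wo = self._out_shape(*x.shape[2:])
        if self.use_offset_sum:
            out = np.zeros((self.cout, n, to, ho, wo), dtype=np.float32)
            for a in range(kt):
                for b in range(kh):
                    for c in range(kw):
                        xs = xp[:, :, a:a + st * to:st, b:b + sh * ho:sh,
                                c:c + sw * wo:sw]
                        out += np.tensordot(self.w.value[:, :, a, b, c], xs,
                                            axes=([1], [1]))
            if train:
                self._cache = (xp, x.shape, (to, ho, wo))
            return np.ascontiguousarray(out.transpose(1, 0, 2, 3, 4))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw),
                                                       axis=(2, 3, 4))
        win = win[:, :, ::st, ::sh, ::sw]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(n * to * ho * wo, -1)
        wmat = self.w.value.reshape(self.cout, -1)
        out = cols @ wmat.T
        out = out.reshape(n, to, ho, wo, -1).transpose(0, 4, 1, 2, 3)
        if train:
            self._cache = (cols, x.shape, (to, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cached, x_shape, (to, ho, wo) = self._cache  # type: ignore[misc]
        self._cache = None
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pt, ph, pw = self._pad()
        n, cin, t, h, w = x_shape
        if self.use_offset_sum:
            xp = cached
            dxp = np.zeros_like(xp)
            for a in range(kt):
                for b in range(kh):
                    for c in range(kw):
                        sl = (slice(None), slice(None),
                              slice(a, a + st * to, st),
                              slice(b, b + sh * ho, sh),
                              slice(c, c + sw * wo, sw))
                        self.w.grad[:, :, a, b, c] += np.tensordot(
                            dy, xp[sl], axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                        dxp[sl] += np.tensordot(
                            self.w.value[:, :, a, b, c], dy,
                            axes=([0], [1])).transpose(1, 0, 2, 3, 4)
            return dxp[:, :, pt:pt + t, ph:ph + h, pw:pw + w]
        cols = cached
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        self.w.grad += (dyr.T @ cols).reshape(self.w.value.shape)
        wmat = self.w.value.reshape(self.cout, -1)
        dcols = (dyr @ wmat).reshape(n, to, ho, wo, cin, kt, kh, kw)
        dxp = np.zeros((n, cin, t + 2 * pt, h + 2 * ph, w + 2 * pw),
                       dtype=np.float32)
        for a in range(kt):
            for b in range(kh):
                for c in range(kw):
                    dxp[:, :, a:a + st * to:st, b:b + sh * ho:sh,
                        c:c + sw * wo:sw] += \
                        dcols[:, :, :, :, :, a, b, c].transpose(0, 4, 1, 2, 3)
        return dxp[:, :, pt:pt + t, ph:ph + h, pw:pw + w]


class BatchNorm3d:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(c, dtype=np.float32), name + ".gamma")
        self.beta = Param(np.zeros(c, dtype=np.float32), name + ".beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * ivar.reshape(shape)
        out = self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)
        if train:
            self._cache = (xhat, ivar)
        return out.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache  # type: ignore[misc]
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        m = dy.size / dy.shape[1]
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        dx = (self.gamma.value.reshape(shape) * ivar.reshape(shape) / m) * (
            m * dy - dbeta.reshape(shape) - xhat * dgamma.reshape(shape))
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def spatiotemporal_conv(cin: int, cout: int, stride: Triple,
                        rng: np.random.Generator, name: str,
                        spatial_kernel: int = 3) -> Sequential:
    """A (2+1)D unit: (1,k,k) conv / BN / ReLU / (3,1,1) conv.

    Intermediate channels equal the output channels (non-increased
    filter count).
    """
    st, sh, sw = stride
    return Sequential([
        Conv3d(cin, cout, (1, spatial_kernel, spatial_kernel), (1, sh, sw),
               rng, name + ".s"),
        BatchNorm3d(cout, name=name + ".sbn"),
        ReLU(),
        Conv3d(cout, cout, (3, 1, 1), (st, 1, 1), rng, name + ".t"),
    ])


class BasicBlock:
    def __init__(self, cin: int, cout: int, stride: Triple,
                 rng: np.random.Generator, name: str):
        self.main = Sequential([
            spatiotemporal_conv(cin, cout, stride, rng, name + ".conv1"),
            BatchNorm3d(cout, name=name + ".bn1"),
            ReLU(),
            spatiotemporal_conv(cout, cout, (1, 1, 1), rng, name + ".conv2"),
            BatchNorm3d(cout, name=name + ".bn2"),
        ])
        # zero-init the residual branch's final scale: each block starts as
        # the identity, which stabilizes training at small widths
        self.main.layers[-1].gamma.value[...] = 0.0
        if cin != cout or stride != (1, 1, 1):
            self.shortcut: Sequential | None = Sequential([
                Conv3d(cin, cout, (1, 1, 1), stride, rng, name + ".down"),
                BatchNorm3d(cout, name=name + ".downbn"),
            ])
        else:
            self.shortcut = None
        self.relu = ReLU()

    def params(self) -> list[Param]:
        ps = self.main.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = self.main.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu.forward(y + s, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu.backward(dy)
        dx = self.main.backward(dy)
        if self.shortcut is None:
            dx = dx + dy
        else:
            dx = dx + self.shortcut.backward(dy)
        return dx


class GlobalAvgPool:
    def __init__(self) -> None:
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, t, h, w = self._shape  # type: ignore[misc]
        scale = 1.0 / (t * h * w)
        return np.broadcast_to(dy[:, :, None, None, None],
                               self._shape).astype(np.float32) * scale


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str = "fc"):
        w = rng.normal(0, np.sqrt(1.0 / cin), size=(cout, cin)).astype(np.float32)
        self.w = Param(w, name + ".w")
        self.b = Param(np.zeros(cout, dtype=np.float32), name + ".b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x  # type: ignore[arg-type]
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value
        self._x = None
        return dx


# ---------------------------------------------------------------------------
# the model

class R2Plus1D:
    """18-layer factorized residual video classifier (NumPy)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3, w4 = spec.widths
        stem_spatial = 7 if not spec.tiny else 5
        self.stem = Sequential([
            Conv3d(1, w0, (1, stem_spatial, stem_spatial), (1, 2, 2), rng, "stem.s"),
            BatchNorm3d(w0, name="stem.sbn"),
            ReLU(),
            Conv3d(w0, w0, (3, 1, 1), (1, 1, 1), rng, "stem.t"),
            BatchNorm3d(w0, name="stem.tbn"),
            ReLU(),
        ])
        blocks: list[BasicBlock] = []
        cin = w0
        for i, (cout, stride) in enumerate(zip(
                (w1, w2, w3, w4),
                ((1, 1, 1), (2, 2, 2), (2, 2, 2), (2, 2, 2)))):
            blocks.append(BasicBlock(cin, cout, stride, rng, f"s{i + 1}b1"))
            blocks.append(BasicBlock(cout, cout, (1, 1, 1), rng, f"s{i + 1}b2"))
            cin = cout
        self.blocks = blocks
        self.pool = GlobalAvgPool()
        self.fc = Linear(w4, spec.n_outputs, rng)

    # -- plumbing -----------------------------------------------------------
    def params(self) -> list[Param]:
        ps = self.stem.params()
        for b in self.blocks:
            ps += b.params()
        ps += self.pool.params() + self.fc.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def modules(self) -> list:
        out: list = []

        def walk(m) -> None:
            out.append(m)
            for attr in ("layers", "blocks"):
                for sub in getattr(m, attr, []):
                    walk(sub)
            for attr in ("main", "shortcut", "relu", "stem", "pool", "fc"):
                sub = getattr(m, attr, None)
                if sub is not None and not isinstance(m, Sequential):
                    walk(sub)

        walk(self)
        return out

    # -- compute ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map a (N, 1, T, H, W) batch to logits (N, n_outputs)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[:, None]
        h = self.stem.forward(x, train)
        for b in self.blocks:
            h = b.forward(h, train)
        return self.fc.forward(self.pool.forward(h, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.fc.backward(dlogits.astype(np.float32))
        dy = self.pool.backward(dy)
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        self.stem.backward(dy)

    def activate(self, logits: np.ndarray) -> np.ndarray:
        if self.spec.head == "softmax":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return 1.0 / (1.0 + np.exp(-logits))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode class scores for a clip batch."""
        return self.activate(self.forward(x, train=False))

    def predict_clip(self, clip: VideoClip) -> np.ndarray:
        scores = self.predict_proba(clip.frames[None])
        return scores[0]

    # -- checkpointing ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"p{i}:{p.name}": p.value for i, p in enumerate(self.params())}
        for i, m in enumerate(m for m in self.modules()
                              if isinstance(m, BatchNorm3d)):
            state[f"bn{i}.mean"] = m.running_mean
            state[f"bn{i}.var"] = m.running_var
        return state

    def save(self, path: str | Path, label_set_name: str | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **self.state_arrays())
        sidecar = {"spec": asdict(self.spec), "label_set": label_set_name}
        with open(path.with_suffix(".json"), "w") as f:
            json.dump(sidecar, f, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> tuple["R2Plus1D", str | None]:
        path = Path(path)
        with open(path.with_suffix(".json")) as f:
            sidecar = json.load(f)
        spec_d = sidecar["spec"]
        spec_d["widths"] = tuple(spec_d["widths"])
        spec_d["input_shape"] = tuple(spec_d["input_shape"])
        model = cls(NetworkSpec(**spec_d))
        with np.load(path) as z:
            for i, p in enumerate(model.params()):
                p.value[...] = z[f"p{i}:{p.name}"]
            for i, m in enumerate(m for m in model.modules()
                                  if isinstance(m, BatchNorm3d)):
                m.running_mean[...] = z[f"bn{i}.mean"]
                m.running_var[...] = z[f"bn{i}.var"]
        return model, sidecar.get("label_set")


def build_model(spec: NetworkSpec, seed: int = 0) -> R2Plus1D:
    return R2Plus1D(spec, seed=seed)


# ---------------------------------------------------------------------------
# closed-form parameter counts (factorized vs full 3D)

def conv_param_counts(spec: NetworkSpec) -> dict[str, int]:
    """Convolution-weight counts of the factorized layout and of the same
    layout with full t x 3 x 3 3D kernels.

    Per unit with C_in -> C_out: factorized (non-increased channels)
    costs 9*C_in*C_out + 3*C_out^2, full 3D costs 27*C_in*C_out (stem:
    k^2*C_in*C_out + 3*C_out^2 vs 3*k^2*C_in*C_out).
    """
    w0, w1, w2, w3, w4 = spec.widths
    k = 7 if not spec.tiny else 5
    fact = k * k * 1 * w0 + 3 * w0 * w0
    full = 3 * k * k * 1 * w0
    cin = w0
    for cout in (w1, w2, w3, w4):
        for blk in range(2):
            c_in_blk = cin if blk == 0 else cout
            for conv_cin in (c_in_blk, cout):
                fact += 9 * conv_cin * cout + 3 * cout * cout
                full += 27 * conv_cin * cout
            if blk == 0 and (c_in_blk != cout or cout != w1):
                fact += c_in_blk * cout  # 1x1x1 projection, same in both
                full += c_in_blk * cout
        cin = cout
    return {"factorized": fact, "full3d": full}


def count_relus(model: R2Plus1D) -> int:
    return sum(isinstance(m, ReLU) for m in model.modules())


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SGD:
    def __init__(self, params: list[Param], lr: float = 1e-3):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad
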