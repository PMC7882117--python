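"""Patch-based CNN that maps 120-kVp CT to pseudo 80- and 140-kVp CT.

The model is a compact three-stage convolutional network trained on 32x32
input patches.  All convolutions are unpadded, and the stage kernels must
satisfy ``sum(kernel - 1) = 14`` so a 32x32 input yields an 18x18 output; one
network emits both pseudo energies as two output channels.  Deep supervision
(DSN) attaches a 1x1 projection head to each hidden stage and adds its MSE
(on the 18x18 center crop) to the final-stage MSE with configurable weights;
optional dense connections feed every stage the center-cropped activations of
all earlier stages plus the input.

Training uses plain SGD with momentum on mini-batches, Xavier-initialized
weights and zero biases.  The implementation is pure numpy (float32, im2col
convolutions) so training runs single-threaded and bit-reproducibly on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .containers import CTImage

__all__ = ["NetConfig", "PatchSet", "Normalization", "TrainState", "Network",
           "extract_patches", "patch_positions", "build_network", "train",
           "predict_full"]

PATCH = 32
TARGET = 18
_BORDER = (PATCH - TARGET) // 2   # 7


@dataclass(frozen=True)
class Normalization:
    """Affine intensity normalization applied to inputs and targets.

    Water-centered by default (HU / 4096): zero-bias ReLU kinks then fall in
    the middle of the tissue intensity range, which is what lets the network
    express the water/iodine bend early in training.  A purely positive
    normalization leaves the initialized network effectively linear over the
    data and the energy mapping converges orders of magnitude slower."""
    shift: float = 0.0
    scale: float = 4096.0

    def forward(self, hu: np.ndarray) -> np.ndarray:
        return ((hu + self.shift) / self.scale).astype(np.float32)

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return x.astype(np.float64) * self.scale - self.shift


@dataclass(frozen=True)
class NetConfig:
    kernels: tuple = (7, 5, 5)
    channels: tuple = (8, 8)            # hidden stage widths
    out_channels: int = 2               # pseudo 80 and 140 kVp
    in_channels: int = 1
    dense: bool = True
    dsn_weights: tuple = (0.15, 0.15, 0.70)

    def __post_init__(self) -> None:
        if sum(k - 1 for k in self.kernels) != PATCH - TARGET:
            raise ValueError(
                f"stage kernels {self.kernels} must satisfy sum(k-1) == "
                f"{PATCH - TARGET} so that {PATCH}x{PATCH} maps to {TARGET}x{TARGET}")
        if len(self.channels) != len(self.kernels) - 1:
            raise ValueError("need one hidden width per non-final stage")
        if len(self.dsn_weights) != len(self.kernels):
            raise ValueError("one DSN weight per stage")
        if any(w < 0 for w in self.dsn_weights):
            raise ValueError("DSN weights must be non-negative")
        if abs(sum(self.dsn_weights) - 1.0) > 1e-9:
            raise ValueError("DSN weights must sum to 1")

    @property
    def n_stages(self) -> int:
        return len(self.kernels)


@dataclass
class PatchSet:
    x: np.ndarray          # (N, 1, 32, 32) normalized 120-kVp inputs
    y: np.ndarray          # (N, 2, 18, 18) normalized 80/140 targets
    stride: int
    source_ids: np.ndarray
    norm: Normalization = field(default_factory=Normalization)

    def __post_init__(self) -> None:
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("input/target counts differ")
        if self.x.shape[2:] != (PATCH, PATCH) or self.y.shape[2:] != (TARGET, TARGET):
            raise ValueError("unexpected patch geometry")

    def __len__(self) -> int:
        return self.x.shape[0]


@dataclass
class TrainState:
    iterations: int
    loss_history: np.ndarray      # (iterations,) total loss
    stage_losses: np.ndarray      # (iterations, n_stages)
    seed: int


def patch_positions(n: int, stride: int, jitter: int = 0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Top-left patch positions along one axis: floor((n - 32)/stride) + 1
    deterministic grid points, optionally jittered by <= jitter pixels."""
    if n < PATCH:
        raise ValueError(f"image axis {n} shorter than the {PATCH}-pixel patch")
    pos = np.arange(0, n - PATCH + 1, stride)
    if jitter:
        if jitter > stride // 2:
            raise ValueError("jitter must not exceed stride/2")
        pos = np.clip(pos + rng.integers(-jitter, jitter + 1, pos.size),
                      0, n - PATCH)
    return pos


def extract_patches(triples: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                    stride: int = 14, jitter: int = 0, seed: int = 0,
                    norm: Normalization = Normalization()) -> PatchSet:
    """Paired patches from co-registered (120, 80, 140) kVp HU slices.

    Targets are the exact 18x18 center crops of each 32x32 input footprint in
    the 80- and 140-kVp slices."""
    rng = np.random.default_rng(seed)
    xs, ys, ids = [], [], []
    for sid, (img120, img80, img140) in enumerate(triples):
        arrs = [np.asarray(a) for a in (img120, img80, img140)]
        if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
            raise ValueError(f"slice triple {sid} is not co-registered")
        ny, nx = arrs[0].shape
        for i in patch_positions(ny, stride, jitter, rng):
            for j in patch_positions(nx, stride, jitter, rng):
                xs.append(norm.forward(arrs[0][i:i + PATCH, j:j + PATCH]))
                ti, tj = i + _BORDER, j + _BORDER
                ys.append(np.stack(
                    [norm.forward(a[ti:ti + TARGET, tj:tj + TARGET])
                     for a in arrs[1:]]))
                ids.append(sid)
    x = np.stack(xs)[:, None]
    y = np.stack(ys)
    return PatchSet(x, y, stride, np.array(ids), norm)


# ---------------------------------------------------------------------------
# Convolution primitives (im2col, float32)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _im2col_kernel(x, k, buf):  # pragma: no cover
    bb, h, wdt, c = x.shape
    hh = h - k + 1
    ww = wdt - k + 1
    for b in range(bb):
        for y in range(hh):
            for xx in range(ww):
                row = (b * hh + y) * ww + xx
                col = 0
                for i in range(k):
                    for j in range(k):
                        for ch in range(c):
                            buf[row, col] = x[b, y + i, xx + j, ch]
                            col += 1


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Channels-last im2col: (B, H, W, C) -> (B*H'*W', k*k*C), row order
    (i, j, c), so the GEMM weight operand is a plain ``w.reshape``."""
    bb, h, wdt, c = x.shape
    hh, ww = h - k + 1, wdt - k + 1
    buf = np.empty((bb * hh * ww, k * k * c), dtype=np.float32)
    _im2col_kernel(np.ascontiguousarray(x, dtype=np.float32), k, buf)
    return buf


def _conv_forward(x, w, b):
    """Unpadded convolution on channels-last activations.

    ``x``: (B, H, W, C); ``w``: (k, k, C, F); returns ((B, H', W', F), cols)
    with the im2col operand cached for the weight gradient."""
    k = w.shape[0]
    bb, h, wdt, c = x.shape
    hh, ww = h - k + 1, wdt - k + 1
    cols = _im2col(x, k)
    out = cols @ w.reshape(-1, w.shape[3]) + b
    return out.reshape(bb, hh, ww, -1), cols


def _conv_backward(dy, cols, w, need_dx=True):
    """Gradients of :func:`_conv_forward`; dx via the transposed convolution
    (full correlation with the rotated kernel), matmul-only."""
    k, _, c, f = w.shape
    bb, hh, ww, _ = dy.shape
    dymat = dy.reshape(bb * hh * ww, f)
    dw = (cols.T @ dymat).reshape(w.shape)
    db = dymat.sum(axis=0)
    if not need_dx:
        return None, dw, db
    pad = k - 1
    dyp = np.zeros((bb, hh + 2 * pad, ww + 2 * pad, f), dtype=np.float32)
    dyp[:, pad:pad + hh, pad:pad + ww, :] = dy
    wrot = np.ascontiguousarray(
        w[::-1, ::-1].transpose(0, 1, 3, 2)).reshape(k * k * f, c)
    dx = (_im2col(dyp, k) @ wrot).reshape(bb, hh + pad, ww + pad, c)
    return dx, dw, db


def _crop(x: np.ndarray, size: int) -> np.ndarray:
    # channels-last center crop
    off = (x.shape[1] - size) // 2
    return x[:, off:off + size, off:off + size, :]


def _pad_grad(dy: np.ndarray, size: int) -> np.ndarray:
    # adjoint of _crop
    out = np.zeros((dy.shape[0], size, size, dy.shape[3]), dtype=np.float32)
    off = (size - dy.shape[1]) // 2
    out[:, off:off + dy.shape[1], off:off + dy.shape[2], :] = dy
    return out


def _xavier(rng, f, c, k):
    # Glorot-uniform; weights stored channels-last as (k, k, C, F)
    bound = np.sqrt(6.0 / (c * k * k + f * k * k))
    return rng.uniform(-bound, bound, size=(k, k, c, f)).astype(np.float32)


class Network:
    """Three-stage unpadded CNN with optional dense connections and DSN heads."""

    def __init__(self, config: NetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        widths = list(config.channels) + [config.out_channels]
        self.stage_in: list[int] = []
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        feats = [config.in_channels]
        for s, k in enumerate(config.kernels):
            cin = sum(feats) if config.dense else feats[-1]
            self.stage_in.append(cin)
            self.weights.append(_xavier(rng, widths[s], cin, k))
            self.biases.append(np.zeros(widths[s], dtype=np.float32))
            feats.append(widths[s])
        self.head_w: list[np.ndarray] = []
        self.head_b: list[np.ndarray] = []
        for s in range(config.n_stages - 1):
            self.head_w.append(_xavier(rng, config.out_channels, widths[s], 1))
            self.head_b.append(np.zeros(config.out_channels, dtype=np.float32))

    # -- forward ----------------------------------------------------------

    def _stage_input(self, feats: list[np.ndarray], size: int) -> np.ndarray:
        if self.config.dense:
            return np.concatenate([_crop(f, size) for f in feats], axis=-1)
        return _crop(feats[-1], size)

    def forward(self, x: np.ndarray, want_aux: bool = False):
        """Map (B, 1, n, n) to channels-last (B, n-14, n-14, 2); optionally
        return the DSN head predictions cropped to the final spatial size."""
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=np.float32)
        feats = [x]
        size = x.shape[1]
        cache = {"cols": [], "pre": [], "feats": feats}
        for s, k in enumerate(self.config.kernels):
            inp = self._stage_input(feats, size)
            z, cols = _conv_forward(inp, self.weights[s], self.biases[s])
            a = np.maximum(z, 0.0) if s < self.config.n_stages - 1 else z
            cache["cols"].append(cols)
            cache["pre"].append(z)
            feats.append(a)
            size = size - (k - 1)
        final = feats[-1]
        if not want_aux:
            return final, cache
        aux = []
        for s in range(self.config.n_stages - 1):
            p, hcols = _conv_forward(feats[s + 1], self.head_w[s], self.head_b[s])
            aux.append((_crop(p, final.shape[1]), p.shape[1], hcols))
        return final, aux, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, n, n) -> (B, 2, n-14, n-14)."""
        return self.forward(x)[0].transpose(0, 3, 1, 2)

    # -- loss and gradients ----------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Weighted DSN loss and gradients for every parameter.

        Per stage the objective is a Euclidean (spatial-sum) loss,
        ``sum(diff^2) / (8 * B * C_out)``, i.e. squared error summed over the
        output pixels, averaged over batch and output channels, with a
        constant fixed once so that SGD at the standard settings (lr 0.01,
        momentum 0.9, batch 128) sits just inside the stable regime on
        water-centered normalized CT intensities.  The step size of SGD is
        the product of the learning rate and the loss scaling, and only the
        former is conventionally reported; a per-pixel-mean MSE would make
        the same learning rate take steps hundreds of times smaller and the
        energy mapping would need orders of magnitude more iterations.  The
        returned total is the DSN-weighted sum of stage objectives;
        ``stage_losses`` logs per-pixel MSEs for readability.
        ``y``: (B, 2, 18, 18)."""
        cfg = self.config
        final, aux, cache = self.forward(x, want_aux=True)
        yc = np.ascontiguousarray(y.transpose(0, 2, 3, 1), dtype=np.float32)
        w_stages = cfg.dsn_weights
        stage_losses = np.zeros(cfg.n_stages)
        d_feats = [np.zeros_like(f) for f in cache["feats"]]
        g_w = [np.zeros_like(w) for w in self.weights]
        g_b = [np.zeros_like(b) for b in self.biases]
        g_hw = [np.zeros_like(w) for w in self.head_w]
        g_hb = [np.zeros_like(b) for b in self.head_b]

        batch = final.shape[0]
        denom = 4 * batch * cfg.out_channels
        stage_obj = np.zeros(cfg.n_stages)
        diff = final - yc
        stage_losses[-1] = float(np.mean(diff ** 2))
        stage_obj[-1] = float((diff ** 2).sum()) / (2 * denom)
        d_feats[-1] += (w_stages[-1] / denom) * diff

        for s in range(cfg.n_stages - 1):
            pred, full_size, hcols = aux[s]
            adiff = pred - yc
            stage_losses[s] = float(np.mean(adiff ** 2))
            stage_obj[s] = float((adiff ** 2).sum()) / (2 * denom)
            if w_stages[s] == 0.0:
                continue
            dpred = (w_stages[s] / denom) * adiff
            dfull = _pad_grad(dpred.astype(np.float32), full_size)
            dfeat, dw, db = _conv_backward(dfull, hcols, self.head_w[s])
            g_hw[s] += dw
            g_hb[s] += db
            d_feats[s + 1] += dfeat

        # backprop through stages, last to first; the gradient with respect
        # to the network input is never needed, so stage 1 skips it
        for s in range(cfg.n_stages - 1, -1, -1):
            da = d_feats[s + 1]
            z = cache["pre"][s]
            dz = da if s == cfg.n_stages - 1 else da * (z > 0)
            dinp, dw, db = _conv_backward(dz.astype(np.float32),
                                          cache["cols"][s], self.weights[s],
                                          need_dx=s > 0)
            g_w[s] += dw
            g_b[s] += db
            if dinp is None:
                continue
            if cfg.dense:
                c0 = 0
                for t, f in enumerate(cache["feats"][:s + 1]):
                    c = f.shape[-1]
                    d_feats[t] += _pad_grad(dinp[..., c0:c0 + c], f.shape[1])
                    c0 += c
            else:
                d_feats[s] += _pad_grad(dinp, cache["feats"][s].shape[1])

        total = float(np.dot(w_stages, stage_obj))
        grads = {"w": g_w, "b": g_b, "hw": g_hw, "hb": g_hb}
        return total, stage_losses, grads

    # -- persistence ------------------------------------------------------

    def params(self):
        return {"w": self.weights, "b": self.biases,
                "hw": self.head_w, "hb": self.head_b}

    def save(self, path: str | Path, norm: Normalization = Normalization()) -> None:
        arrays = {}
        for key, lst in self.params().items():
            for i, arr in enumerate(lst):
                arrays[f"{key}{i}"] = arr
        cfg = self.config
        header = {"kernels": cfg.kernels, "channels": cfg.channels,
                  "out_channels": cfg.out_channels, "in_channels": cfg.in_channels,
                  "dense": cfg.dense, "dsn_weights": cfg.dsn_weights,
                  "norm_shift": norm.shift, "norm_scale": norm.scale}
        np.savez(Path(path), header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["Network", Normalization]:
        data = np.load(Path(path) if str(path).endswith(".npz")
                       else Path(str(path) + ".npz"))
        h = json.loads(str(data["header"]))
        cfg = NetConfig(tuple(h["kernels"]), tuple(h["channels"]),
                        h["out_channels"], h["in_channels"], h["dense"],
                        tuple(h["dsn_weights"]))
        net = cls(cfg, seed=0)
        for key, lst in net.params().items():
            for i in range(len(lst)):
                lst[i][...] = data[f"{key}{i}"]
        return net, Normalization(h["norm_shift"], h["norm_scale"])


def build_network(config: NetConfig = NetConfig(), seed: int = 0) -> Network:
    """Xavier-initialized network (biases zero), deterministic in the seed."""
    return Network(config, seed)


def train(network: Network, patchset: PatchSet, iters: int, *, lr: float = 0.01,
          momentum: float = 0.9, batch: int = 128, seed: int = 0,
          log_every: int = 1, callback=None) -> TrainState:
    """SGD-with-momentum training on mini-batches drawn with replacement.

    Aborts if the loss exceeds 1000x its initial value (divergence guard).
    """
    if len(patchset) == 0:
        raise ValueError("empty patch set")
    rng = np.random.default_rng(seed)
    params = network.params()
    vel = {k: [np.zeros_like(a) for a in lst] for k, lst in params.items()}
    losses, stagelosses = [], []
    initial = None
    for it in range(iters):
        idx = rng.integers(0, len(patchset), size=min(batch, len(patchset)))
        total, per_stage, grads = network.loss_and_grads(patchset.x[idx],
                                                         patchset.y[idx])
        if initial is None:
            initial = max(total, 1e-12)
        if not np.isfinite(total) or total > 1e3 * initial:
            raise RuntimeError(f"training diverged at iteration {it}: "
                               f"loss {total:.3e} vs initial {initial:.3e}")
        for key, lst in params.items():
            for i, p in enumerate(lst):
                v = vel[key][i]
                v *= momentum
                v -= lr * grads[key][i]
                p += v
        losses.append(total)
        stagelosses.append(per_stage)
        if callback is not None and (it + 1) % log_every == 0:
            callback(it + 1, total)
    return TrainState(iters, np.array(losses), np.array(stagelosses), seed)


def predict_full(network: Network, image_120: CTImage,
                 norm: Normalization = Normalization(), stride: int = TARGET
                 ) -> tuple[CTImage, CTImage]:
    """Slide the network over a full 120-kVp slice and tile the 18x18 outputs
    (averaging overlaps); the 7-pixel border is handled by reflect-padding."""
    ny, nx = image_120.shape
    if ny < PATCH or nx < PATCH:
        raise ValueError("image smaller than one patch")
    x = norm.forward(image_120.values)
    xp = np.pad(x, _BORDER, mode="reflect")
    acc = np.zeros((2, ny, nx), dtype=np.float64)
    cnt = np.zeros((ny, nx), dtype=np.float64)

    def axis_positions(n_pad):
        pos = list(range(0, n_pad - PATCH + 1, stride))
        if pos[-1] != n_pad - PATCH:
            pos.append(n_pad - PATCH)
        return pos

    rows = axis_positions(xp.shape[0])
    cols = axis_positions(xp.shape[1])
    batch = []
    coords = []
    for i in rows:
        for j in cols:
            batch.append(xp[i:i + PATCH, j:j + PATCH])
            coords.append((i, j))
    out = network.predict(np.stack(batch)[:, None])
    for (i, j), o in zip(coords, out):
        acc[:, i:i + TARGET, j:j + TARGET] += o
        cnt[i:i + TARGET, j:j + TARGET] += 1.0
    hu = norm.inverse(acc / cnt[None])
    meta = dict(image_120.meta)
    meta["provenance"] = "pseudo-DECT"
    p80 = CTImage(hu[0], image_120.spacing, "HU", "80", dict(meta))
    p140 = CTImage(hu[1], image_120.spacing, "HU", "140Sn", dict(meta))
    return p80, p140
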