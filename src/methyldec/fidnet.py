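"""Gated dilated convolutional networks for FID enhancement.

Two networks are used by the pipeline: a 13C network that removes one
13C-13C scalar-coupling modulation per signal and sharpens peaks, and a 1H
network that only sharpens.  Both share one architecture: a stack of
residual units, one per entry of the dilation schedule.  Each unit applies
a dilated convolution (kernel 8 along time x 4 across the packed rows)
producing 2F channels, splits them in half through sigmoid and tanh
activations whose elementwise product gates the unit, and passes the gated
output through a second 8 x 4 convolution with F output channels.  The
second convolution's output is (i) accumulated into a skip aggregate that a
final 1 x 1 convolution maps to the output plane and (ii) added to the
unit's input to form the next unit's input.

The training loss is the mean squared error between the Fourier transforms
of the predicted and target planes (rows 0/1 unpacked to a complex vector;
both quadratures compared).  Optimisation is RMSprop with a two-phase
schedule: the
initial learning rate holds until the validation loss plateaus, is then
reduced once, and training stops at the second plateau.

Everything here is plain numpy (float32): forward, backward and the
optimiser.  The implementation favours im2col + BLAS matmuls, which keeps
the reduced configurations trainable on a single CPU core.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simkit import PACKING

_EPS = 1e-7


class TrainingDivergedError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ModelConfig:
    input_length: int
    dilations: tuple
    filters_per_layer: int
    n_rows: int = 4
    kernel: tuple = (8, 4)        # (time, rows)

    def __post_init__(self) -> None:
        if self.n_rows != 4:
            raise ValueError("the packing uses 4 rows")
        if not self.dilations or any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be positive")
        if list(self.dilations) != sorted(self.dilations):
            raise ValueError("dilations must be non-decreasing within a cycle")
        if self.filters_per_layer < 2 or self.filters_per_layer % 2:
            raise ValueError("filters_per_layer must be an even count >= 2")

    @classmethod
    def default_c13(cls) -> "ModelConfig":
        return cls(
            input_length=1024,
            dilations=(1, 2, 4, 6, 8, 10, 12, 14, 16, 20, 24, 28, 32, 40, 48, 56, 64),
            filters_per_layer=128,
        )

    @classmethod
    def default_h1(cls) -> "ModelConfig":
        return cls(
            input_length=512,
            dilations=(1, 2, 4, 6, 8, 10, 12, 14, 16, 20, 24, 28, 32),
            filters_per_layer=64,
        )


@dataclass
class TrainConfig:
    optimiser: str = "rmsprop"
    lr_initial: float = 1e-4
    lr_reduced: float = 1e-5
    plateau_patience: int = 5
    min_delta: float = 1e-6
    batch_size: int = 32
    max_epochs: int = 200
    rho: float = 0.9
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimiser != "rmsprop":
            raise ValueError("only rmsprop is supported")
        if self.lr_reduced >= self.lr_initial:
            raise ValueError("lr_reduced must be < lr_initial")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")


# ----------------------------------------------------------------------
# Convolution primitives (channels-last: arrays are (B, H, L, C))
# ----------------------------------------------------------------------
def _same_pads(kernel: tuple, dilation: int) -> tuple:
    kw, kh = kernel
    ke = (kw - 1) * dilation + 1
    pw = (ke - 1) // 2
    ph = (kh - 1) // 2
    return (ph, kh - 1 - ph, pw, ke - 1 - pw)


def conv2d_same(x, w, b, dilation):
    """'same'-padded dilated 2D convolution with bias.

    x: (B, H, L, Cin); w: (KH, KW, Cin, Cout) with KW along time.  The
    channels-last im2col keeps every gather contiguous and reduces the
    convolution to one BLAS matmul, which is what makes CPU training of
    the reduced configurations practical.  Returns (out, im2col matrix);
    the latter is cached for the backward pass.
    """
    ph_l, ph_r, pw_l, pw_r = _same_pads((w.shape[1], w.shape[0]), dilation)
    kh, kw, cin, cout = w.shape
    bsz, h, l = x.shape[:3]
    xp = np.pad(x, ((0, 0), (ph_l, ph_r), (pw_l, pw_r), (0, 0)))
    x2 = np.empty((bsz, h, l, kh, kw, cin), dtype=x.dtype)
    for r in range(kh):
        for k in range(kw):
            kd = k * dilation
            x2[:, :, :, r, k, :] = xp[:, r : r + h, kd : kd + l, :]
    x2 = x2.reshape(bsz * h * l, kh * kw * cin)
    out = x2 @ w.reshape(-1, cout)
    return out.reshape(bsz, h, l, cout) + b, x2


def conv2d_same_backward(x2, w, dilation, dout, in_shape):
    """Gradients of :func:`conv2d_same` given the cached im2col matrix."""
    kh, kw, cin, cout = w.shape
    ph_l, ph_r, pw_l, pw_r = _same_pads((kw, kh), dilation)
    bsz, h, l = in_shape[:3]
    dout2 = dout.reshape(-1, cout)
    dw = (x2.T @ dout2).reshape(w.shape)
    db = dout2.sum(axis=0)
    # scatter-add the im2col gradient back onto the padded input grid
    dx2 = (dout2 @ w.reshape(-1, cout).T).reshape(bsz, h, l, kh, kw, cin)
    dxp = np.zeros(
        (bsz, h + kh - 1, l + (kw - 1) * dilation, cin), dtype=dout.dtype
    )
    for r in range(kh):
        for k in range(kw):
            kd = k * dilation
            dxp[:, r : r + h, kd : kd + l, :] += dx2[:, :, :, r, k, :]
    return dxp[:, ph_l : ph_l + h, pw_l : pw_l + l, :], dw, db


def _sigmoid(x):
    from scipy.special import expit

    return expit(x)


# ----------------------------------------------------------------------
# Spectral loss
# ----------------------------------------------------------------------
def spectral_loss(pred, target, return_grad: bool = False):
    """Frequency-domain MSE between packed planes.

    Planes of shape (..., 4, L) are unpacked to complex vectors (rows 0/1),
    Fourier transformed, and the mean squared modulus of the complex
    frequency-domain difference is returned (averaged over batch and
    grid).  Both quadratures enter the loss: matching only the absorptive
    component would leave an L-dimensional null space (anticausal
    admixtures with zero real spectrum) through which a network can emit
    sideband artefacts that the magnitude spectrum still shows.

    With ``return_grad=True`` the gradient with respect to ``pred`` is also
    returned (zero on the shifted-copy rows, which the loss does not see).
    By Parseval the gradient is proportional to the time-domain residual.
    """
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    dv = (pred[..., 0, :] - target[..., 0, :]) + 1j * (
        pred[..., 1, :] - target[..., 1, :]
    )
    err = np.fft.fft(dv, axis=-1)
    loss = float(np.mean(err.real ** 2 + err.imag ** 2))
    if not return_grad:
        return loss
    n = dv.shape[-1]
    scale = 2.0 * n / err.size
    grad = np.zeros_like(pred)
    grad[..., 0, :] = scale * dv.real
    grad[..., 1, :] = scale * dv.imag
    return loss, grad


# ----------------------------------------------------------------------
# Network
# ----------------------------------------------------------------------
class GatedConvNet:
    """Stacked gated dilated-convolution residual network (see module docs)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.input_length = cfg.input_length
        self.dtype = np.dtype(dtype)
        f = cfg.filters_per_layer
        kw, kh = cfg.kernel
        rng = np.random.default_rng(seed)

        def glorot(*shape):
            # weights are (KH, KW, Cin, Cout); fan counts over the kernel
            fan_in = int(np.prod(shape[:-1]))
            fan_out = int(np.prod(shape[:-2])) * shape[-1]
            std = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.normal(0.0, std, size=shape).astype(dtype)

        self.params: dict[str, np.ndarray] = {
            "w_in": glorot(1, f),
            "b_in": np.zeros(f, self.dtype),
            "w_out": glorot(f, 1),
            "b_out": np.zeros(1, self.dtype),
        }
        for i, _ in enumerate(cfg.dilations):
            self.params[f"u{i}_w1"] = glorot(kh, kw, f, 2 * f)
            self.params[f"u{i}_b1"] = np.zeros(2 * f, self.dtype)
            self.params[f"u{i}_w2"] = glorot(kh, kw, f, f)
            self.params[f"u{i}_b2"] = np.zeros(f, self.dtype)

    @property
    def n_units(self) -> int:
        return len(self.cfg.dilations)

    # ------------------------------------------------------------------
    def forward(self, planes: np.ndarray, want_cache: bool = False):
        """planes (B, 4, L) -> output (B, 4, L)."""
        if planes.ndim != 3 or planes.shape[1] != 4:
            raise ValueError("expected a batch of 4-row planes")
        if planes.shape[2] != self.input_length:
            raise ValueError(
                f"plane length {planes.shape[2]} != input_length {self.input_length}"
            )
        p = self.params
        f = self.cfg.filters_per_layer
        x = np.ascontiguousarray(planes.astype(self.dtype).transpose(0, 2, 1))
        x = x[..., None]  # (B, 4, L, 1) -> rows x time x channel
        h = x @ p["w_in"] + p["b_in"]
        skip = np.zeros_like(h)
        cache = {"x0": x, "h": []} if want_cache else None
        for i, d in enumerate(self.cfg.dilations):
            u, col1 = conv2d_same(h, p[f"u{i}_w1"], p[f"u{i}_b1"], d)
            sa = _sigmoid(u[..., :f])
            tb = np.tanh(u[..., f:])
            g = sa * tb
            z, col2 = conv2d_same(g, p[f"u{i}_w2"], p[f"u{i}_b2"], 1)
            skip += z
            if want_cache:
                cache["h"].append((col1, sa, tb, col2, h.shape))
            h = h + z
        y = skip @ p["w_out"] + p["b_out"]
        out = np.ascontiguousarray(y[..., 0].transpose(0, 2, 1))  # (B, 4, L)
        if want_cache:
            cache["skip"] = skip
            return out, cache
        return out

    # ------------------------------------------------------------------
    def backward(self, cache, dout: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of all parameters given d(loss)/d(output plane)."""
        p = self.params
        f = self.cfg.filters_per_layer
        dy = dout.astype(self.dtype).transpose(0, 2, 1)[..., None]  # (B,4,L,1)
        grads: dict[str, np.ndarray] = {}
        skip = cache["skip"]
        grads["w_out"] = np.tensordot(skip, dy, axes=([0, 1, 2], [0, 1, 2]))
        grads["b_out"] = dy.sum(axis=(0, 1, 2))
        dskip = dy @ p["w_out"].T
        dh = np.zeros_like(dskip)  # gradient wrt the unit input stream
        for i in reversed(range(self.n_units)):
            d = self.cfg.dilations[i]
            col1, sa, tb, col2, h_shape = cache["h"][i]
            dz = dskip + dh
            dg, dw2, db2 = conv2d_same_backward(
                col2, p[f"u{i}_w2"], 1, dz, h_shape
            )
            grads[f"u{i}_w2"], grads[f"u{i}_b2"] = dw2, db2
            du = np.concatenate(
                [dg * tb * sa * (1.0 - sa), dg * sa * (1.0 - tb * tb)], axis=-1
            )
            dx_unit, dw1, db1 = conv2d_same_backward(
                col1, p[f"u{i}_w1"], d, du, h_shape
            )
            grads[f"u{i}_w1"], grads[f"u{i}_b1"] = dw1, db1
            dh = dh + dx_unit
        grads["w_in"] = np.tensordot(cache["x0"], dh, axes=([0, 1, 2], [0, 1, 2]))
        grads["b_in"] = dh.sum(axis=(0, 1, 2))
        return grads

    # ------------------------------------------------------------------
    def apply(self, planes: np.ndarray) -> np.ndarray:
        """Normalised inference on a batch of planes (see apply_network)."""
        return apply_network(self, planes)

    # ------------------------------------------------------------------
    def sidecar(self) -> dict:
        return {
            "model_config": dataclasses.asdict(self.cfg),
            "packing": PACKING,
            "skip_source": "second-convolution output",
            "gating": "2F channels split F/F into sigmoid/tanh, multiplied",
        }

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path, **self.params)
        path.with_suffix(".json").write_text(json.dumps(self.sidecar(), indent=1))

    @classmethod
    def load(cls, path) -> "GatedConvNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if sidecar.get("packing") != PACKING:
            raise ValueError(
                "weight sidecar declares a different packing convention; refusing"
            )
        mc = sidecar["model_config"]
        mc["dilations"] = tuple(mc["dilations"])
        mc["kernel"] = tuple(mc["kernel"])
        net = cls(ModelConfig(**mc))
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            net.params = {k: z[k] for k in z.files}
        return net


class IdentityNetwork:
    """Pass-through stand-in network (debugging / reference processing)."""

    input_length: int | None = None

    def apply(self, planes: np.ndarray) -> np.ndarray:
        return planes


def apply_network(net, planes: np.ndarray) -> np.ndarray:
    """Deterministic batched inference with per-plane normalisation.

    Planes shorter than the network input length are zero-filled; longer
    planes are rejected (truncate or band-select the vectors before calling,
    e.g. by frequency-domain extraction of the region of interest).
    The per-plane scale applied on entry is inverted on exit.
    """
    if isinstance(net, IdentityNetwork):
        return net.apply(planes)
    if planes.ndim == 2:
        return apply_network(net, planes[None])[0]
    b, rows, l = planes.shape
    if rows != 4:
        raise ValueError("expected 4-row planes")
    if l > net.input_length:
        raise ValueError(
            f"plane length {l} exceeds network input length {net.input_length}; "
            "truncate the vectors (policy: band-select then crop) before applying"
        )
    if l < net.input_length:
        planes = np.pad(planes, ((0, 0), (0, 0), (0, net.input_length - l)))
    scale = np.abs(planes).max(axis=(1, 2))
    scale[scale == 0] = 1.0
    out = net.forward((planes / scale[:, None, None]).astype(np.float32))
    return out * scale[:, None, None]


# ----------------------------------------------------------------------
# Training
# ----------------------------------------------------------------------
def train(
    net: GatedConvNet,
    dataset,
    cfg: TrainConfig,
    verbose: bool = False,
) -> dict:
    """Train a network with RMSprop and the two-phase plateau schedule.

    ``dataset`` is ``((x_train, y_train), (x_val, y_val))`` of packed planes
    (N, 4, L) in the network's packing, already normalised per pair.
    Returns a history dict with per-epoch train/validation losses, the
    learning-rate trace and reduction events.  Raises
    :class:`TrainingDivergedError` on NaN loss.
    """
    (xt, yt), (xv, yv) = dataset
    xt = np.asarray(xt, np.float32)
    yt = np.asarray(yt, np.float32)
    xv = np.asarray(xv, np.float32)
    yv = np.asarray(yv, np.float32)
    rng = np.random.default_rng(cfg.seed)
    state = {k: np.zeros_like(v) for k, v in net.params.items()}
    mom = {k: np.zeros_like(v) for k, v in net.params.items()}
    lr = cfg.lr_initial
    phase = 0
    best = np.inf
    stall = 0
    history = {"train_loss": [], "val_loss": [], "lr": [], "lr_events": []}
    n = xt.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        tot = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            out, cache = net.forward(xt[idx], want_cache=True)
            loss, dplane = spectral_loss(out, yt[idx], return_grad=True)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            grads = net.backward(cache, dplane.astype(np.float32))
            for k, g in grads.items():
                v = state[k]
                v *= cfg.rho
                v += (1.0 - cfg.rho) * g * g
                step = lr * g / (np.sqrt(v) + _EPS)
                if cfg.momentum:
                    m = mom[k]
                    m *= cfg.momentum
                    m += step
                    step = m
                net.params[k] -= step
            tot += loss * len(idx)
        val = _batched_loss(net, xv, yv, cfg.batch_size)
        history["train_loss"].append(tot / n)
        history["val_loss"].append(val)
        history["lr"].append(lr)
        if verbose:
            print(
                f"epoch {epoch}: train {tot / n:.5g} val {val:.5g} lr {lr:g}",
                file=sys.stderr, flush=True,
            )
        if best - val > cfg.min_delta:
            best = val
            stall = 0
        else:
            stall += 1
        if stall >= cfg.plateau_patience:
            if phase == 0:
                lr = cfg.lr_reduced
                phase = 1
                stall = 0
                best = val
                history["lr_events"].append(epoch)
            else:
                break
    return history


def _batched_loss(net, x, y, batch_size: int) -> float:
    tot = 0.0
    for start in range(0, x.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        out = net.forward(x[sl])
        tot += spectral_loss(out, y[sl]) * (min(x.shape[0], start + batch_size) - start)
    return tot / x.shape[0]


def identity_baseline_loss(x, y, batch_size: int = 256) -> float:
    """Spectral loss of the identity mapping (input vs target)."""
    tot = 0.0
    for start in range(0, x.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        tot += spectral_loss(x[sl], y[sl]) * (min(x.shape[0], start + batch_size) - start)
    return tot / x.shape[0]
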