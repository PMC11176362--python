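"""Synthetic time-domain NMR signals, training pairs and benchmark spectra.

The signal model is a sum of decaying complex exponentials with cosine
modulations from one-bond 13C-13C scalar couplings:

    s(t_k) = sum_j a_j exp(i 2 pi f_j t_k) exp(-R2_j t_k)
                 prod_c cos(pi J_c t_k),      t_k = k / sw

Methyl 13C nuclei have exactly one aliphatic 13C neighbour and appear as
doublets in the 13C dimension; non-methyl CH carbons have two neighbours
and appear as triplets.  "Virtual decoupling" removes exactly one cosine
factor per signal, so doublets collapse to singlets and triplets to
doublets.  Resolution enhancement replaces the input decay rate by the
bounded target rate of :func:`target_r2`, which drives all linewidths
towards ``r2_max`` (default 25 1/s) from both sides.

Training pairs pack a complex FID of length L into a real 4 x L plane with
rows ``[Re v, Im v, Re v(+1), Im v(+1)]`` where ``v(+1)`` is the
one-sample-advanced copy (last sample zero).  The same packing is used at
inference time; it is recorded in every dataset and weight sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .axes import ALLOWED_FIELDS_MHZ, AxisSpec, c13_larmor
from .grid import SpectrumGrid
from .shiftstats import default_shift_stats, draw_methyl_shifts, validate_shift_stats

#: Upper bound of the target transverse relaxation rate (1/s).
R2_MAX_DEFAULT = 25.0

PACKING = "rows=[re,im,re_shift1,im_shift1]; shift1 = one-sample-advanced copy"


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SignalSpec:
    """One resonance: shifts, amplitude, relaxation rates and couplings."""

    shift_h: float                       # ppm
    shift_c: float                       # ppm
    amplitude: float                     # arbitrary units, > 0
    r2_h: float                          # 1/s
    r2_c: float                          # 1/s
    couplings_c: tuple[float, ...] = ()  # Hz, one-bond 13C-13C
    is_methyl: bool = False
    residue_type: str | None = None

    def __post_init__(self) -> None:
        vals = (self.shift_h, self.shift_c, self.amplitude, self.r2_h, self.r2_c,
                *self.couplings_c)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite signal parameters")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.r2_h <= 0 or self.r2_c <= 0:
            raise ValueError("relaxation rates must be > 0")
        if any(j <= 0 for j in self.couplings_c):
            raise ValueError("couplings must be > 0")
        if len(self.couplings_c) > 2:
            raise ValueError("at most two 13C-13C couplings are modelled")
        if self.is_methyl and len(self.couplings_c) != 1:
            raise ValueError("methyl signals carry exactly one coupling (doublet)")
        if (not self.is_methyl) and self.couplings_c and len(self.couplings_c) != 2:
            raise ValueError(
                "non-methyl CH signals carry exactly two couplings (triplet)"
            )


@dataclass
class TrainingPair:
    """Packed input/target plane pair sharing shifts and amplitudes."""

    input_plane: np.ndarray   # (4, L) float
    target_plane: np.ndarray  # (4, L) float
    scale: float              # normalisation divisor applied to both planes
    axis: AxisSpec

    def __post_init__(self) -> None:
        if self.input_plane.shape != self.target_plane.shape:
            raise ValueError("input and target planes must share a shape")
        if self.input_plane.shape[0] != 4:
            raise ValueError("planes must have 4 rows")
        if not (np.isfinite(self.input_plane).all()
                and np.isfinite(self.target_plane).all()):
            raise ValueError("planes must be finite")


# ----------------------------------------------------------------------
# Core operations
# ----------------------------------------------------------------------
def target_r2(r2_in, r2_max: float = R2_MAX_DEFAULT):
    """Bounded target relaxation rate.

    Returns ``max(r2_max*tanh(r2_in/r2_max), r2_max*(1 - tanh(r2_in/r2_max)))``.
    Rates above ``r2_max`` are pulled down towards it and rates below are
    pushed up, so target linewidths are roughly uniform.  The result lies in
    ``[r2_max/2, r2_max]`` with the minimum at ``r2_in = r2_max*atanh(1/2)``.
    """
    r2_in = np.asarray(r2_in, dtype=float)
    if r2_max <= 0:
        raise ValueError("r2_max must be > 0")
    if not np.isfinite(r2_in).all() or (r2_in < 0).any():
        raise ValueError("r2_in must be finite and >= 0")
    th = np.tanh(r2_in / r2_max)
    out = np.maximum(r2_max * th, r2_max * (1.0 - th))
    return float(out) if out.ndim == 0 else out


def pack_fid(v: np.ndarray, length: int | None = None, dtype=np.float64) -> np.ndarray:
    """Pack a complex vector into the real 4 x L network plane."""
    v = np.asarray(v)
    n = v.shape[-1]
    if length is None:
        length = n
    if n > length:
        raise ValueError(f"vector of length {n} exceeds packing length {length}")
    plane = np.zeros(v.shape[:-1] + (4, length), dtype=dtype)
    plane[..., 0, :n] = v.real
    plane[..., 1, :n] = v.imag
    plane[..., 2, : n - 1] = v.real[..., 1:]
    plane[..., 3, : n - 1] = v.imag[..., 1:]
    return plane


def unpack_plane(plane: np.ndarray, n_points: int | None = None) -> np.ndarray:
    """Inverse of :func:`pack_fid` (rows 0 and 1; the shifted copy is dropped)."""
    v = plane[..., 0, :] + 1j * plane[..., 1, :]
    if n_points is not None:
        v = v[..., :n_points]
    return v


def synthesize_fid(
    signals,
    axis: AxisSpec,
    dim: str = "13C",
    decoupled: bool = False,
    r2_override=None,
    n_points: int | None = None,
) -> np.ndarray:
    """Simulate a 1D quadrature FID for one spectral dimension.

    ``dim`` selects which shift/rate of each :class:`SignalSpec` is used and
    must match ``axis.nucleus``.  Couplings modulate the 13C dimension only.
    With ``decoupled=True`` exactly one cosine factor per signal is omitted.
    ``r2_override`` replaces the per-signal decay rates (array-like, 1/s).
    """
    if dim not in ("1H", "13C"):
        raise ValueError(f"bad dim {dim!r}")
    if axis.nucleus != dim:
        raise ValueError(f"axis nucleus {axis.nucleus} does not match dim {dim}")
    n = axis.n_complex_points if n_points is None else n_points
    if not signals:
        warnings.warn("empty signal list; returning a zero FID", stacklevel=2)
        return np.zeros(n, dtype=complex)
    t = axis.times(n)
    out = np.zeros(n, dtype=complex)
    for j, sig in enumerate(signals):
        shift = sig.shift_h if dim == "1H" else sig.shift_c
        r2 = sig.r2_h if dim == "1H" else sig.r2_c
        if r2_override is not None:
            r2 = float(np.asarray(r2_override)[j])
        f = axis.ppm_to_hz(shift)
        term = sig.amplitude * np.exp((2j * np.pi * f - r2) * t)
        if dim == "13C":
            coup = sig.couplings_c[1:] if decoupled else sig.couplings_c
            for jc in coup:
                term = term * np.cos(np.pi * jc * t)
        out += term
    return out


# ----------------------------------------------------------------------
# Training-pair generation
# ----------------------------------------------------------------------
@dataclass
class TrainingSetConfig:
    """Parameter ranges for one network's synthetic training planes.

    Defaults mirror the benchmark parameter table: couplings ~ N(34, 2) Hz,
    sweep widths uniform on 2000-5000 Hz, and broad uniform decay-rate
    ranges that bracket the per-protein normal distributions.  All ranges
    are configurable; they are the study conditions, not tuning knobs.
    """

    network: str = "c13"                      # "c13" | "h1"
    n_points: int = 1024                      # complex points = packing length
    sweep_width_range: tuple = (2000.0, 5000.0)   # Hz, per plane
    n_signals_range: tuple = (1, 8)           # inclusive, per plane
    r2_range: tuple = (5.0, 100.0)            # 1/s, uniform per signal
    j_mean: float = 34.0                      # Hz
    j_sd: float = 2.0                         # Hz
    couplings_per_signal: int = 1             # 13C network only
    amplitude_decades: float = 1.0            # log-uniform amplitude span
    noise_sigma_range: tuple = (0.0, 0.04)    # input noise, rel. plane max
    freq_fraction: float = 0.45               # |offset| < fraction * sw
    r2_max: float = R2_MAX_DEFAULT

    def __post_init__(self) -> None:
        if self.network not in ("c13", "h1"):
            raise ValueError("network must be 'c13' or 'h1'")
        if self.network == "h1":
            self.couplings_per_signal = 0

    @classmethod
    def default_h1(cls, **kw) -> "TrainingSetConfig":
        kw.setdefault("network", "h1")
        kw.setdefault("n_points", 512)
        return cls(**kw)


def _draw_plane_params(cfg: TrainingSetConfig, n_planes: int, rng: np.random.Generator):
    """Draw per-plane and per-signal parameters for a batch of planes."""
    lo, hi = cfg.n_signals_range
    n_sig = rng.integers(lo, hi + 1, size=n_planes)
    sw = rng.uniform(*cfg.sweep_width_range, size=n_planes)
    noise = rng.uniform(*cfg.noise_sigma_range, size=n_planes)
    total = int(n_sig.sum())
    plane_of = np.repeat(np.arange(n_planes), n_sig)
    freq = rng.uniform(-cfg.freq_fraction, cfg.freq_fraction, size=total) * sw[plane_of]
    r2 = rng.uniform(*cfg.r2_range, size=total)
    amp = 10.0 ** rng.uniform(
        -cfg.amplitude_decades / 2.0, cfg.amplitude_decades / 2.0, size=total
    )
    ncoup = cfg.couplings_per_signal
    j = (
        rng.normal(cfg.j_mean, cfg.j_sd, size=(total, ncoup))
        if ncoup
        else np.zeros((total, 0))
    )
    j = np.abs(j)  # couplings are positive; N(34,2) essentially never crosses 0
    return {
        "n_signals": n_sig,
        "plane_of": plane_of,
        "sweep_width": sw,
        "noise_sigma": noise,
        "freq_hz": freq,
        "r2_in": r2,
        "amplitude": amp,
        "j_hz": j,
    }


def _geometric_fids(ratio: np.ndarray, n_points: int) -> np.ndarray:
    """Rows of z**k for k = 0..n-1 computed by cumulative products.

    Single precision: the relative drift of the cumulative product stays
    well below the float16 quantisation of the stored planes.
    """
    m = np.broadcast_to(ratio.astype(np.complex64)[:, None],
                        (ratio.size, n_points)).copy()
    m[:, 0] = 1.0
    return np.cumprod(m, axis=1, out=m)


def _synthesize_batch(params, cfg: TrainingSetConfig, which: str) -> np.ndarray:
    """Vectorised FID synthesis for a parameter batch.

    ``which`` is "input" (full couplings, drawn R2) or "target" (one
    coupling removed for the 13C network, R2 mapped through target_r2).
    Couplings are expanded into sums of pure complex exponentials:
    cos(pi J t) = (e^{i pi J t} + e^{-i pi J t}) / 2.
    """
    dt = 1.0 / params["sweep_width"][params["plane_of"]]
    freq, amp = params["freq_hz"], params["amplitude"]
    r2 = params["r2_in"] if which == "input" else target_r2(params["r2_in"], cfg.r2_max)
    j = params["j_hz"] if which == "input" else params["j_hz"][:, 1:]
    total = freq.size

    # expand each signal into 2**ncoup exponential terms
    ncoup = j.shape[1]
    n_terms = 2 ** ncoup
    signs = np.array(
        [[(1 if (i >> c) & 1 else -1) for c in range(ncoup)] for i in range(n_terms)],
        dtype=float,
    )  # (n_terms, ncoup)
    f_eff = freq[:, None] + 0.5 * (j[:, None, :] * signs[None, :, :]).sum(-1)
    a_eff = np.broadcast_to((amp / n_terms)[:, None], f_eff.shape)
    ratio = np.exp((2j * np.pi * f_eff - r2[:, None]) * dt[:, None])
    fids = _geometric_fids(ratio.ravel(), cfg.n_points)
    fids *= a_eff.ravel().astype(np.float32)[:, None]
    # sum terms per signal, then signals per plane
    fids = fids.reshape(total, n_terms, cfg.n_points).sum(axis=1)
    edges = np.concatenate([[0], np.cumsum(params["n_signals"])[:-1]])
    return np.add.reduceat(fids, edges, axis=0)


def generate_pairs(
    cfg: TrainingSetConfig, n_planes: int, rng: np.random.Generator
) -> dict:
    """Generate a batch of packed, normalised training pairs.

    Returns a dict with ``input`` and ``target`` arrays of shape
    (n_planes, 4, L), per-pair ``scale`` factors, and the drawn parameters.
    Noise (complex Gaussian, per-plane sigma relative to the plane maximum)
    is added to the input only; the target stays ideal.
    """
    params = _draw_plane_params(cfg, n_planes, rng)
    v_in = _synthesize_batch(params, cfg, "input")
    v_tar = _synthesize_batch(params, cfg, "target")
    sigma = (params["noise_sigma"] * np.abs(v_in).max(axis=1)).astype(np.float32)
    noise = (
        rng.standard_normal(v_in.shape) + 1j * rng.standard_normal(v_in.shape)
    ).astype(np.complex64)
    v_in = v_in + sigma[:, None] * noise
    x = pack_fid(v_in, dtype=np.float32)
    y = pack_fid(v_tar, dtype=np.float32)
    scale = np.abs(x).max(axis=(1, 2))
    scale[scale == 0] = 1.0
    x /= scale[:, None, None]
    y /= scale[:, None, None]
    return {"input": x, "target": y, "scale": scale, "params": params}


def make_training_pair(
    signals,
    axis: AxisSpec,
    network: str,
    r2_max: float = R2_MAX_DEFAULT,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
) -> TrainingPair:
    """Build one input/target pair from explicit :class:`SignalSpec` values.

    The input packs the coupled FID with the signals' own decay rates; the
    target packs the FID with one coupling removed per signal (13C network)
    and rates replaced by :func:`target_r2`.  Both planes are divided by the
    same scale (the input-plane maximum).
    """
    if network not in ("c13", "h1"):
        raise ValueError("network must be 'c13' or 'h1'")
    dim = "13C" if network == "c13" else "1H"
    r2 = np.array([s.r2_c if dim == "13C" else s.r2_h for s in signals])
    v_in = synthesize_fid(signals, axis, dim=dim, decoupled=False)
    v_tar = synthesize_fid(
        signals, axis, dim=dim, decoupled=(network == "c13"),
        r2_override=target_r2(r2, r2_max),
    )
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        s = noise_sigma * np.abs(v_in).max()
        v_in = v_in + s * (
            rng.standard_normal(v_in.shape) + 1j * rng.standard_normal(v_in.shape)
        )
    x, y = pack_fid(v_in), pack_fid(v_tar)
    scale = float(np.abs(x).max()) or 1.0
    return TrainingPair(x / scale, y / scale, scale, axis)


def generate_training_set(
    cfg: TrainingSetConfig,
    n_train: int,
    n_test: int,
    seed: int,
    out_path,
    batch: int = 2048,
    plane_dtype: str = "float16",
) -> dict:
    """Stream a seeded training/test dataset to HDF5 and write a manifest.

    Layout: groups ``/train`` and ``/test`` with datasets ``input`` and
    ``target`` of shape (n, 4, L) (normalised planes, stored ``plane_dtype``),
    ``scale`` (float32) and per-pair parameter metadata (true frequencies,
    couplings and decay rates, NaN-padded to the per-plane signal maximum)
    for auditability.  A JSON manifest ``<out>.manifest.json`` records the
    split, config, packing convention and seed.
    """
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    out_path = Path(out_path)
    rng = np.random.default_rng(seed)
    max_sig = cfg.n_signals_range[1]
    ncoup = cfg.couplings_per_signal
    with h5py.File(out_path, "w") as h5:
        h5.attrs["packing"] = PACKING
        h5.attrs["config"] = json.dumps(dataclasses.asdict(cfg))
        h5.attrs["seed"] = seed
        for split, n_total in (("train", n_train), ("test", n_test)):
            g = h5.create_group(split)
            L = cfg.n_points
            chunk = (min(64, n_total), 4, L)
            dsx = g.create_dataset(
                "input", (n_total, 4, L), dtype=plane_dtype, chunks=chunk
            )
            dsy = g.create_dataset(
                "target", (n_total, 4, L), dtype=plane_dtype, chunks=chunk
            )
            dss = g.create_dataset("scale", (n_total,), dtype="float32")
            meta = {
                name: g.create_dataset(
                    f"meta_{name}", (n_total, max_sig), dtype="float32"
                )
                for name in ("freq_hz", "r2_in", "r2_target", "amplitude")
            }
            meta_j = g.create_dataset(
                "meta_j_hz", (n_total, max_sig, max(ncoup, 1)), dtype="float32"
            )
            g.create_dataset("sweep_width", (n_total,), dtype="float32")
            g.create_dataset("n_signals", (n_total,), dtype="int32")
            done = 0
            while done < n_total:
                nb = min(batch, n_total - done)
                out = generate_pairs(cfg, nb, rng)
                sl = slice(done, done + nb)
                dsx[sl] = out["input"].astype(plane_dtype)
                dsy[sl] = out["target"].astype(plane_dtype)
                dss[sl] = out["scale"]
                p = out["params"]
                g["sweep_width"][sl] = p["sweep_width"]
                g["n_signals"][sl] = p["n_signals"]
                pad = np.full((nb, max_sig), np.nan, dtype="float32")
                row = p["plane_of"]
                col = np.concatenate([np.arange(k) for k in p["n_signals"]]).astype(int) \
                    if nb else np.array([], dtype=int)
                for name, key in (
                    ("freq_hz", "freq_hz"),
                    ("r2_in", "r2_in"),
                    ("amplitude", "amplitude"),
                ):
                    m = pad.copy()
                    m[row, col] = p[key]
                    meta[name][sl] = m
                m = pad.copy()
                m[row, col] = target_r2(p["r2_in"], cfg.r2_max)
                meta["r2_target"][sl] = m
                mj = np.full((nb, max_sig, max(ncoup, 1)), np.nan, dtype="float32")
                if ncoup:
                    mj[row, col, :] = p["j_hz"]
                meta_j[sl] = mj
                done += nb
    manifest = {
        "path": str(out_path),
        "n_train": n_train,
        "n_test": n_test,
        "seed": seed,
        "packing": PACKING,
        "plane_dtype": plane_dtype,
        "config": dataclasses.asdict(cfg),
    }
    mpath = out_path.with_suffix(out_path.suffix + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=1))
    return manifest


def load_training_arrays(path, split: str = "train", n: int | None = None):
    """Load (input, target) planes from a generated HDF5 dataset as float32."""
    with h5py.File(path, "r") as h5:
        g = h5[split]
        sl = slice(None) if n is None else slice(n)
        return (
            g["input"][sl].astype(np.float32),
            g["target"][sl].astype(np.float32),
        )


# ----------------------------------------------------------------------
# Benchmark spectra
# ----------------------------------------------------------------------
@dataclass
class BenchmarkConfig:
    """Per-kind parameters of the synthetic 2D benchmark spectra.

    The two kinds emulate proteins of different size: ``hdac_like`` spectra
    carry 275 signals, ``msg_like`` 600.  Half of the signals are methyls
    (doublets, shifts from the methyl statistics table); the other half are
    non-methyl CH moieties (triplets) placed in a higher-frequency region.
    """

    kind: str = "hdac_like"
    n_signals: int = 275
    r2_h_mean: float = 50.0
    r2_h_sd: float = 10.0
    r2_c_mean: float = 50.0
    r2_c_sd: float = 10.0
    j_mean: float = 34.0
    j_sd: float = 2.0
    fields_mhz: tuple = ALLOWED_FIELDS_MHZ
    sw_h_range: tuple = (2000.0, 5000.0)
    sw_c_range: tuple = (2000.0, 5000.0)
    td_h: int = 512                       # complex points, 1H
    td_c: int = 128                       # complex points, 13C
    carrier_h: float = 1.2                # ppm
    carrier_c: float = 19.5               # ppm
    nonmethyl_h_range: tuple = (2.6, 5.4)  # ppm
    nonmethyl_c_range: tuple = (24.0, 36.0)
    amplitude_decades: float = 1.0
    noise_level: float = 0.02             # sigma relative to median amplitude

    @classmethod
    def preset(cls, kind: str, **kw) -> "BenchmarkConfig":
        presets = {
            "hdac_like": dict(n_signals=275, r2_h_mean=50, r2_h_sd=10,
                              r2_c_mean=50, r2_c_sd=10),
            "msg_like": dict(n_signals=600, r2_h_mean=60, r2_h_sd=15,
                             r2_c_mean=60, r2_c_sd=10),
        }
        if kind not in presets:
            raise ValueError(f"unknown benchmark kind {kind!r}")
        merged = {**presets[kind], **kw}
        return cls(kind=kind, **merged)


def _clipped_range(lo, hi, wlo, whi, margin):
    """Intersect a configured ppm range with the spectral window.

    Falls back to the top 30% of the window when the intersection is empty
    (narrow windows at high field cannot reach the configured region).
    """
    a, b = max(lo, wlo + margin), min(hi, whi - margin)
    if a >= b:
        a, b = whi - 0.30 * (whi - wlo), whi - margin
    return a, b


def draw_benchmark_signals(
    cfg: BenchmarkConfig,
    stats: pd.DataFrame,
    rng: np.random.Generator,
    axis_h: AxisSpec,
    axis_c: AxisSpec,
) -> list[SignalSpec]:
    validate_shift_stats(stats)
    n = cfg.n_signals
    n_methyl = n // 2 + n % 2  # half, rounding the odd signal to methyl
    n_other = n - n_methyl
    h_lo, h_hi = axis_h.ppm_window()
    c_lo, c_hi = axis_c.ppm_window()
    mh, mc = draw_methyl_shifts(stats, n_methyl, rng)
    # keep truth inside the acquired window
    h_marg = 0.02 * (h_hi - h_lo)
    c_marg = 0.02 * (c_hi - c_lo)
    mh = np.clip(mh, h_lo + h_marg, h_hi - h_marg)
    mc = np.clip(mc, c_lo + c_marg, c_hi - c_marg)
    oh_range = _clipped_range(*cfg.nonmethyl_h_range, h_lo, h_hi, h_marg)
    oc_range = _clipped_range(*cfg.nonmethyl_c_range, c_lo, c_hi, c_marg)
    oh = rng.uniform(*oh_range, size=n_other)
    oc = rng.uniform(*oc_range, size=n_other)

    def pos(x):
        return np.maximum(x, 1e-3)

    r2h = pos(rng.normal(cfg.r2_h_mean, cfg.r2_h_sd, size=n))
    r2c = pos(rng.normal(cfg.r2_c_mean, cfg.r2_c_sd, size=n))
    amp = 10.0 ** rng.uniform(
        -cfg.amplitude_decades / 2, cfg.amplitude_decades / 2, size=n
    )
    n_coup = np.r_[np.ones(n_methyl, int), np.full(n_other, 2, int)]
    j = np.abs(rng.normal(cfg.j_mean, cfg.j_sd, size=(n, 2)))
    signals = []
    hh = np.r_[mh, oh]
    cc = np.r_[mc, oc]
    for i in range(n):
        signals.append(
            SignalSpec(
                shift_h=float(hh[i]),
                shift_c=float(cc[i]),
                amplitude=float(amp[i]),
                r2_h=float(r2h[i]),
                r2_c=float(r2c[i]),
                couplings_c=tuple(j[i, : n_coup[i]]),
                is_methyl=bool(i < n_methyl),
            )
        )
    return signals


def truth_peaklist(signals: list[SignalSpec]) -> pd.DataFrame:
    """Ground-truth (coupling-free) peak positions of a signal list."""
    mult = {1: "doublet", 2: "triplet", 0: "singlet"}
    return pd.DataFrame(
        {
            "id": np.arange(len(signals)),
            "h_ppm": [s.shift_h for s in signals],
            "c_ppm": [s.shift_c for s in signals],
            "amplitude": [s.amplitude for s in signals],
            "multiplicity": [mult[len(s.couplings_c)] for s in signals],
            "is_methyl": [s.is_methyl for s in signals],
        }
    )


def _dim_vectors(
    signals, axis: AxisSpec, dim: str, decoupled: bool, use_target_r2: bool,
    r2_max: float,
) -> np.ndarray:
    """Per-signal complex modulation vectors (S, N) for one dimension."""
    t = axis.times()
    S = len(signals)
    out = np.empty((S, t.size), dtype=complex)
    for i, sig in enumerate(signals):
        shift = sig.shift_h if dim == "1H" else sig.shift_c
        r2 = sig.r2_h if dim == "1H" else sig.r2_c
        if use_target_r2:
            r2 = target_r2(r2, r2_max)
        f = axis.ppm_to_hz(shift)
        v = np.exp((2j * np.pi * f - r2) * t)
        if dim == "13C":
            coup = sig.couplings_c[1:] if decoupled else sig.couplings_c
            for jc in coup:
                v = v * np.cos(np.pi * jc * t)
        out[i] = v
    return out


def synthesize_time_grid(
    signals: list[SignalSpec],
    axes: list[AxisSpec],
    idealised: bool = False,
    r2_max: float = R2_MAX_DEFAULT,
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SpectrumGrid:
    """Assemble a hypercomplex time-domain grid (2D or 3D).

    The last axis is the directly detected 1H dimension (complex dtype);
    every preceding axis is an indirect 13C dimension stored States-
    interleaved (cosine component on even indices, sine on odd).  With
    ``idealised=True`` one coupling per signal is removed and decay rates
    are mapped through :func:`target_r2` in every dimension (the benchmark
    target spectrum); idealised grids are noise-free.
    """
    ndim = len(axes)
    if ndim not in (2, 3):
        raise ValueError("only 2D and 3D grids are supported")
    if axes[-1].nucleus != "1H" or any(a.nucleus != "13C" for a in axes[:-1]):
        raise ValueError("expect indirect 13C axes and a direct 1H axis")
    amp = np.array([s.amplitude for s in signals])
    vh = _dim_vectors(signals, axes[-1], "1H", False, idealised, r2_max)
    vh = vh * amp[:, None]
    comps = []
    for ax in axes[:-1]:
        vc = _dim_vectors(signals, ax, "13C", idealised, idealised, r2_max)
        inter = np.empty((vc.shape[0], 2 * vc.shape[1]))
        inter[:, 0::2] = vc.real
        inter[:, 1::2] = vc.imag
        comps.append(inter)
    if ndim == 2:
        data = comps[0].T @ vh
    else:
        data = np.einsum("sa,sb,sn->abn", comps[0], comps[1], vh, optimize=True)
    if noise_level > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        sigma = noise_level * float(np.median(amp))
        data = data + sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    grid = SpectrumGrid(
        data,
        list(axes),
        domains=["time"] * ndim,
        interleaved=[True] * (ndim - 1) + [False],
    )
    grid.log(f"synthesize_time_grid(idealised={idealised}, ndim={ndim})")
    return grid


def generate_benchmark_spectrum(
    kind: str,
    stats: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    config: BenchmarkConfig | None = None,
):
    """One synthetic benchmark spectrum: coupled input, idealised target, truth.

    The sweep widths are drawn uniformly from the configured ranges and the
    spectrometer field from the configured set, per spectrum.  Returns
    ``(coupled_grid, target_grid, truth_peaklist)``; both grids are
    time-domain and share axes.
    """
    cfg = config if config is not None else BenchmarkConfig.preset(kind)
    if config is not None and config.kind != kind:
        raise ValueError("config.kind does not match requested kind")
    if stats is None:
        stats = default_shift_stats()
    if rng is None:
        rng = np.random.default_rng()
    field = float(rng.choice(cfg.fields_mhz))
    sw_h = float(rng.uniform(*cfg.sw_h_range))
    sw_c = float(rng.uniform(*cfg.sw_c_range))
    axis_h = AxisSpec(cfg.td_h, sw_h, field, cfg.carrier_h, "1H")
    axis_c = AxisSpec(cfg.td_c, sw_c, c13_larmor(field), cfg.carrier_c, "13C")
    signals = draw_benchmark_signals(cfg, stats, rng, axis_h, axis_c)
    coupled = synthesize_time_grid(
        signals, [axis_c, axis_h], idealised=False,
        noise_level=cfg.noise_level, rng=rng,
    )
    target = synthesize_time_grid(signals, [axis_c, axis_h], idealised=True)
    return coupled, target, truth_peaklist(signals)


def generate_benchmark_suite(
    out_dir,
    n_per_kind: int = 100,
    seed: int = 0,
    configs: dict | None = None,
    stats: pd.DataFrame | None = None,
    overwrite: bool = False,
) -> dict:
    """Write a full benchmark suite (both kinds) plus a JSON manifest.

    Each spectrum is stored as a pair of nmrPipe-format 2D files (coupled
    input and idealised target) with a TSV truth peak list.  The manifest
    records per-spectrum parameters and SHA-256 checksums of every file.
    """
    from .pipeio import write_pipe_2d

    if n_per_kind < 1:
        raise ValueError("n_per_kind must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} is not empty; pass overwrite=True to replace it"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    if stats is None:
        stats = default_shift_stats()
    kinds = ("hdac_like", "msg_like")
    entries = []
    streams = np.random.SeedSequence(seed).spawn(len(kinds))
    for kind, ss in zip(kinds, streams):
        cfg = (configs or {}).get(kind) or BenchmarkConfig.preset(kind)
        rng = np.random.default_rng(ss)
        for i in range(n_per_kind):
            coupled, target, truth = generate_benchmark_spectrum(
                kind, stats=stats, rng=rng, config=cfg
            )
            base = f"{kind}_{i:03d}"
            paths = {
                "coupled": out_dir / f"{base}_coupled.fid",
                "target": out_dir / f"{base}_target.fid",
                "truth": out_dir / f"{base}_truth.tsv",
            }
            write_pipe_2d(paths["coupled"], coupled)
            write_pipe_2d(paths["target"], target)
            truth.to_csv(paths["truth"], sep="\t", index=False)
            entries.append(
                {
                    "kind": kind,
                    "index": i,
                    "field_mhz": coupled.axes[1].larmor_frequency,
                    "sw_h": coupled.axes[1].sweep_width,
                    "sw_c": coupled.axes[0].sweep_width,
                    "n_signals": int(len(truth)),
                    "files": {k: p.name for k, p in paths.items()},
                    "sha256": {
                        k: hashlib.sha256(p.read_bytes()).hexdigest()
                        for k, p in paths.items()
                    },
                }
            )
    manifest = {
        "seed": seed,
        "n_per_kind": n_per_kind,
        "n_spectra": len(entries),
        "spectra": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
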