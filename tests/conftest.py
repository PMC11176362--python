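"""Shared fixtures.

The trained-network fixtures run real (reduced-scale) training once per
session; they back both the learning demonstrations and the end-to-end
benchmark tests.  Everything is seeded, so repeated runs are identical.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from methyldec.fidnet import GatedConvNet, identity_baseline_loss, train
from methyldec.presets import (
    REDUCED_C13_DATA,
    REDUCED_C13_MODEL,
    REDUCED_H1_DATA,
    REDUCED_H1_MODEL,
    REDUCED_TRAIN,
)
from methyldec.simkit import generate_pairs, unpack_plane


def singlet_conversion(planes, true_freqs, sweep_width, n_fft=256):
    """Fraction of planes whose apodized display spectrum is a singlet at
    the true shift.

    A plane counts as converted when its cosine-apodized, zero-filled FT
    has exactly one local maximum above 25% of the spectrum maximum and
    the global maximum sits within one grid step of the true frequency.
    The apodization matters: the sharpened (truncated) FIDs ring at ~15%
    of the peak without it, so the raw FT of even a perfect output is not
    singlet-shaped.
    """
    n_ok = 0
    for i in range(planes.shape[0]):
        v = unpack_plane(planes[i])
        n = v.shape[-1]
        window = np.cos(0.5 * np.pi * np.arange(n) / n)
        spec = np.abs(np.fft.fft(v * window, n_fft))
        bins = np.fft.fftfreq(n_fft, 1.0 / sweep_width)
        arg = int(np.argmax(spec))
        maxima = [
            j for j in range(n_fft)
            if spec[j] > spec[j - 1]
            and spec[j] >= spec[(j + 1) % n_fft]
            and spec[j] > 0.25 * spec.max()
        ]
        offset = bins[arg] - true_freqs[i]
        wrapped = abs((offset + sweep_width / 2) % sweep_width - sweep_width / 2)
        n_ok += len(maxima) == 1 and wrapped <= sweep_width / n_fft * 1.01
    return n_ok / planes.shape[0]


@pytest.fixture(scope="session")
def conversion_metric():
    return singlet_conversion


@pytest.fixture(scope="session")
def reduced_c13_sets():
    """Seeded train/validation/held-out pair batches for the 13C network."""
    tr = generate_pairs(REDUCED_C13_DATA, 1500, np.random.default_rng(42))
    va = generate_pairs(REDUCED_C13_DATA, 300, np.random.default_rng(43))
    hold_cfg = dataclasses.replace(
        REDUCED_C13_DATA, noise_sigma_range=(0.01, 0.01)
    )
    hold = generate_pairs(hold_cfg, 100, np.random.default_rng(99))
    return {"train": tr, "val": va, "holdout": hold}


@pytest.fixture(scope="session")
def trained_c13(reduced_c13_sets):
    """A reduced 13C decoupling/sharpening network trained for real."""
    sets = reduced_c13_sets
    net = GatedConvNet(REDUCED_C13_MODEL, seed=7)
    history = train(
        net,
        ((sets["train"]["input"], sets["train"]["target"]),
         (sets["val"]["input"], sets["val"]["target"])),
        REDUCED_TRAIN,
    )
    baseline = identity_baseline_loss(sets["val"]["input"], sets["val"]["target"])
    return {"net": net, "history": history, "baseline": baseline}


@pytest.fixture(scope="session")
def trained_h1():
    """A reduced 1H sharpening network trained for real."""
    rng = np.random.default_rng(11)
    tr = generate_pairs(REDUCED_H1_DATA, 600, rng)
    va = generate_pairs(REDUCED_H1_DATA, 120, rng)
    net = GatedConvNet(REDUCED_H1_MODEL, seed=5)
    cfg = dataclasses.replace(REDUCED_TRAIN, max_epochs=6)
    history = train(
        net,
        ((tr["input"], tr["target"]), (va["input"], va["target"])),
        cfg,
    )
    return {"net": net, "history": history}
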