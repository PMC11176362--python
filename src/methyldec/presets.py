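"""Shared full-scale and desk-scale (reduced) configurations.

The full-scale settings are the method's full training conditions
(1024/512-point packings, 17/13 dilation cycles, 128/64 filters, 500k/50k
pair datasets).  Training those networks is accelerator-scale work; the
reduced presets keep the same architecture family and signal model at
sizes a single CPU core can train in minutes, and are what the test-suite
demonstrations use.  The reduced 13C preset fixes the sweep width so the
network sees one dwell time; the benchmark preset below matches it.
"""

from __future__ import annotations

from .fidnet import ModelConfig, TrainConfig
from .simkit import BenchmarkConfig, TrainingSetConfig

# ----------------------------------------------------------------------
# Full scale
# ----------------------------------------------------------------------
FULL_C13_MODEL = ModelConfig.default_c13()
FULL_H1_MODEL = ModelConfig.default_h1()
FULL_TRAIN = TrainConfig()  # RMSprop, 1e-4 -> 1e-5 on validation plateaus
FULL_C13_DATA = TrainingSetConfig(network="c13")
FULL_H1_DATA = TrainingSetConfig.default_h1()
FULL_N_TRAIN = 500_000
FULL_N_TEST = 50_000

# ----------------------------------------------------------------------
# Reduced (desk) scale
# ----------------------------------------------------------------------
# two short dilation cycles: demodulation is a composed multiplicative
# computation, and depth (more gated stages) matters more than width here
REDUCED_C13_MODEL = ModelConfig(
    input_length=128, dilations=(1, 1, 2, 2, 4, 8, 16, 16), filters_per_layer=8
)
REDUCED_H1_MODEL = ModelConfig(
    input_length=256, dilations=(1, 2, 4), filters_per_layer=8
)

# single-doublet planes: the desk-scale 13C demonstration trains and is
# scored on isolated doublet pairs
REDUCED_C13_DATA = TrainingSetConfig(
    network="c13",
    n_points=128,
    sweep_width_range=(2000.0, 2000.0),
    n_signals_range=(1, 1),
    r2_range=(20.0, 80.0),
    noise_sigma_range=(0.0, 0.03),
)
REDUCED_H1_DATA = TrainingSetConfig(
    network="h1",
    n_points=256,
    sweep_width_range=(3000.0, 3000.0),
    n_signals_range=(1, 3),
    r2_range=(20.0, 80.0),
    noise_sigma_range=(0.0, 0.03),
)

# the full-scale learning rates suit half-million-pair epochs; the reduced
# runs see two orders of magnitude fewer updates, so they use a higher
# rate with RMSprop momentum and a tighter epoch cap
REDUCED_TRAIN = TrainConfig(
    lr_initial=2e-3,
    lr_reduced=5e-4,
    plateau_patience=3,
    min_delta=1e-4,
    batch_size=32,
    max_epochs=16,
    momentum=0.9,
    seed=3,
)

#: benchmark generator settings matched to the reduced networks (fixed
#: sweep widths equal to the training dwell times, half-scale grids)
REDUCED_BENCH_KW = dict(
    sw_h_range=(3000.0, 3000.0),
    sw_c_range=(2000.0, 2000.0),
    fields_mhz=(800.0,),
    td_h=256,
    td_c=128,
)


def reduced_benchmark_config(kind: str) -> BenchmarkConfig:
    return BenchmarkConfig.preset(kind, **REDUCED_BENCH_KW)


PRESETS = {
    "full-c13": (FULL_C13_MODEL, FULL_C13_DATA),
    "full-h1": (FULL_H1_MODEL, FULL_H1_DATA),
    "reduced-c13": (REDUCED_C13_MODEL, REDUCED_C13_DATA),
    "reduced-h1": (REDUCED_H1_MODEL, REDUCED_H1_DATA),
}
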