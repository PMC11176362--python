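# methyldec

Methyl `13C–1H` correlation spectra of large **non-deuterated, uniformly
13C-labelled proteins** are broadened by dipolar relaxation and split into
multiplets by one-bond `13C–13C` scalar couplings (`1J_CC ≈ 34 Hz`), which
makes them hard to interpret even though methyl groups remain sensitive.
`methyldec` implements the deep-learning processing route around this:
two gated dilated convolutional networks applied *inside* an otherwise
conventional Fourier-processing pipeline

1. **13C network** — virtually decouples (removes one cosine modulation
   `cos(pi J t)` per signal, so doublets collapse to singlets and triplets
   to doublets) and sharpens the indirect dimension, and
2. **1H network** — sharpens the detected dimension,

yielding spectra of similar quality to methyl-TROSY spectra of deuterated,
specifically labelled samples, without the deuteration.  Line sharpening
maps each input decay rate through the bounded target

    R2_tar = max( R2max·tanh(R2in/R2max), R2max·(1 − tanh(R2in/R2max)) ),
    R2max = 25 s⁻¹,

so broad lines narrow toward `R2max` and already-sharp lines broaden
slightly toward it (uniform target linewidths, no truncation artefacts).

The package is aimed at NMR spectroscopists and methods developers: it
contains the synthetic FID/training-pair generator, the networks with a
pure-numpy training loop (RMSprop, frequency-domain MSE loss), the 2D/3D
enhancement pipeline with nmrPipe-format I/O, the synthetic peak-picking
benchmark (isolation/region filters, greedy one-to-one matching, TP/FP/FN
scoring), and NOE cross-peak volume–distance analysis (`V = C/r⁶`).

## Worked example

Train a reduced 13C decoupling network (8 dilated gated units, 8 filters,
128-point FIDs — about ten minutes on one CPU core) and enhance a
synthetic five-doublet plane:

```python
import numpy as np
from methyldec.axes import AxisSpec, c13_larmor
from methyldec.simkit import (SignalSpec, generate_pairs, synthesize_time_grid)
from methyldec.fidnet import GatedConvNet, train, identity_baseline_loss
from methyldec.presets import (REDUCED_C13_MODEL, REDUCED_C13_DATA,
                               REDUCED_H1_MODEL, REDUCED_H1_DATA, REDUCED_TRAIN)
from methyldec.spectro import ProcConfig, enhance_2d
from methyldec.benchkit import pick_peaks
import dataclasses

tr = generate_pairs(REDUCED_C13_DATA, 1500, np.random.default_rng(42))
va = generate_pairs(REDUCED_C13_DATA, 300, np.random.default_rng(43))
c13 = GatedConvNet(REDUCED_C13_MODEL, seed=7)
hist = train(c13, ((tr["input"], tr["target"]),
                   (va["input"], va["target"])), REDUCED_TRAIN)
print("identity baseline :", round(identity_baseline_loss(va["input"], va["target"]), 2))
print("trained val loss  :", round(hist["val_loss"][-1], 2))

rng = np.random.default_rng(11)
trh = generate_pairs(REDUCED_H1_DATA, 600, rng)
vah = generate_pairs(REDUCED_H1_DATA, 120, rng)
h1 = GatedConvNet(REDUCED_H1_MODEL, seed=5)
train(h1, ((trh["input"], trh["target"]), (vah["input"], vah["target"])),
      dataclasses.replace(REDUCED_TRAIN, max_epochs=6))

axc = AxisSpec(128, 2000.0, c13_larmor(800.0), 19.5, "13C")
axh = AxisSpec(256, 3000.0, 800.0, 1.2, "1H")
doublets = [SignalSpec(0.5 + 0.35 * k, 16.0 + 1.6 * k, 1.0, 50.0, 50.0,
                       (34.0,), True) for k in range(5)]
grid = synthesize_time_grid(doublets, [axc, axh], noise_level=0.005,
                            rng=np.random.default_rng(0))
spectrum = enhance_2d(grid, c13, h1, ProcConfig(apodize="cosine"))
peaks = pick_peaks(spectrum, threshold_sigmas=8)
strong = peaks[peaks.height > 0.25 * peaks.height.max()]
for _, p in strong.sort_values("h_ppm").iterrows():
    print(f"peak at 1H {p.h_ppm:5.2f} ppm, 13C {p.c_ppm:5.2f} ppm")
```

Output from this exact script (seeds included):

```
identity baseline : 37.73
trained val loss  : 6.49
peak at 1H  0.50 ppm, 13C 16.00 ppm
peak at 1H  0.85 ppm, 13C 17.60 ppm
peak at 1H  1.20 ppm, 13C 19.20 ppm
peak at 1H  1.55 ppm, 13C 20.80 ppm
peak at 1H  1.90 ppm, 13C 22.40 ppm
```

The identity baseline is the frequency-domain mean-squared error between
the coupled/broad input planes and the decoupled/sharpened targets; the
trained network reduces it almost six-fold (and by ~6.9x on held-out
isolated doublets).  The five 34-Hz doublets — ten broad 13C components
in the conventional spectrum — come out as five peaks at the
coupling-free truth positions (0.5/16.0, 0.85/17.6, 1.2/19.2, 1.55/20.8,
1.9/22.4 ppm), each within one grid step.

The same pipeline runs from the shell:

```sh
methyldec fixtures  --out demo --seed 3
methyldec simulate  --preset reduced-c13 --n-train 2000 --n-test 300 \
                    --seed 42 --out pairs.h5
methyldec train     --preset reduced-c13 --dataset pairs.h5 --out c13.npz
methyldec enhance2d --in demo/bench/hdac_like_000_coupled.fid \
                    --c13-model c13.npz --out enhanced.ft2
methyldec benchmark --suite demo/bench/manifest.json --c13-model c13.npz \
                    --report report.json
methyldec noe-fit   --in demo/noe_records.tsv --out fit.json
```

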