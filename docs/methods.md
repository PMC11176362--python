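# Methods

## The problem and the signal model

Methyl `13C-1H` correlation spectra of large, protonated, uniformly
`13C`-labelled proteins are hard to interpret for two reasons: every
aliphatic carbon is scalar-coupled to its `13C` neighbours (one-bond
`1J_CC` around 34 Hz), splitting indirect-dimension signals into
multiplets, and the lack of deuteration broadens lines in both dimensions
through dipolar relaxation.  `methyldec` implements the computational
route around both problems: two neural networks, applied inside an
otherwise conventional Fourier-processing pipeline, remove one coupling
modulation per signal in the `13C` dimension and sharpen lines in both
dimensions.

Everything in the package rests on one time-domain signal model:

    s(t_k) = sum_j a_j exp(i 2 pi f_j t_k) exp(-R2_j t_k)
                  prod_c cos(pi J_c t_k),     t_k = k / sw.

Methyl carbons carry exactly one coupling (doublets in the `13C`
dimension), non-methyl CH carbons two (triplets).  `1H-1H` couplings,
cross-correlated relaxation and methyl rotor dynamics are deliberately
outside the model: shifts, exponential decay and `13C-13C` cosine factors
only.

## The target transformation

The networks map an input FID to a target FID in which (i) exactly one
cosine factor per signal is removed — doublets become singlets, triplets
become doublets — and (ii) the decay rate is replaced by

    R2_tar = max( R2max tanh(R2in/R2max), R2max (1 - tanh(R2in/R2max)) ),

with `R2max = 25 1/s`.  The map is bounded in `[R2max/2, R2max]`:
broad signals are sharpened towards `R2max` while already-sharp signals
are *broadened* slightly towards it, giving near-uniform target
linewidths and avoiding truncation artefacts from over-sharpening.
The minimum `R2max/2` sits at `R2in = R2max atanh(1/2) ≈ 13.7 1/s`.

## Network architecture

Both networks are stacks of gated residual units, one per entry of a
dilation schedule.  A unit applies a dilated convolution (kernel 8 along
time × 4 across the packed rows) producing `2F` channels, splits them
`F/F` through sigmoid and tanh and multiplies the halves (the standard
gated-activation reading of a 50%/50% split), then applies a second
8 × 4 convolution with `F` outputs.  That second convolution's output
feeds both the skip aggregate — whose sum a final 1 × 1 convolution maps
to the output plane — and the residual stream.  A 1 × 1 input convolution
lifts the single-channel plane to `F` channels.  Convolutions are
"same"-padded along both axes so the shape contract (4 × L in, 4 × L out)
holds; which tensor feeds the skip aggregate (the second convolution's
output, here) and the packing convention are recorded in every weight
sidecar, and weights whose sidecar disagrees are refused at load time.

Complex FIDs of length L are packed as four real rows
`[Re v, Im v, Re v(+1), Im v(+1)]` (the last two a one-sample-advanced
copy, final sample zero).  Planes entering a network are divided by their
maximum absolute value; the scale is inverted on exit.

Full-scale configurations: `13C` network — input 1024 × 4, dilations
1, 2, 4, 6, 8, 10, 12, 14, 16, 20, 24, 28, 32, 40, 48, 56, 64, 128 filters;
`1H` network — input 512 × 4, dilations 1…32 (13 values), 64 filters.

The networks, backpropagation and the optimiser are implemented directly
in numpy (channels-last im2col + BLAS matmuls); training the reduced
configurations below takes minutes on one CPU core.

## Loss and optimisation

The training loss is the mean squared modulus of the complex difference
between the Fourier transforms of predicted and target planes
("frequency-domain MSE"), taken over both quadratures.  Comparing only
the absorptive (real) component would leave an L-dimensional null space —
anticausal admixtures with zero real spectrum — through which a network
can emit sideband artefacts invisible to the loss yet present in the
magnitude spectrum; the two-quadrature loss closes it.  By Parseval the
loss equals L times the time-domain MSE and its gradient is proportional
to the time-domain residual.

Optimisation is RMSprop (rho 0.9, epsilon 1e-7) with a two-phase plateau
schedule: learning rate 1e-4 until the validation loss stops improving by
more than `min_delta` for `patience` epochs (defaults 1e-6 and 5; the
plateau definition is this package's own choice), then 1e-5 until
a second plateau ends training.  `TrainConfig.momentum` adds the standard
RMSprop momentum term (default 0 = plain RMSprop).

## Synthetic training data

Training planes are drawn per pair: 1–8 signals (13C full scale),
frequencies uniform over the central 90% of the window, sweep width
uniform 2000–5000 Hz, decay rates uniform 5–100 1/s (a broad bracket of
the per-protein normal distributions below), couplings normal(34, 2) Hz
(one per signal for the `13C` network, none for `1H`), amplitudes
log-uniform over one decade, signal phases zero, and complex Gaussian
noise on the input plane only with sigma uniform up to 4% of the plane
maximum (experimental data are noisy; targets stay ideal).  The full-scale
dataset sizes are 500,000 training and 50,000 test pairs; the generator
streams them to HDF5 (float16 planes — the normalised dynamic range makes
quantisation ≈ 5e-4, below the noise floor — with float32 scales and
NaN-padded per-signal parameter metadata for auditability).

## Benchmark spectra

The benchmark generator emulates realistic correlation maps of two
protein sizes: `hdac_like` spectra carry 275 signals with decay rates
normal(50, 10) 1/s in both dimensions; `msg_like` spectra carry 600
signals with normal(60, 15) (`1H`) and normal(60, 10) (`13C`).  Per
spectrum the spectrometer field is drawn from {600, 700, 800, 950} MHz
and both sweep widths uniform 2000–5000 Hz (the `13C` range is read as
2000–5000 for both kinds).  Half of the signals are methyls whose shifts
come from a per-site table of means and standard deviations for Ala-beta,
Ile-delta1/gamma2, Leu-delta1/2, Val-gamma1/2, Thr-gamma2 and Met-epsilon
— a synthetic, literature-plausible emulation of database statistics, not
extracted values — truncated to the acquired window.  The other half are
non-methyl CH triplets placed uniformly in a configured higher-frequency
region (`1H` 2.6–5.4 ppm, `13C` 24–36 ppm) intersected with the window;
when a narrow window cannot reach that region they fall back to its
high-frequency 30%.  Amplitudes are log-uniform over a decade; complex
Gaussian noise with sigma 2% of the median amplitude is added to every
quadrature component.  Default grids are 512 (`1H`) × 128 (`13C`) complex
points — half of typical experimental acquisition sizes, chosen so a 200-spectrum
suite is generated in well under a minute.  The idealised target grid of
each spectrum removes one coupling per signal, maps both decay rates
through the target-rate function and carries no noise; the truth list
stores coupling-free positions, amplitudes, multiplicities and methyl
flags.

## Processing pipeline

2D workflow: FT of the detected `1H` dimension (first point scaled 0.5,
zero-fill ×2, zero phase by default) and discard of imaginaries;
combination of the States-interleaved `13C` axis into complex vectors;
packing and `13C` network; `13C` FT; Hilbert reconstruction of the `1H`
imaginaries; inverse `1H` FT back to (causal) time domain; `1H` network;
final `1H` FT.  No apodization is applied to data entering a network —
the networks are trained on unapodized decays — while an optional cosine
bell acts at every post-network transform (the `13C` FT and the final
display FT), where it suppresses the truncation ringing of the sharpened
FIDs.  Vectors shorter than a network's input length are zero-filled to it;
longer vectors are rejected with instructions to band-select/truncate
first.  3D NOESY spectra run the same route with the `13C` network
applied along each indirect axis in turn, NOESY axis first (an arbitrary
but fixed, logged order; a single-axis option exists because decoupling
only one indirect dimension is an equally defensible protocol).

Because the `1H` data are zero-filled before the first FT, the time
signal is exactly causal and the Hilbert/IFT/FT detour is an exact
identity on the real part (to float roundoff); with identity stand-in
networks the whole pipeline therefore agrees with plain DFT processing at
double precision, which is regression-tested.  Every operation appends a
provenance entry sufficient to replay the processing.

Frequency axes are stored in descending ppm (display order); ppm↔Hz uses
`offset = (ppm - carrier) × Larmor(MHz)` exactly.

## Benchmark scoring

Distances between peaks combine the dimensions as
`d = max(|Δh|, |Δc|/4)` in `1H` ppm equivalents — the 4:1 equivalence is
fixed by the stated isolation thresholds (0.06 `1H` ppm = 0.24 `13C`
ppm), and the Chebyshev combination keeps each axis auditable.  A truth
peak is *isolated* when its nearest truth neighbour is ≥ 0.06 away in
this metric.  Scoring defaults restrict truth to doublet (methyl) signals
and drop truth and picked peaks more than 1.50 `1H` ppm from every methyl
truth peak; the two filters are independent toggles because either reading of
the exclusion rule is defensible.  Matching is greedy one-to-one within a
0.03 radius, consumed closest-first (the literal "descending order of
distance" is exposed via a flag; closest-first is the default because the
literal order discards the best candidates first, which we read as a
slip).  Rates: `tp = matched/|isolated truth|`, `fn = 1 − tp`,
`fp = unmatched picked/|retained picked|` — the denominator is the
retained picked count so the rate is scale-free across spectra; suite
aggregation averages per-spectrum rates.

The peak picker is a local-maximum detector (8-neighbourhood) above
`k·sigma`, where sigma is 1.4826 × MAD of the lowest-|intensity| quartile
of grid points, with 3-point parabolic refinement per axis; the default
threshold is 8 sigma, which yields near-zero false positives on idealised
targets in the fixture tests.  It documents its own behaviour and does
not try to reproduce any external picker's internals.

## NOE analysis

Cross-peak volumes are box sums over the frequency grid; normalised
volumes are cross/diagonal.  Records are binned in 0.2 Å distance
intervals (mean = sum/count per bin) over the 3.0–5.0 Å window, and
`V = C r^(-b)` is fitted by least squares on `(log r, log V)` over the
individual records — log-space OLS linearises the model and is exactly
reproducible; the constrained `b = 6` fit of `C` is reported alongside the
floating-exponent fit, since fixing the theoretical exponent is the
other common convention.
Distances come from user-supplied tables; structure parsing is out of
scope.

## Reduced (desk-scale) demonstrations

Training the full-scale networks is accelerator-scale work, so the test
suite demonstrates the learning claim at a reduced scale chosen once:
`13C` network with two short dilation cycles (1, 1, 2, 2, 4, 8, 16, 16)
and 8 filters on 128-point FIDs at a fixed 2000 Hz sweep width, trained
on 1,500 single-doublet pairs (rates uniform 20–80 1/s, couplings
normal(34, 2) Hz, input noise up to 3%) with RMSprop momentum 0.9 at
learning rate 2e-3 → 5e-4 (plateau patience 3), batch 32, ≤ 16 epochs —
about ten minutes on one CPU core.  Depth matters here: removing a cosine
modulation is a composed multiplicative computation (squaring a doublet
FID already contains an unmodulated component at twice the frequency),
and the two-cycle stack clearly outperforms a single wider cycle at equal
cost in our experiments.

Evaluation uses held-out isolated doublets: "converted" means the
cosine-apodized display FT has exactly one local maximum above 25% of the
spectrum maximum, with the global maximum within one grid step of the
true shift (apodization is essential — sharpened FIDs are truncated, and
the unwindowed FT of even a perfect target rings at ~15% of the peak).
The reduced network cuts the identity-baseline spectral loss on that set
by ~6.5× and places its dominant maximum at the true shift essentially
always, but retains residual ±J/2 sidebands of ~30% of the peak, so most
outputs are "singlet plus minor ghost" rather than clean singlets; clean
conversion at desk scale would need substantially more optimisation time
than the reduced budget allows.  A matching reduced `1H` sharpener (256
points, 3 dilations) and a density-matched benchmark configuration (137
signals on the half-size grid, preserving the full-scale per-area peak
density) support an end-to-end check of the decoupling direction: the
mean number of picked components inside a ±J window around each isolated
methyl truth peak drops materially relative to conventionally processed
spectra.  The true-positive rate itself cannot carry that comparison: a
doublet component lies J/2 from the truth position, within the protocol's
0.03-ppm matching radius at every benchmark field, so conventionally
processed spectra match isolated truths perfectly by construction.  The
reduced demonstrations establish that the architecture, loss, data
distribution and pipeline wiring are correct and learn the intended
transformation; they do not measure full-scale performance, which is
accelerator-scale work.

## Numerical choices and degenerate inputs

- Single-precision throughout the networks; float64 is available for
  gradient checking (the backward pass matches finite differences to
  ~1e-6 relative).
- FID synthesis in the bulk generators uses cumulative products of the
  per-sample complex ratio (couplings expanded into sums of exponentials);
  drift is ~1e-5 relative over 1024 points, below the stored float16
  quantisation.
- Empty signal lists synthesize a zero FID with a warning; all-zero
  spectra pick no peaks; empty truth lists flag the benchmark report
  degenerate; NOE fits refuse < 5 records, < 3 occupied bins or
  degenerate distance spreads.
- Peak-pick ties across plateaus resolve to the first grid point
  (maximum-filter equality); parabolic offsets are clamped to ± half a
  bin.
- nmrPipe-format I/O implements the documented subset needed to
  round-trip the package's own grids (sizes, sweep widths,
  observe/carrier frequencies, quadrature/FT flags, axis labels) as a
  512-float32 header at the canonical word offsets; it is not a full
  re-implementation of the format.

## Known limitations

- Per-vector normalisation on network entry amplifies vectors that
  contain only noise (an empty column's maximum is the noise amplitude),
  so enhanced spectra carry an elevated artefact floor in signal-free
  regions, and the trained biases add a small constant response even to
  empty input.  Peak-picking thresholds are noise-relative, which absorbs
  part of this, but false-positive accounting on enhanced spectra is
  pessimistic at desk scale.

- The synthetic generator draws all signals with zero phase and no
  first-order phase errors; experimental spectra need phasing before the
  pipeline's assumptions hold.
- Peak intensities after enhancement are not quantitative (the sharpening
  deliberately reshapes lines); volume-based analyses should use the
  conventional FT path.
- The reduced networks are trained at fixed sweep widths and do not
  generalise across dwell times; the full-scale configurations exist for
  that and train the same way, given the compute.
- Non-methyl signal placement is a configured emulation; real spectra
  fold distant signals into the window in ways the generator does not
  model.
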