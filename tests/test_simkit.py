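"""Signal model, training pairs and benchmark generator."""

import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methyldec.axes import AxisSpec, c13_larmor
from methyldec.shiftstats import default_shift_stats, validate_shift_stats
from methyldec.simkit import (
    BenchmarkConfig,
    SignalSpec,
    TrainingSetConfig,
    draw_benchmark_signals,
    generate_benchmark_spectrum,
    generate_benchmark_suite,
    generate_pairs,
    generate_training_set,
    make_training_pair,
    pack_fid,
    synthesize_fid,
    synthesize_time_grid,
    target_r2,
    truth_peaklist,
    unpack_plane,
)

AXIS_C = AxisSpec(256, 4000.0, c13_larmor(800.0), 19.5, "13C")
AXIS_H = AxisSpec(256, 4000.0, 800.0, 1.2, "1H")


def _signal(**kw):
    base = dict(
        shift_h=1.0, shift_c=19.5, amplitude=1.0, r2_h=30.0, r2_c=30.0,
        couplings_c=(34.0,), is_methyl=True,
    )
    base.update(kw)
    return SignalSpec(**base)


# ----------------------------------------------------------------------
# target_r2
# ----------------------------------------------------------------------
class TestTargetR2:
    @pytest.mark.parametrize(
        "r2_in,expected",
        [
            (0.0, 25.0),                          # tanh(0) forces the 1-tanh branch
            (1e6, 25.0),                          # tanh -> 1 limit
            (25.0, 25.0 * np.tanh(1.0)),          # high-precision evaluation
            (25.0 * np.arctanh(0.5), 12.5),       # branch-equality point
        ],
    )
    def test_closed_form_values(self, r2_in, expected):
        assert target_r2(r2_in, 25.0) == pytest.approx(expected, abs=1e-9)

    def test_bounded_and_minimum_location(self):
        grid = np.linspace(0.0, 500.0, 200001)
        vals = target_r2(grid, 25.0)
        assert vals.min() >= 12.5 - 1e-12 and vals.max() <= 25.0 + 1e-12
        argmin = grid[np.argmin(vals)]
        assert argmin == pytest.approx(25.0 * np.arctanh(0.5), abs=grid[1])

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            target_r2(-1.0)


# ----------------------------------------------------------------------
# synthesize_fid
# ----------------------------------------------------------------------
class TestSynthesizeFid:
    def test_on_carrier_no_decay_gives_ones(self):
        sig = SignalSpec(1.2, 19.5, 1.0, 1e-12, 1e-12, (), False)
        fid = synthesize_fid([sig], AXIS_C, "13C")
        assert np.allclose(fid, 1.0, atol=1e-8)

    def test_first_point_is_amplitude_sum(self):
        rng = np.random.default_rng(0)
        sigs = [
            _signal(amplitude=float(a), shift_c=float(s))
            for a, s in zip(rng.uniform(0.5, 2, 5), rng.uniform(15, 24, 5))
        ]
        fid = synthesize_fid(sigs, AXIS_C, "13C")
        assert fid[0] == pytest.approx(sum(s.amplitude for s in sigs))

    def test_doublet_splitting_is_the_coupling(self):
        # FT oracle: cosine modulation makes sidebands at +-J/2; use a
        # fully decayed FID so truncation ripple cannot shift the maxima
        ax = AxisSpec(1024, 4000.0, c13_larmor(800.0), 19.5, "13C")
        sig = _signal(r2_c=25.0)
        fid = synthesize_fid([sig], ax, "13C")
        spec = np.abs(np.fft.fftshift(np.fft.fft(fid, 4096)))
        freqs = np.fft.fftshift(np.fft.fftfreq(4096, 1.0 / ax.sweep_width))
        peaks = []
        for i in range(1, 4095):
            if spec[i] > spec[i - 1] and spec[i] > spec[i + 1]:
                peaks.append((spec[i], freqs[i]))
        peaks.sort(reverse=True)
        sep = abs(peaks[0][1] - peaks[1][1])
        assert sep == pytest.approx(34.0, abs=ax.sweep_width / 4096 * 2)

    def test_decoupled_removes_exactly_one_coupling(self):
        trip = _signal(is_methyl=False, couplings_c=(34.0, 36.0))
        dec = synthesize_fid([trip], AXIS_C, "13C", decoupled=True)
        ref = synthesize_fid(
            [_signal(is_methyl=True, couplings_c=(36.0,))], AXIS_C, "13C"
        )
        assert np.allclose(dec, ref)

    def test_empty_list_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning):
            fid = synthesize_fid([], AXIS_C, "13C")
        assert not fid.any()

    def test_amplitude_conservation_under_decoupling(self):
        # cosine modulation redistributes intensity; the integral over the
        # multiplet (= first FID point) is invariant
        sig = _signal(r2_c=40.0)
        a = synthesize_fid([sig], AXIS_C, "13C")
        b = synthesize_fid([sig], AXIS_C, "13C", decoupled=True)
        int_a = np.fft.fft(a).real.sum()
        int_b = np.fft.fft(b).real.sum()
        assert int_a == pytest.approx(int_b, rel=1e-2)


# ----------------------------------------------------------------------
# SignalSpec invariants
# ----------------------------------------------------------------------
class TestSignalSpec:
    def test_methyl_must_be_doublet(self):
        with pytest.raises(ValueError):
            _signal(couplings_c=(34.0, 35.0))

    def test_non_methyl_must_be_triplet(self):
        with pytest.raises(ValueError):
            _signal(is_methyl=False, couplings_c=(34.0,))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            _signal(shift_c=np.nan)


# ----------------------------------------------------------------------
# Packing and training pairs
# ----------------------------------------------------------------------
class TestTrainingPairs:
    def test_pack_unpack_roundtrip(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        plane = pack_fid(v, 80)
        assert plane.shape == (4, 80)
        assert np.allclose(unpack_plane(plane, 64), v)
        # shifted-copy rows
        assert np.allclose(plane[2, :63], v.real[1:])
        assert plane[2, 63:].max() == 0

    def test_fixed_point_h1_pair_is_identity(self):
        # a coupling-free signal whose R2 is the fixed point of the
        # target-rate map: input and target FIDs coincide
        from scipy.optimize import brentq

        r2_fix = brentq(lambda r: target_r2(r) - r, 1.0, 24.9)
        assert target_r2(r2_fix) == pytest.approx(r2_fix, abs=1e-9)
        sig = SignalSpec(1.0, 19.5, 1.0, r2_fix, 30.0, (), False)
        pair = make_training_pair([sig], AXIS_H, "h1")
        assert np.allclose(pair.input_plane, pair.target_plane, atol=1e-9)

    def test_c13_pair_collapses_doublet(self):
        sig = _signal(r2_c=60.0)
        pair = make_training_pair([sig], AXIS_C, "c13")

        def n_major_maxima(plane):
            spec = np.abs(np.fft.fft(unpack_plane(plane)))
            return sum(
                1
                for i in range(spec.size)
                if spec[i] > spec[i - 1]
                and spec[i] > spec[(i + 1) % spec.size]
                and spec[i] > 0.3 * spec.max()
            )

        assert n_major_maxima(pair.target_plane) == 1
        assert n_major_maxima(pair.input_plane) == 2

    def test_seeded_batches_are_bit_identical(self):
        cfg = TrainingSetConfig(network="c13", n_points=64)
        a = generate_pairs(cfg, 20, np.random.default_rng(5))
        b = generate_pairs(cfg, 20, np.random.default_rng(5))
        assert np.array_equal(a["input"], b["input"])
        assert np.array_equal(a["target"], b["target"])
        c = generate_pairs(cfg, 20, np.random.default_rng(6))
        assert not np.array_equal(a["input"], c["input"])


# ----------------------------------------------------------------------
# Training-set files
# ----------------------------------------------------------------------
class TestGenerateTrainingSet:
    def test_split_counts_and_manifest(self, tmp_path):
        cfg = TrainingSetConfig(network="c13", n_points=64)
        out = tmp_path / "set.h5"
        manifest = generate_training_set(cfg, 10, 2, 3, out)
        assert manifest["n_train"] == 10 and manifest["n_test"] == 2
        import h5py

        with h5py.File(out) as h5:
            assert h5["train/input"].shape == (10, 4, 64)
            assert h5["test/input"].shape == (2, 4, 64)
            assert json.loads(h5.attrs["config"])["network"] == "c13"
            assert "re_shift1" in h5.attrs["packing"]

    def test_same_seed_reproduces_metadata_bytes(self, tmp_path):
        cfg = TrainingSetConfig(network="c13", n_points=64)
        m1 = generate_training_set(cfg, 8, 2, 7, tmp_path / "a.h5")
        m2 = generate_training_set(cfg, 8, 2, 7, tmp_path / "b.h5")
        import h5py

        with h5py.File(tmp_path / "a.h5") as a, h5py.File(tmp_path / "b.h5") as b:
            for key in ("train/meta_freq_hz", "train/meta_r2_in", "train/input"):
                assert np.array_equal(a[key][:], b[key][:], equal_nan=True)

    def test_zero_counts_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_training_set(
                TrainingSetConfig(network="h1", n_points=64), 0, 1, 0,
                tmp_path / "x.h5",
            )


# ----------------------------------------------------------------------
# Benchmark generator
# ----------------------------------------------------------------------
class TestBenchmarkGenerator:
    @pytest.mark.parametrize("kind,n", [("hdac_like", 275), ("msg_like", 600)])
    def test_signal_counts(self, kind, n):
        _, _, truth = generate_benchmark_spectrum(
            kind, rng=np.random.default_rng(0),
            config=BenchmarkConfig.preset(kind, td_h=64, td_c=32),
        )
        assert len(truth) == n
        assert truth["is_methyl"].sum() == (n + 1) // 2

    def test_half_methyl_multiplet_structure(self):
        cfg = BenchmarkConfig.preset("hdac_like", td_h=64, td_c=32)
        rng = np.random.default_rng(2)
        axis_h = AxisSpec(64, 3000.0, 800.0, cfg.carrier_h, "1H")
        axis_c = AxisSpec(32, 2000.0, c13_larmor(800.0), cfg.carrier_c, "13C")
        signals = draw_benchmark_signals(cfg, default_shift_stats(), rng,
                                         axis_h, axis_c)
        methyl = [s for s in signals if s.is_methyl]
        other = [s for s in signals if not s.is_methyl]
        assert all(len(s.couplings_c) == 1 for s in methyl)
        assert all(len(s.couplings_c) == 2 for s in other)

    def test_coupling_distribution_mean(self):
        cfg = BenchmarkConfig.preset("msg_like", n_signals=10000, td_h=16,
                                     td_c=16)
        rng = np.random.default_rng(12)
        axis_h = AxisSpec(16, 3000.0, 800.0, cfg.carrier_h, "1H")
        axis_c = AxisSpec(16, 2000.0, c13_larmor(800.0), cfg.carrier_c, "13C")
        signals = draw_benchmark_signals(cfg, default_shift_stats(), rng,
                                         axis_h, axis_c)
        j = np.array([s.couplings_c[0] for s in signals])
        se = 2.0 / np.sqrt(len(j))
        assert abs(j.mean() - 34.0) < 3 * se

    def test_missing_methyl_site_raises(self):
        stats = default_shift_stats().iloc[:-2]
        with pytest.raises(ValueError):
            validate_shift_stats(stats)

    def test_suite_counts_checksums_and_overwrite(self, tmp_path):
        cfgs = {
            k: BenchmarkConfig.preset(k, td_h=32, td_c=16, n_signals=10)
            for k in ("hdac_like", "msg_like")
        }
        out = tmp_path / "suite"
        m1 = generate_benchmark_suite(out, n_per_kind=2, seed=1, configs=cfgs)
        assert m1["n_spectra"] == 4
        with pytest.raises(FileExistsError):
            generate_benchmark_suite(out, n_per_kind=2, seed=1, configs=cfgs)
        m2 = generate_benchmark_suite(out, n_per_kind=2, seed=1, configs=cfgs,
                                      overwrite=True)
        assert [e["sha256"] for e in m1["spectra"]] == [
            e["sha256"] for e in m2["spectra"]
        ]

    def test_truth_positions_match_idealised_spectrum(self):
        # FT of the decoupled, target-R2 grid peaks at the truth positions
        from methyldec.spectro import reference_ft

        rng = np.random.default_rng(3)
        cfg = BenchmarkConfig.preset("hdac_like", n_signals=6, td_h=128,
                                     td_c=64, noise_level=0.0)
        coupled, target, truth = generate_benchmark_spectrum(
            "hdac_like", rng=rng, config=cfg
        )
        spec = reference_ft(target)
        ppm_c = spec.ppm_scale(0)
        ppm_h = spec.ppm_scale(1)
        step_c = abs(ppm_c[1] - ppm_c[0])
        step_h = abs(ppm_h[1] - ppm_h[0])
        data = np.asarray(spec.data)
        for _, row in truth.iterrows():
            r = int(np.argmin(np.abs(ppm_c - row.c_ppm)))
            c = int(np.argmin(np.abs(ppm_h - row.h_ppm)))
            window = data[max(r - 2, 0) : r + 3, max(c - 2, 0) : c + 3]
            i, j = np.unravel_index(np.argmax(window), window.shape)
            assert abs(ppm_c[max(r - 2, 0) + i] - row.c_ppm) <= step_c * 1.5
            assert abs(ppm_h[max(c - 2, 0) + j] - row.h_ppm) <= step_h * 1.5


# ----------------------------------------------------------------------
# Property tests
# ----------------------------------------------------------------------
@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    r2_in=st.floats(0.0, 1e4, allow_nan=False),
    r2_max=st.floats(1.0, 200.0, allow_nan=False),
)
def test_target_r2_bounded_for_any_input(r2_in, r2_max):
    out = target_r2(r2_in, r2_max)
    assert r2_max / 2 - 1e-9 <= out <= r2_max + 1e-9


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    ppm=st.floats(-50.0, 250.0, allow_nan=False),
    sw=st.floats(500.0, 20000.0, allow_nan=False),
    carrier=st.floats(-5.0, 200.0, allow_nan=False),
)
def test_ppm_hz_conversion_exactly_invertible(ppm, sw, carrier):
    ax = AxisSpec(64, sw, 150.9, carrier, "13C")
    assert ax.hz_to_ppm(ax.ppm_to_hz(ppm)) == pytest.approx(ppm, abs=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(n=st.integers(8, 96), pad=st.integers(0, 32), seed=st.integers(0, 999))
def test_pack_unpack_roundtrip_property(n, pad, seed):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    assert np.allclose(unpack_plane(pack_fid(v, n + pad), n), v)


# ----------------------------------------------------------------------
# 3D assembly
# ----------------------------------------------------------------------
def test_3d_grid_shapes_and_interleave():
    sigs = [
        SignalSpec(1.0, 18.0, 1.0, 30.0, 30.0, (34.0,), True),
        SignalSpec(1.0, 22.0, 1.0, 30.0, 30.0, (34.0,), True),
    ]
    ax3 = AxisSpec(16, 2000.0, c13_larmor(800.0), 19.5, "13C")
    ax2 = AxisSpec(12, 2000.0, c13_larmor(800.0), 19.5, "13C")
    axh = AxisSpec(32, 3000.0, 800.0, 1.2, "1H")
    g = synthesize_time_grid(sigs, [ax3, ax2, axh])
    assert g.data.shape == (32, 24, 32)
    assert g.interleaved == [True, True, False]
    # first hypercomplex component at t=0 is the amplitude sum
    assert g.data[0, 0, 0] == pytest.approx(2.0)
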