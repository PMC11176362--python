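"""Spectral axis metadata and ppm/Hz bookkeeping.

An :class:`AxisSpec` describes one dimension of an NMR experiment: the
number of complex (quadrature) points sampled, the sweep width in Hz, the
Larmor frequency of the observed nucleus in MHz and the carrier position in
ppm.  The chemical-shift convention used throughout the package is

    offset_hz = (shift_ppm - carrier_ppm) * larmor_frequency_MHz

which is exactly invertible.  Frequency axes are stored left-to-right in
descending ppm (standard NMR display order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: 1H spectrometer fields (MHz) used by the synthetic benchmark.
ALLOWED_FIELDS_MHZ = (600.0, 700.0, 800.0, 950.0)

#: gamma(13C)/gamma(1H); maps a 1H field in MHz to the 13C Larmor frequency.
GAMMA_RATIO_C13 = 0.251449530


@dataclass(frozen=True)
class AxisSpec:
    """Sampling and frequency metadata for one spectral dimension."""

    n_complex_points: int
    sweep_width: float          # Hz
    larmor_frequency: float     # MHz of the observed nucleus
    carrier: float              # ppm
    nucleus: str                # "1H" or "13C"

    def __post_init__(self) -> None:
        if self.n_complex_points < 8:
            raise ValueError("n_complex_points must be >= 8")
        if self.sweep_width <= 0:
            raise ValueError("sweep_width must be positive")
        if self.larmor_frequency <= 0:
            raise ValueError("larmor_frequency must be positive")
        if self.nucleus not in ("1H", "13C"):
            raise ValueError(f"unknown nucleus {self.nucleus!r}")

    @property
    def dwell(self) -> float:
        """Dwell time in seconds."""
        return 1.0 / self.sweep_width

    def times(self, n: int | None = None) -> np.ndarray:
        """Sampling times t_k = k / sweep_width for k = 0..n-1."""
        if n is None:
            n = self.n_complex_points
        return np.arange(n) / self.sweep_width

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        """Offset from the carrier in Hz of a resonance at ``ppm``."""
        return (np.asarray(ppm) - self.carrier) * self.larmor_frequency

    def hz_to_ppm(self, hz: float | np.ndarray) -> float | np.ndarray:
        """Inverse of :meth:`ppm_to_hz`."""
        return np.asarray(hz) / self.larmor_frequency + self.carrier

    def ppm_scale(self, n_points: int) -> np.ndarray:
        """Descending ppm scale of a frequency axis with ``n_points`` bins.

        Bin b covers the offset sw/2 - (b+1)*sw/n relative to the carrier,
        i.e. high-field (large ppm) on the left, the NMR display convention
        (the first bin after the fftshift/flip pair is sw/2 - sw/n).
        """
        offsets = self.sweep_width / 2.0 - (np.arange(n_points) + 1) * (
            self.sweep_width / n_points
        )
        return self.hz_to_ppm(offsets)

    def ppm_window(self) -> tuple[float, float]:
        """(low, high) ppm limits of the spectral window."""
        half = self.sweep_width / 2.0 / self.larmor_frequency
        return (self.carrier - half, self.carrier + half)

    def with_points(self, n: int) -> "AxisSpec":
        return replace(self, n_complex_points=n)


def validate_field(field_mhz: float, allowed=ALLOWED_FIELDS_MHZ) -> float:
    if field_mhz not in allowed:
        raise ValueError(
            f"Larmor field {field_mhz} MHz not in the configured set {allowed}"
        )
    return field_mhz


def c13_larmor(field_mhz: float) -> float:
    """13C Larmor frequency (MHz) at a given 1H field."""
    return field_mhz * GAMMA_RATIO_C13
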