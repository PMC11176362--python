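"""The in-memory spectrum container used by the processing pipeline.

``SpectrumGrid`` wraps an N-dimensional numpy array together with one
:class:`~methyldec.axes.AxisSpec` per dimension, per-axis domain flags
("time" or "freq") and a provenance log.  Quadrature conventions:

* the directly detected axis holds complex dtype data;
* indirect time axes are stored *interleaved* (States convention): the axis
  length is ``2 * n_complex_points`` with the cosine-modulated component on
  even indices and the sine-modulated component on odd indices.  Combining
  an interleaved axis produces complex data of half the length.

At most one axis carries live complex data at any point in the pipeline;
the processing order (detected axis first) guarantees this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axes import AxisSpec


@dataclass
class SpectrumGrid:
    data: np.ndarray
    axes: list[AxisSpec]
    domains: list[str]            # "time" | "freq" per axis
    interleaved: list[bool]       # States interleave flag per axis
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != len(self.axes):
            raise ValueError("axes length must equal data rank")
        if not (len(self.axes) == len(self.domains) == len(self.interleaved)):
            raise ValueError("per-axis metadata lists must have equal length")
        for d in self.domains:
            if d not in ("time", "freq"):
                raise ValueError(f"bad domain flag {d!r}")

    # ------------------------------------------------------------------
    def log(self, entry: str) -> None:
        self.provenance.append(entry)

    def copy(self) -> "SpectrumGrid":
        return SpectrumGrid(
            self.data.copy(),
            list(self.axes),
            list(self.domains),
            list(self.interleaved),
            list(self.provenance),
        )

    # ------------------------------------------------------------------
    def combine_interleaved(self, axis: int) -> "SpectrumGrid":
        """Merge a States-interleaved time axis into complex data.

        Even rows (cosine component) become the real part, odd rows (sine
        component) the imaginary part; the axis length halves.
        """
        if not self.interleaved[axis]:
            raise ValueError(f"axis {axis} is not interleaved")
        if self.data.shape[axis] % 2:
            raise ValueError("interleaved axis must have even length")
        cos = np.take(self.data, np.arange(0, self.data.shape[axis], 2), axis=axis)
        sin = np.take(self.data, np.arange(1, self.data.shape[axis], 2), axis=axis)
        g = self.copy()
        g.data = cos + 1j * sin
        g.interleaved[axis] = False
        g.log(f"combine_interleaved(axis={axis})")
        return g

    def discard_imaginary(self) -> "SpectrumGrid":
        """Keep the real component of the data (after phasing)."""
        g = self.copy()
        g.data = np.ascontiguousarray(self.data.real)
        g.log("discard_imaginary")
        return g

    # ------------------------------------------------------------------
    def ppm_scale(self, axis: int) -> np.ndarray:
        """Descending ppm scale of a frequency-domain axis."""
        if self.domains[axis] != "freq":
            raise ValueError(f"axis {axis} is not in the frequency domain")
        return self.axes[axis].ppm_scale(self.data.shape[axis])

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.data).all())
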