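"""NOE cross-peak volumes and the volume-distance power law.

Cross-relaxation makes the NOE cross-peak volume scale approximately as
the inverse sixth power of the interproton distance, V = C / r^6.  This
module integrates peak volumes from processed spectra, normalises cross
peaks by their diagonal peaks, bins the normalised volumes in 0.2 A
distance intervals and fits the power law.  The fit is ordinary least
squares in log space, log V = log C - b log r, reported both with the
exponent floating and constrained to b = 6.

Interproton distances come from user-supplied tables (computed externally,
e.g. from a deposited structure); structure parsing is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import SpectrumGrid

DISTANCE_WINDOW = (3.0, 5.0)  # Angstrom
BIN_WIDTH = 0.2               # Angstrom


@dataclass(frozen=True)
class NoeRecord:
    """One NOE observation: volumes in arbitrary (shared) units, r in A."""

    cross_volume: float
    diagonal_volume: float
    distance: float

    def __post_init__(self) -> None:
        if self.cross_volume <= 0 or self.diagonal_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.distance <= 0:
            raise ValueError("distance must be positive")

    @property
    def normalised_volume(self) -> float:
        return self.cross_volume / self.diagonal_volume


def integrate_volume(
    grid: SpectrumGrid, center: tuple, box: tuple
) -> float:
    """Sum of intensities over a box (in bins) centred on a ppm position.

    ``center`` is a ppm tuple ordered like the grid axes; ``box`` gives the
    half-width in bins per axis.  Boxes extending beyond the grid are
    clipped with a warning.  Deterministic; linear in the data.
    """
    if any(d != "freq" for d in grid.domains):
        raise ValueError("integrate_volume expects a frequency-domain spectrum")
    data = np.asarray(grid.data.real, dtype=float)
    slices = []
    clipped = False
    for ax, (ppm, half) in enumerate(zip(center, box)):
        scale = grid.ppm_scale(ax)
        idx = int(np.argmin(np.abs(scale - ppm)))
        lo, hi = idx - int(half), idx + int(half) + 1
        if lo < 0 or hi > data.shape[ax]:
            clipped = True
        slices.append(slice(max(lo, 0), min(hi, data.shape[ax])))
    if clipped:
        import warnings

        warnings.warn("integration box clipped to the grid", stacklevel=2)
    return float(data[tuple(slices)].sum())


def bin_records(records, bin_width: float = BIN_WIDTH) -> pd.DataFrame:
    """Mean normalised volume per distance bin (sum / count)."""
    r = np.array([rec.distance for rec in records])
    v = np.array([rec.normalised_volume for rec in records])
    edges = np.arange(
        np.floor(r.min() / bin_width) * bin_width,
        r.max() + bin_width,
        bin_width,
    )
    idx = np.digitize(r, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue  # empty bins are skipped
        rows.append(
            {
                "r_lo": edges[b],
                "r_hi": edges[b + 1],
                "r_mid": 0.5 * (edges[b] + edges[b + 1]),
                "mean_volume": v[sel].mean(),
                "count": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def bin_and_fit(records, bin_width: float = BIN_WIDTH) -> dict:
    """Bin normalised volumes and fit V = C * r**(-b).

    Requires at least 5 records spanning at least 3 occupied bins.  The
    floating-exponent fit is least squares on (log r, log V) over the
    individual records; the constrained fit (b = 6) reports the matching C.
    Returns a dict with ``C``, ``exponent``, ``C_b6`` and the binned table.
    """
    records = list(records)
    if len(records) < 5:
        raise ValueError("need at least 5 records")
    binned = bin_records(records, bin_width)
    if len(binned) < 3:
        raise ValueError("records must span at least 3 distance bins")
    r = np.array([rec.distance for rec in records])
    v = np.array([rec.normalised_volume for rec in records])
    if np.ptp(np.log(r)) < 1e-12:
        raise ValueError("degenerate distance spread")
    slope, intercept = np.polyfit(np.log(r), np.log(v), 1)
    c_b6 = float(np.exp(np.mean(np.log(v) + 6.0 * np.log(r))))
    return {
        "C": float(np.exp(intercept)),
        "exponent": float(-slope),
        "C_b6": c_b6,
        "binned": binned,
        "n_records": len(records),
    }


def simulate_noe_records(
    n: int,
    c: float = 50.0,
    exponent: float = 6.0,
    noise_cv: float = 0.0,
    distance_window: tuple = DISTANCE_WINDOW,
    rng: np.random.Generator | None = None,
    diagonal_volume: float = 1.0,
) -> list:
    """Synthetic NOE records under the power-law model.

    Distances are uniform over the window; with ``noise_cv`` > 0 the
    volumes carry lognormal noise of that coefficient of variation.
    """
    if rng is None:
        rng = np.random.default_rng()
    r = rng.uniform(*distance_window, size=n)
    v = c * r ** (-exponent)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        v = v * rng.lognormal(-0.5 * sigma ** 2, sigma, size=n)
    return [
        NoeRecord(float(vi * diagonal_volume), diagonal_volume, float(ri))
        for vi, ri in zip(v, r)
    ]


def load_records_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        NoeRecord(row.cross_volume, row.diagonal_volume, row.distance)
        for row in df.itertuples()
    ]


def save_fit_json(fit: dict, path) -> None:
    import json

    out = dict(fit)
    out["binned"] = fit["binned"].to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
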