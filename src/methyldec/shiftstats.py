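"""Per-methyl-type chemical-shift statistics for the benchmark generator.

The table gives mean and standard deviation of the 1H and 13C shifts of the
methyl groups observable in uniformly 13C-labelled proteins (Ala beta,
Ile delta1/gamma2, Leu delta1/delta2, Val gamma1/gamma2, Thr gamma2,
Met epsilon).  The default table is a synthetic, literature-plausible
emulation of database (BMRB-style) methyl shift statistics, shipped so the
generator is self-contained; it is not a database extract.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

REQUIRED_SITES = [
    ("ALA", "CB"),
    ("ILE", "CD1"),
    ("ILE", "CG2"),
    ("LEU", "CD1"),
    ("LEU", "CD2"),
    ("VAL", "CG1"),
    ("VAL", "CG2"),
    ("THR", "CG2"),
    ("MET", "CE"),
]

# residue_type, methyl_site, mean_h, sd_h, mean_c, sd_c   (ppm)
_DEFAULT_ROWS = """\
residue_type\tmethyl_site\tmean_shift_h\tsd_shift_h\tmean_shift_c\tsd_shift_c
ALA\tCB\t1.39\t0.26\t19.0\t1.8
ILE\tCD1\t0.68\t0.29\t13.4\t1.7
ILE\tCG2\t0.78\t0.27\t17.4\t1.4
LEU\tCD1\t0.76\t0.28\t24.6\t1.6
LEU\tCD2\t0.73\t0.29\t24.0\t1.7
VAL\tCG1\t0.83\t0.27\t21.4\t1.4
VAL\tCG2\t0.80\t0.29\t21.3\t1.6
THR\tCG2\t1.14\t0.24\t21.6\t1.2
MET\tCE\t1.86\t0.42\t17.2\t1.3
"""


def default_shift_stats() -> pd.DataFrame:
    """The shipped synthetic methyl shift-statistics table."""
    return pd.read_csv(io.StringIO(_DEFAULT_ROWS), sep="\t")


def validate_shift_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Check column schema, positive SDs and coverage of all methyl sites."""
    cols = [
        "residue_type",
        "methyl_site",
        "mean_shift_h",
        "sd_shift_h",
        "mean_shift_c",
        "sd_shift_c",
    ]
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"shift-stats table missing columns {sorted(missing)}")
    if not ((table["sd_shift_h"] > 0).all() and (table["sd_shift_c"] > 0).all()):
        raise ValueError("all shift standard deviations must be > 0")
    have = set(zip(table["residue_type"], table["methyl_site"]))
    absent = [site for site in REQUIRED_SITES if site not in have]
    if absent:
        raise ValueError(f"shift-stats table missing required methyl sites {absent}")
    return table


def load_shift_stats(path) -> pd.DataFrame:
    return validate_shift_stats(pd.read_csv(path, sep="\t"))


def save_shift_stats(table: pd.DataFrame, path) -> None:
    validate_shift_stats(table).to_csv(path, sep="\t", index=False)


def draw_methyl_shifts(
    table: pd.DataFrame, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (h_ppm, c_ppm) pairs from the per-site normal statistics.

    Sites are sampled uniformly; within a site the 1H and 13C shifts are
    drawn independently from the tabulated normal distributions.
    """
    validate_shift_stats(table)
    idx = rng.integers(0, len(table), size=n)
    rows = table.iloc[idx]
    h = rng.normal(rows["mean_shift_h"].to_numpy(), rows["sd_shift_h"].to_numpy())
    c = rng.normal(rows["mean_shift_c"].to_numpy(), rows["sd_shift_c"].to_numpy())
    return h, c
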