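"""Small reference tables bundled with the package."""

from __future__ import annotations

import pandas as pd

__all__ = ["load_andean_path_coefficients"]

_METRICS = ["N0", "H", "N1", "N2", "E10", "E20", "J", "TB", "LCBD"]
_FACTORS = ["connectivity", "size", "cooccurrence", "environment"]

# Standardized path coefficients reported for 21 high Andean wetland plant
# communities: effect of each of four ecological factors (wetland
# connectivity, wetland size, species co-occurrence, environmental
# variability) on each of nine community metrics, estimated by PLS path
# modeling with 10,000 bootstrap iterations.
_COEFFICIENTS = [
    # connectivity, size, cooccurrence, environment
    [0.53, -0.23, 0.18, 0.34],    # N0
    [0.50, -0.13, 0.13, -0.35],   # H
    [0.60, -0.07, 0.11, 0.28],    # N1
    [0.34, -0.07, -0.01, 0.58],   # N2
    [0.19, -0.02, -0.16, -0.43],  # E10
    [0.13, -0.06, -0.23, -0.50],  # E20
    [0.26, -0.11, -0.08, -0.50],  # J
    [0.23, -0.06, 0.001, -0.48],  # TB
    [0.38, 0.02, -0.09, -0.61],   # LCBD
]


def load_andean_path_coefficients() -> pd.DataFrame:
    """Published 9 metric x 4 factor standardized path-coefficient table.

    Rows are community metrics, columns ecological factors. Feeding this
    table to :func:`spatsig.plssem.path_summary_stats` reproduces the
    published per-factor summary statistics (mean absolute coefficient and
    coefficient of variation).
    """
    return pd.DataFrame(_COEFFICIENTS, index=_METRICS, columns=_FACTORS)
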