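"""Taxonomic community metrics per site.

Nine metrics are computed from the pooled site x species biomass matrix:

=====  =============================================================
N0     species richness (count of species with positive biomass)
H      Shannon entropy, in nats, from biomass proportions
N1     Shannon diversity (Hill number of order 1), ``exp(H)``
N2     Simpson diversity (Hill number of order 2), ``1 / sum(p^2)``
E10    Shannon evenness, ``N1 / N0``
E20    Simpson evenness, ``N2 / N0``
J      Pielou's evenness, ``H / ln(N0)`` (undefined when N0 = 1)
TB     total biomass, g/m^2
LCBD   local contribution to beta-diversity (Hellinger-based)
=====  =============================================================

Proportions are biomass shares, not individual counts — the field data are
dry weights per quadrat. Hill numbers satisfy ``N0 >= N1 >= N2`` with
equality only for perfectly even communities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import PooledCommunityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_NAMES",
    "alpha_metrics",
    "hellinger_transform",
    "lcbd",
    "diversity_profile",
]

METRIC_NAMES = ("N0", "H", "N1", "N2", "E10", "E20", "J", "TB", "LCBD")

#: richness/dominance group vs evenness group, the two families whose
#: spatial autocorrelation signatures are contrasted downstream
RICHNESS_DOMINANCE = ("N0", "H", "N1", "N2")
EVENNESS = ("E10", "E20", "J")


def alpha_metrics(biomass_row) -> dict:
    """Alpha-diversity metrics of one site from its biomass vector.

    Returns a dict with keys N0, H, N1, N2, E10, E20, J, TB. ``J`` is NaN
    for single-species sites (0/0); by the formulas E10 = E20 = 1 there.
    """
    b = np.asarray(biomass_row, dtype=float)
    if b.ndim != 1:
        raise ValueError("expected a 1-d biomass vector")
    if (b < 0).any() or not np.all(np.isfinite(b)):
        raise ValueError("biomass must be finite and nonnegative")
    tb = b.sum()
    if tb <= 0:
        raise ValueError("all-zero biomass row; drop the site upstream")
    p = b[b > 0] / tb
    n0 = int(p.size)
    h = float(-(p * np.log(p)).sum())
    n1 = float(np.exp(h))
    n2 = float(1.0 / (p**2).sum())
    if n0 > 1:
        j = h / np.log(n0)
    else:
        j = float("nan")
        logger.warning("single-species site: Pielou's J undefined, reported NaN")
    return {
        "N0": n0, "H": h, "N1": n1, "N2": n2,
        "E10": n1 / n0, "E20": n2 / n0, "J": j, "TB": float(tb),
    }


def hellinger_transform(matrix) -> np.ndarray:
    """Row-wise Hellinger transform: ``sqrt(y_ij / row_total_i)``.

    Each transformed row has unit sum of squares.
    """
    y = np.asarray(matrix, dtype=float)
    totals = y.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("zero-total row in community matrix")
    return np.sqrt(y / totals)


def lcbd(matrix) -> np.ndarray:
    """Local contributions to beta-diversity from a pooled biomass matrix.

    The matrix is Hellinger-transformed, its columns centered, and each
    site's share of the total sum of squares returned. Values sum to 1.
    """
    y = hellinger_transform(matrix)
    if y.shape[0] < 2:
        raise ValueError("LCBD needs at least two sites")
    centered = y - y.mean(axis=0, keepdims=True)
    ss_site = (centered**2).sum(axis=1)
    total = ss_site.sum()
    if total <= 0:
        raise ValueError("all sites identical: total sum of squares is zero")
    return ss_site / total


def diversity_profile(matrix: PooledCommunityMatrix | np.ndarray,
                      site_ids=None) -> pd.DataFrame:
    """The full nine-metric site table (one row per site).

    Accepts either a :class:`~spatsig.io.PooledCommunityMatrix` or a bare
    nonnegative array plus ``site_ids``.
    """
    if isinstance(matrix, PooledCommunityMatrix):
        site_ids = matrix.site_ids
        y = matrix.biomass
    else:
        y = np.asarray(matrix, dtype=float)
        if site_ids is None:
            site_ids = list(range(y.shape[0]))
    rows = [alpha_metrics(row) for row in y]
    out = pd.DataFrame(rows, index=pd.Index(site_ids, name="site_id"))
    out["LCBD"] = lcbd(y)
    return out[list(METRIC_NAMES)]
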