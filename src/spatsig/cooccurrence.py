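"""Within-site species segregation via the C-score.

For one site, species presences across its quadrats form a binary
species x quadrat matrix. For a species pair (a, b) with row totals
``r_a, r_b`` and ``S_ab`` joint occurrences, the checkerboard unit count is
``(r_a - S_ab) * (r_b - S_ab)``; the C-score is its mean over all unordered
pairs of species present at the site. Larger values mean more segregated
(less co-occurring) assemblages.

Because downstream models treat "species co-occurrence" as a positive
quantity, the per-site indicator fed to them is the additive opposite,
``cooccurrence = -c_score``: larger values mean species co-occur more.

The score is the raw (unstandardized) statistic; no null-model
standardization is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import QuadratRecords

__all__ = ["presence_matrix", "c_score", "site_cooccurrence_scores"]


def presence_matrix(records: QuadratRecords, site) -> pd.DataFrame:
    """Species x quadrat 0/1 matrix for one site (biomass > 0 = present).

    Species never present at the site are dropped.
    """
    sub = records.table[records.table["wetland_id"] == site]
    if sub.empty:
        raise KeyError(f"site {site!r} not in community records")
    quadrats = sorted(sub["quadrat_id"].unique())
    if len(quadrats) < 2:
        warnings.warn(
            f"site {site!r} has {len(quadrats)} quadrat(s); "
            "C-score is weakly informative", stacklevel=2,
        )
    wide = (
        sub.assign(present=(sub["biomass"] > 0).astype(int))
        .pivot_table(index="species_id", columns="quadrat_id",
                     values="present", aggfunc="max", fill_value=0)
        .reindex(columns=quadrats, fill_value=0)
    )
    return wide[wide.sum(axis=1) > 0].astype(int)


def c_score(m) -> float:
    """Mean checkerboard-unit count over all unordered species pairs.

    NaN (with a warning) when fewer than two species are present.
    """
    a = np.asarray(m, dtype=int)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    n_sp = a.shape[0]
    if n_sp < 2:
        warnings.warn("fewer than 2 species: C-score undefined", stacklevel=2)
        return float("nan")
    r = a.sum(axis=1)                      # row totals
    s = a @ a.T                            # joint occurrences
    iu = np.triu_indices(n_sp, k=1)
    units = (r[iu[0]] - s[iu]) * (r[iu[1]] - s[iu])
    return float(units.mean())


def site_cooccurrence_scores(records: QuadratRecords) -> pd.DataFrame:
    """Per-site C-score and its sign-flipped co-occurrence indicator."""
    rows = []
    for site in records.site_ids:
        cs = c_score(presence_matrix(records, site))
        rows.append({"site_id": site, "c_score": cs, "cooccurrence": -cs})
    return pd.DataFrame(rows).set_index("site_id")
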