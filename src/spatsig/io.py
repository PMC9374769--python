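"""Input tables, validation, and quadrat pooling.

Four flat CSV tables feed the pipeline:

* a quadrat-level community table (``wetland_id, quadrat_id, species_id,
  biomass`` in g/m^2),
* a site table with projected coordinates (meters) and the ecological
  variables entering the models,
* a landscape patch map covering every wetland patch, sampled or not,
* (optionally) pre-computed per-site ecological factors.

All validation failures raise :class:`ValidationError` with the offending
rows named, so that malformed field data never propagates silently into the
spatial analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "QuadratRecords",
    "PooledCommunityMatrix",
    "SiteTable",
    "PatchMap",
    "read_community_table",
    "read_site_table",
    "read_patch_map",
    "pool_quadrats",
]

#: ecological variables expected in the site table (beyond id and coordinates)
ECOLOGICAL_VARIABLES = (
    "altitude",
    "slope",
    "MAWS",
    "SnowNDays",
    "NDVI",
    "dNDVI",
    "wetland_size",
)


class ValidationError(ValueError):
    """An input table violates a structural or numeric invariant."""


@dataclass
class QuadratRecords:
    """Long-format quadrat-level biomass records for all sites."""

    table: pd.DataFrame  # columns: wetland_id, quadrat_id, species_id, biomass

    def __post_init__(self) -> None:
        required = ["wetland_id", "quadrat_id", "species_id", "biomass"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"community table missing columns: {missing}")
        biomass = pd.to_numeric(self.table["biomass"], errors="coerce")
        bad = self.table.index[~np.isfinite(biomass) | (biomass < 0)]
        if len(bad):
            rows = self.table.loc[bad[:10]].to_dict("records")
            raise ValidationError(
                f"negative or non-finite biomass in {len(bad)} rows, e.g. {rows}"
            )
        key = ["wetland_id", "quadrat_id", "species_id"]
        dup = self.table.duplicated(subset=key, keep=False)
        if dup.any():
            triples = (
                self.table.loc[dup, key].drop_duplicates().head(10).to_records(index=False)
            )
            raise ValidationError(
                f"duplicated (wetland, quadrat, species) triples: {list(triples)}"
            )
        self.table = self.table.assign(biomass=biomass.astype(float))

    @property
    def site_ids(self) -> list:
        return sorted(self.table["wetland_id"].unique().tolist())

    def quadrats_of(self, site) -> list:
        sub = self.table[self.table["wetland_id"] == site]
        return sorted(sub["quadrat_id"].unique().tolist())


@dataclass
class PooledCommunityMatrix:
    """Site x species biomass (g/m^2) after summing over quadrats."""

    site_ids: list
    species_ids: list
    biomass: np.ndarray  # shape (n_sites, n_species)

    def __post_init__(self) -> None:
        self.biomass = np.asarray(self.biomass, dtype=float)
        if self.biomass.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValidationError("biomass matrix shape does not match labels")
        if not np.all(np.isfinite(self.biomass)) or (self.biomass < 0).any():
            raise ValidationError("biomass matrix must be finite and nonnegative")
        if (self.biomass.sum(axis=1) <= 0).any():
            empty = [s for s, t in zip(self.site_ids, self.biomass.sum(axis=1)) if t <= 0]
            raise ValidationError(f"sites with zero total biomass: {empty}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.biomass, index=self.site_ids, columns=self.species_ids)


@dataclass
class SiteTable:
    """Per-site coordinates (projected meters) and ecological variables."""

    table: pd.DataFrame  # columns: site_id, x, y, + ecological variables
    coordinate_mode: str = "projected"

    def __post_init__(self) -> None:
        for c in ("site_id", "x", "y"):
            if c not in self.table.columns:
                raise ValidationError(f"site table missing column {c!r}")
        if self.table["site_id"].duplicated().any():
            raise ValidationError("duplicate site ids in site table")
        xy = self.table[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError("non-finite coordinates in site table")
        if self.coordinate_mode == "lonlat":
            self.table = self.table.assign(
                **dict(zip(("x", "y"), _equirectangular(xy)))
            )
            self.coordinate_mode = "projected(from lonlat)"
            logger.info("converted lon/lat coordinates to planar meters")

    @property
    def site_ids(self) -> list:
        return self.table["site_id"].tolist()

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    def variables(self, names=ECOLOGICAL_VARIABLES) -> pd.DataFrame:
        present = [n for n in names if n in self.table.columns]
        out = self.table.set_index("site_id")[present]
        if out.isna().any().any():
            bad = out.columns[out.isna().any()].tolist()
            raise ValidationError(f"missing values in ecological variables: {bad}")
        return out


@dataclass
class PatchMap:
    """All wetland patches in the landscape, sampled or not."""

    table: pd.DataFrame  # columns: patch_id, x, y, size, is_sampled, site_id

    def __post_init__(self) -> None:
        for c in ("patch_id", "x", "y"):
            if c not in self.table.columns:
                raise ValidationError(f"patch map missing column {c!r}")
        if self.table["patch_id"].duplicated().any():
            raise ValidationError("duplicate patch ids in patch map")
        if "is_sampled" not in self.table.columns:
            self.table = self.table.assign(is_sampled=False)
        if "site_id" not in self.table.columns:
            self.table = self.table.assign(site_id=pd.NA)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    @property
    def sampled_site_ids(self) -> list:
        sub = self.table[self.table["is_sampled"].astype(bool)]
        return sub["site_id"].tolist()


def _equirectangular(lonlat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat degrees to planar meters at the mean latitude."""
    R = 6_371_000.0
    lon, lat = np.radians(lonlat[:, 0]), np.radians(lonlat[:, 1])
    lat0 = lat.mean()
    return R * (lon - lon.mean()) * math.cos(lat0), R * (lat - lat0)


def read_community_table(path) -> QuadratRecords:
    """Read and validate a quadrat-level community CSV."""
    df = pd.read_csv(path)
    return QuadratRecords(df)


def read_site_table(path, community: PooledCommunityMatrix | None = None,
                    coordinate_mode: str = "projected") -> SiteTable:
    """Read the per-site coordinate/variable CSV, cross-checking site ids."""
    st = SiteTable(pd.read_csv(path), coordinate_mode=coordinate_mode)
    if community is not None:
        missing = set(community.site_ids) - set(st.site_ids)
        if missing:
            raise ValidationError(
                f"sites in community matrix absent from site table: {sorted(missing)}"
            )
    return st


def read_patch_map(path, sites: SiteTable | None = None) -> PatchMap:
    """Read the landscape patch map CSV, checking all sampled sites appear."""
    pm = PatchMap(pd.read_csv(path))
    if sites is not None:
        missing = set(sites.site_ids) - set(pm.sampled_site_ids)
        if missing:
            raise ValidationError(
                f"sampled sites absent from patch map: {sorted(missing)}"
            )
    return pm


def pool_quadrats(records: QuadratRecords) -> PooledCommunityMatrix:
    """Sum quadrat biomass within each site into a site x species matrix.

    Species never observed anywhere are absent by construction; species
    observed at some sites get explicit zeros elsewhere. Total biomass is
    conserved: ``pooled.biomass.sum() == records.table.biomass.sum()``.
    """
    if len(records.table) == 0:
        raise ValidationError("empty community table")
    wide = records.table.pivot_table(
        index="wetland_id", columns="species_id", values="biomass",
        aggfunc="sum", fill_value=0.0,
    )
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    dead = wide.columns[(wide <= 0).all(axis=0)]
    if len(dead):
        logger.warning("dropping %d species with zero biomass everywhere", len(dead))
        wide = wide.drop(columns=dead)
    return PooledCommunityMatrix(
        site_ids=wide.index.tolist(),
        species_ids=wide.columns.tolist(),
        biomass=wide.to_numpy(dtype=float),
    )
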