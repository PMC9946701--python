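"""Region-year resource panels and their conversion to allocation vectors.

The central container is :class:`ResourcePanel`, a validated long-format panel
of resource densities (units per 1,000 population) by region, year and
indicator, joined with per-region attributes (population, land area, group
label).  :func:`build_allocation` turns one (indicator, year) slice into an
:class:`AllocationVector` — parallel weight/amount arrays — which is the unit
of measurement for all inequality statistics: weights are persons in the
population dimension and km² in the geographic dimension, while the absolute
resource amounts are identical in both.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "WESTERN_CHINA_GROUPS",
    "AllocationVector",
    "GroupPartition",
    "PanelValidationError",
    "RegionYearRecord",
    "ResourcePanel",
    "build_allocation",
    "extrema_report",
    "load_western_china",
    "published_contribution_ratios",
    "published_gini",
    "published_theil_components",
    "read_panel",
]

DIMENSIONS = ("population", "geographic")

#: Group membership of the twelve western-China provincial units: the five
#: ethnic-minority autonomous regions versus the seven other provinces and
#: municipalities.  Overridable through the attributes table for other panels.
WESTERN_CHINA_GROUPS: Mapping[str, str] = {
    "Guangxi": "minority",
    "Ningxia": "minority",
    "Tibet": "minority",
    "Xinjiang": "minority",
    "Inner Mongolia": "minority",
    "Shaanxi": "nonminority",
    "Sichuan": "nonminority",
    "Yunnan": "nonminority",
    "Guizhou": "nonminority",
    "Gansu": "nonminority",
    "Qinghai": "nonminority",
    "Chongqing": "nonminority",
}

DENSITY_COLUMNS = ["region_id", "year", "indicator", "density_per_1000"]
ATTRIBUTE_COLUMNS = ["region_id", "year", "population", "land_area_km2", "group"]


class PanelValidationError(ValueError):
    """Raised when a panel or allocation violates its invariants."""


@dataclass(frozen=True)
class RegionYearRecord:
    """One region's densities and attributes for one calendar year."""

    region_id: str
    year: int
    densities: Mapping[str, float]
    group: str | None = None
    population: float | None = None
    land_area: float | None = None


@dataclass(frozen=True)
class GroupPartition:
    """Assignment of regions to groups for subgroup decomposition."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise PanelValidationError("partition must assign at least one region")

    @property
    def k(self) -> int:
        return len(set(self.mapping.values()))

    def labels_for(self, region_ids: Sequence[str]) -> np.ndarray:
        missing = [r for r in region_ids if r not in self.mapping]
        if missing:
            raise PanelValidationError(f"regions without a group label: {missing}")
        return np.asarray([self.mapping[r] for r in region_ids], dtype=object)


@dataclass(frozen=True)
class AllocationVector:
    """Parallel (weight, amount) arrays for one indicator, year and dimension.

    ``weights`` are persons (population dimension) or km² (geographic
    dimension); ``amounts`` are absolute resource counts, identical across
    dimensions for the same slice.  Densities are amounts per weight unit;
    ``mu`` is the weighted mean density ``sum(amounts) / sum(weights)``.
    """

    region_ids: tuple[str, ...]
    weights: np.ndarray
    amounts: np.ndarray
    dimension: str = "population"
    indicator: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "amounts", np.asarray(self.amounts, dtype=float))
        n = len(self.region_ids)
        if self.weights.shape != (n,) or self.amounts.shape != (n,):
            raise PanelValidationError("region_ids, weights and amounts must have equal length")
        if n == 0:
            raise PanelValidationError("empty allocation")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise PanelValidationError("weights must be finite and strictly positive")
        if not np.all(np.isfinite(self.amounts)) or np.any(self.amounts < 0):
            raise PanelValidationError("amounts must be finite and non-negative")

    @property
    def n(self) -> int:
        return len(self.region_ids)

    @property
    def densities(self) -> np.ndarray:
        return self.amounts / self.weights

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def total_amount(self) -> float:
        return float(self.amounts.sum())

    @property
    def mu(self) -> float:
        """Weighted mean density per weight unit (persons or km²)."""
        return self.total_amount / self.total_weight

    def weight_shares(self) -> np.ndarray:
        return self.weights / self.weights.sum()

    def amount_shares(self) -> np.ndarray:
        total = self.amounts.sum()
        if total <= 0:
            raise PanelValidationError("allocation has zero total amount")
        return self.amounts / total


class ResourcePanel:
    """Validated panel of densities joined with region attributes.

    Parameters
    ----------
    densities
        Long-format frame with columns ``region_id, year, indicator,
        density_per_1000``.
    attributes
        Optional frame with columns ``region_id, year, population,
        land_area_km2, group``.  Without it the panel can be inspected
        (extrema, benchmarks) but not converted to allocation vectors.
    """

    def __init__(self, densities: pd.DataFrame, attributes: pd.DataFrame | None = None):
        self._densities = self._validate_densities(densities)
        self._attributes = self._validate_attributes(attributes) if attributes is not None else None
        if self._attributes is not None:
            self._check_attribute_coverage()

    # -- validation ------------------------------------------------------

    @staticmethod
    def _validate_densities(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(f"densities table missing columns {missing}")
        df = df.loc[:, DENSITY_COLUMNS].copy()
        df["region_id"] = df["region_id"].astype(str)
        df["year"] = df["year"].astype(int)
        df["indicator"] = df["indicator"].astype(str)
        df["density_per_1000"] = df["density_per_1000"].astype(float)
        bad = df[~np.isfinite(df["density_per_1000"]) | (df["density_per_1000"] < 0)]
        if not bad.empty:
            row = bad.iloc[0]
            raise PanelValidationError(
                f"negative or non-finite density for ({row.region_id!r}, {row.year}, "
                f"{row.indicator!r}): {row.density_per_1000}"
            )
        dups = df[df.duplicated(["region_id", "year", "indicator"], keep=False)]
        if not dups.empty:
            row = dups.iloc[0]
            raise PanelValidationError(
                f"duplicate density row for ({row.region_id!r}, {row.year}, {row.indicator!r})"
            )
        # fail fast on gaps: every (region, year) must carry every indicator
        counts = df.pivot_table(
            index=["region_id", "year"], columns="indicator", values="density_per_1000", aggfunc="size"
        )
        if counts.isna().any().any():
            region, year = counts[counts.isna().any(axis=1)].index[0]
            raise PanelValidationError(
                f"incomplete indicator coverage for ({region!r}, {year})"
            )
        return df.sort_values(["indicator", "year", "region_id"], ignore_index=True)

    @staticmethod
    def _validate_attributes(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in ATTRIBUTE_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(f"attributes table missing columns {missing}")
        df = df.loc[:, ATTRIBUTE_COLUMNS].copy()
        df["region_id"] = df["region_id"].astype(str)
        df["year"] = df["year"].astype(int)
        df["population"] = df["population"].astype(float)
        df["land_area_km2"] = df["land_area_km2"].astype(float)
        df["group"] = df["group"].astype(str)
        for col in ("population", "land_area_km2"):
            bad = df[~np.isfinite(df[col]) | (df[col] <= 0)]
            if not bad.empty:
                row = bad.iloc[0]
                raise PanelValidationError(
                    f"non-positive {col} for ({row.region_id!r}, {row.year}): {row[col]}"
                )
        dups = df[df.duplicated(["region_id", "year"], keep=False)]
        if not dups.empty:
            row = dups.iloc[0]
            raise PanelValidationError(
                f"duplicate attribute row for ({row.region_id!r}, {row.year})"
            )
        # a region's group label must not change across years
        ngroups = df.groupby("region_id")["group"].nunique()
        unstable = ngroups[ngroups > 1]
        if not unstable.empty:
            raise PanelValidationError(
                f"group label changes across years for region {unstable.index[0]!r}"
            )
        return df.sort_values(["year", "region_id"], ignore_index=True)

    def _check_attribute_coverage(self) -> None:
        need = set(map(tuple, self._densities[["region_id", "year"]].drop_duplicates().values))
        have = set(map(tuple, self._attributes[["region_id", "year"]].values))
        gaps = sorted(need - have)
        if gaps:
            region, year = gaps[0]
            raise PanelValidationError(f"attributes missing for ({region!r}, {year})")

    # -- introspection ---------------------------------------------------

    @property
    def densities(self) -> pd.DataFrame:
        return self._densities.copy()

    @property
    def attributes(self) -> pd.DataFrame | None:
        return None if self._attributes is None else self._attributes.copy()

    @property
    def has_attributes(self) -> bool:
        return self._attributes is not None

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(sorted(self._densities["indicator"].unique()))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self._densities["year"].unique()))

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._densities["region_id"].unique()))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def with_attributes(self, attributes: pd.DataFrame) -> "ResourcePanel":
        """Return a new panel joining this panel's densities with ``attributes``."""
        return ResourcePanel(self._densities, attributes)

    def partition(self) -> GroupPartition:
        """Group partition from the attribute table's ``group`` column."""
        if self._attributes is None:
            raise PanelValidationError("panel has no attributes; group labels unknown")
        mapping = dict(
            self._attributes.drop_duplicates("region_id")[["region_id", "group"]].values
        )
        return GroupPartition(mapping)

    def records(self) -> list[RegionYearRecord]:
        out = []
        attr = {} if self._attributes is None else {
            (r.region_id, r.year): r for r in self._attributes.itertuples()
        }
        wide = self._densities.pivot_table(
            index=["region_id", "year"], columns="indicator", values="density_per_1000"
        )
        for (region, year), row in wide.iterrows():
            a = attr.get((region, year))
            out.append(
                RegionYearRecord(
                    region_id=region,
                    year=int(year),
                    densities=dict(row),
                    group=getattr(a, "group", None),
                    population=getattr(a, "population", None),
                    land_area=getattr(a, "land_area_km2", None),
                )
            )
        return out

    def density(self, region_id: str, year: int, indicator: str) -> float:
        df = self._densities
        sel = df[
            (df["region_id"] == region_id) & (df["year"] == year) & (df["indicator"] == indicator)
        ]
        if sel.empty:
            raise KeyError((region_id, year, indicator))
        return float(sel["density_per_1000"].iloc[0])

    # -- I/O -------------------------------------------------------------

    def to_csv(self, densities_path: str | Path, attributes_path: str | Path | None = None) -> None:
        self._densities.to_csv(densities_path, index=False)
        if attributes_path is not None:
            if self._attributes is None:
                raise PanelValidationError("panel has no attributes to write")
            self._attributes.to_csv(attributes_path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResourcePanel):
            return NotImplemented
        if not self._densities.equals(other._densities):
            return False
        if (self._attributes is None) != (other._attributes is None):
            return False
        return self._attributes is None or self._attributes.equals(other._attributes)

    def __repr__(self) -> str:
        return (
            f"ResourcePanel({self.n_regions} regions × {len(self.years)} years × "
            f"{len(self.indicators)} indicators, attributes={self.has_attributes})"
        )


def read_panel(
    densities_path: str | Path, attributes_path: str | Path | None = None
) -> ResourcePanel:
    """Read a panel from the two standard CSVs (attributes optional)."""
    densities = pd.read_csv(densities_path)
    attributes = pd.read_csv(attributes_path) if attributes_path is not None else None
    return ResourcePanel(densities, attributes)


def _data_path(name: str):
    return resources.files("equipanel.data").joinpath(name)


def load_western_china(attributes_path: str | Path | None = None) -> ResourcePanel:
    """The packaged 12-province western-China density panel, 2014–2018.

    Densities (beds, physicians, nurses per 1,000 population) are shipped
    exactly as published at two decimal places.  Provincial populations and
    land areas are **not** part of the published record and are left unset;
    pass a statistical-yearbook attributes CSV to enable the weighted
    analyses.  Group labels (minority autonomous regions vs the rest) follow
    :data:`WESTERN_CHINA_GROUPS` when no attributes file is given.
    """
    with resources.as_file(_data_path("western_china_densities.csv")) as p:
        densities = pd.read_csv(p)
    attributes = pd.read_csv(attributes_path) if attributes_path is not None else None
    return ResourcePanel(densities, attributes)


def _load_reference(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def published_gini() -> pd.DataFrame:
    """Published western-China Gini coefficients by dimension, year, indicator."""
    return _load_reference("western_china_gini_published.csv")


def published_theil_components() -> pd.DataFrame:
    """Published western-China Theil totals and components (standard naming).

    Columns ``theil_within`` / ``theil_between`` hold the within-group and
    between-group components of the standard decomposition; the original
    report labels them with the opposite convention.  The geographic nurses
    rows are internally inconsistent in the published record (components do
    not sum to the printed total) and should not be used for additivity
    checks.
    """
    return _load_reference("western_china_theil_published.csv")


def published_contribution_ratios() -> pd.DataFrame:
    """Published contribution ratios (percent of total Theil, standard naming)."""
    return _load_reference("western_china_contribution_published.csv")


def build_allocation(
    panel: ResourcePanel,
    indicator: str,
    year: int,
    dimension: str = "population",
) -> AllocationVector:
    """Convert one (indicator, year) panel slice into an allocation vector.

    Amounts are ``density × population / 1000`` (kept fractional); weights are
    persons or km² according to ``dimension``.  Total amounts are therefore
    identical across dimensions for the same slice.
    """
    if dimension not in DIMENSIONS:
        raise PanelValidationError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    if not panel.has_attributes:
        raise PanelValidationError(
            "panel has no attributes; populations are required to build allocations"
        )
    dens = panel.densities
    sel = dens[(dens["indicator"] == indicator) & (dens["year"] == year)]
    if sel.empty:
        raise PanelValidationError(f"no densities for ({indicator!r}, {year})")
    attr = panel.attributes
    attr = attr[attr["year"] == year]
    merged = sel.merge(attr, on=["region_id", "year"], validate="one_to_one")
    merged = merged.sort_values("region_id", ignore_index=True)
    amounts = merged["density_per_1000"].to_numpy() * merged["population"].to_numpy() / 1000.0
    weights = (
        merged["population"].to_numpy()
        if dimension == "population"
        else merged["land_area_km2"].to_numpy()
    )
    return AllocationVector(
        region_ids=tuple(merged["region_id"]),
        weights=weights,
        amounts=amounts,
        dimension=dimension,
        indicator=indicator,
        year=year,
    )


@dataclass(frozen=True)
class RankedDensities:
    """Regions ranked by density, descending (ties broken by region id)."""

    indicator: str
    year: int
    table: pd.DataFrame = field(repr=False)

    @property
    def max(self) -> tuple[str, float]:
        row = self.table.iloc[0]
        return str(row["region_id"]), float(row["density_per_1000"])

    @property
    def min(self) -> tuple[str, float]:
        row = self.table.iloc[-1]
        return str(row["region_id"]), float(row["density_per_1000"])


def extrema_report(panel: ResourcePanel, indicator: str, year: int) -> RankedDensities:
    """Rank regions by density for one (indicator, year)."""
    dens = panel.densities
    sel = dens[(dens["indicator"] == indicator) & (dens["year"] == year)]
    if sel.empty:
        raise PanelValidationError(f"no densities for ({indicator!r}, {year})")
    table = sel.sort_values(
        ["density_per_1000", "region_id"], ascending=[False, True], ignore_index=True
    )[["region_id", "density_per_1000"]]
    return RankedDensities(indicator=indicator, year=year, table=table)
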