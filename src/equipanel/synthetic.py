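"""Synthetic region-year panels with controllable inequality structure.

The generator emulates the shape of a western-China-style study panel: a
dozen regions split into two groups, several calendar years, positive
populations and land areas at provincial scales, and per-capita resource
densities whose dispersion (hence Gini/Theil level) is a dial.  It exists so
every pipeline stage is testable without the statistical-yearbook attribute
data that published density tables omit.

Two exact constructions complement the stochastic models:

* :func:`two_point_allocation` — a two-region allocation whose Gini equals
  its first weight share exactly (all resources in the second region), the
  closed-form oracle used by the test-suite;
* :func:`calibrate_dispersion` — bisection on the lognormal density scale σ
  so that the *mean sample* Gini at a given panel size matches a target.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import (
    WESTERN_CHINA_GROUPS,
    AllocationVector,
    PanelValidationError,
    ResourcePanel,
)

__all__ = [
    "ScenarioSpec",
    "calibrate_dispersion",
    "generate_panel",
    "mean_sample_gini",
    "synthetic_attributes",
    "two_point_allocation",
    "western_synthetic_attributes",
]

#: Default per-1,000-population density scales, one per indicator — the
#: order of magnitude of bed/physician/nurse densities in western China
#: at the end of the study window.
DEFAULT_BASE_DENSITIES: Mapping[str, float] = {
    "beds": 6.0,
    "physicians": 2.4,
    "nurses": 2.8,
}

#: Provincial-scale weight defaults: mean resident population (persons) and
#: mean land area (km²) per region, matching western-China magnitudes
#: (~380 M persons and ~6.8 M km² over 12 units).
DEFAULT_MEAN_POPULATION = 3.2e7
DEFAULT_MEAN_AREA = 5.6e5

#: Log-scale dispersions of population and land area across regions.  The
#: real provinces span ~3.4 M–83 M persons and ~6.6e4–1.2e6 km²; lognormal
#: spreads of 0.8 and 1.3 reproduce those ranges.
DEFAULT_POPULATION_SIGMA = 0.8
DEFAULT_AREA_SIGMA = 1.3

#: Default per-capita density dispersion: σ ≈ 0.1 gives equal-weight Ginis
#: around 0.05, the level seen in population-dimension analyses.
DEFAULT_DENSITY_SIGMA = 0.1


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic panel.

    ``drift`` multiplies the density dispersion each successive year, so
    values above 1 make inequality worsen over time and below 1 improve.
    ``group_density_ratio`` scales the first (minority) group's densities,
    injecting a between-group component when ≠ 1.
    """

    n_regions: int = 12
    group_sizes: tuple[int, int] = (5, 7)
    years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)
    weight_model: str = "lognormal"  # or "equal"
    population_sigma: float = DEFAULT_POPULATION_SIGMA
    area_sigma: float = DEFAULT_AREA_SIGMA
    density_model: str = "lognormal"  # or "two_point", "dirichlet"
    density_sigma: float = DEFAULT_DENSITY_SIGMA
    two_point_p: float = 0.5
    two_point_low: float = 1.0
    two_point_high: float = 4.0
    dirichlet_alpha: float = 50.0
    drift: float = 1.0
    group_density_ratio: float = 1.0
    base_densities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_DENSITIES)
    )
    mean_population: float = DEFAULT_MEAN_POPULATION
    mean_area: float = DEFAULT_MEAN_AREA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise PanelValidationError("need at least 2 regions")
        if sum(self.group_sizes) != self.n_regions:
            raise PanelValidationError("group sizes must sum to n_regions")
        if min(self.group_sizes) < 0:
            raise PanelValidationError("group sizes must be non-negative")
        for name in ("population_sigma", "area_sigma", "density_sigma"):
            if getattr(self, name) < 0:
                raise PanelValidationError(f"{name} must be ≥ 0")
        if self.weight_model not in ("equal", "lognormal"):
            raise PanelValidationError(f"unknown weight model {self.weight_model!r}")
        if self.density_model not in ("lognormal", "two_point", "dirichlet"):
            raise PanelValidationError(f"unknown density model {self.density_model!r}")
        if self.density_model == "two_point" and not (
            0 < self.two_point_low <= self.two_point_high
        ):
            raise PanelValidationError("two-point levels must satisfy 0 < low ≤ high")
        if not self.years:
            raise PanelValidationError("need at least one year")

    @classmethod
    def population_vs_area_contrast(cls, seed: int = 0) -> "ScenarioSpec":
        """Near-uniform per-capita densities over strongly heterogeneous areas.

        This is the qualitative signature of the western-China panels: low
        population-dimension inequality coexisting with geographic-dimension
        Ginis above the 0.6 danger band, driven purely by how unevenly people
        (and hence resources) sit on the land.
        """
        return cls(density_sigma=0.05, population_sigma=0.8, area_sigma=1.5, seed=seed)


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, size) -> np.ndarray:
    # mean-preserving parameterization: E[x] = mean for every sigma
    return mean * np.exp(rng.standard_normal(size) * sigma - sigma**2 / 2.0)


def generate_panel(spec: ScenarioSpec) -> ResourcePanel:
    """Generate a reproducible synthetic :class:`ResourcePanel` from a spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    region_ids = [f"R{i + 1:02d}" for i in range(n)]
    groups = ["minority"] * spec.group_sizes[0] + ["nonminority"] * spec.group_sizes[1]

    if spec.weight_model == "equal":
        populations = np.full(n, spec.mean_population)
        areas = np.full(n, spec.mean_area)
    else:
        populations = _lognormal(rng, spec.mean_population, spec.population_sigma, n)
        areas = _lognormal(rng, spec.mean_area, spec.area_sigma, n)

    group_factor = np.where(
        np.asarray(groups, dtype=object) == "minority", spec.group_density_ratio, 1.0
    )

    dens_rows = []
    attr_rows = []
    for ti, year in enumerate(spec.years):
        for region, pop, area, g in zip(region_ids, populations, areas, groups):
            attr_rows.append(
                {
                    "region_id": region,
                    "year": int(year),
                    "population": pop,
                    "land_area_km2": area,
                    "group": g,
                }
            )
        for indicator, base in spec.base_densities.items():
            sigma_t = spec.density_sigma * spec.drift**ti
            if spec.density_model == "lognormal":
                dens = _lognormal(rng, base, sigma_t, n)
            elif spec.density_model == "two_point":
                hi = rng.random(n) < spec.two_point_p
                dens = np.where(hi, spec.two_point_high, spec.two_point_low).astype(float)
            else:  # dirichlet resource shares over regions
                shares = rng.dirichlet(np.full(n, spec.dirichlet_alpha))
                total_amount = base * populations.sum() / 1000.0
                dens = 1000.0 * shares * total_amount / populations
            dens = dens * group_factor
            for region, d in zip(region_ids, dens):
                dens_rows.append(
                    {
                        "region_id": region,
                        "year": int(year),
                        "indicator": indicator,
                        "density_per_1000": float(d),
                    }
                )
    return ResourcePanel(pd.DataFrame(dens_rows), pd.DataFrame(attr_rows))


def synthetic_attributes(
    region_ids: Sequence[str],
    years: Sequence[int],
    seed: int = 0,
    groups: Mapping[str, str] | None = None,
    mean_population: float = DEFAULT_MEAN_POPULATION,
    population_sigma: float = DEFAULT_POPULATION_SIGMA,
    mean_area: float = DEFAULT_MEAN_AREA,
    area_sigma: float = DEFAULT_AREA_SIGMA,
) -> pd.DataFrame:
    """Synthetic attribute table (population, area, group) for given regions.

    Stands in for yearbook population/area figures when only densities are
    available; values are drawn once per region and held constant over years.
    """
    rng = np.random.default_rng(seed)
    n = len(region_ids)
    populations = _lognormal(rng, mean_population, population_sigma, n)
    areas = _lognormal(rng, mean_area, area_sigma, n)
    rows = []
    for year in years:
        for i, region in enumerate(region_ids):
            g = groups.get(region) if groups else None
            if g is None:
                g = "minority" if i % 2 == 0 else "nonminority"
            rows.append(
                {
                    "region_id": region,
                    "year": int(year),
                    "population": populations[i],
                    "land_area_km2": areas[i],
                    "group": g,
                }
            )
    return pd.DataFrame(rows)


def western_synthetic_attributes(
    years: Sequence[int] = (2014, 2015, 2016, 2017, 2018), seed: int = 0
) -> pd.DataFrame:
    """Synthetic stand-in attributes for the 12 western-China regions.

    Populations and land areas are *not* the yearbook values (those are not
    part of the packaged record); they are drawn at provincial scales so the
    packaged density panel can exercise the full weighted pipeline.  Group
    labels are the real minority / nonminority assignment.
    """
    return synthetic_attributes(
        sorted(WESTERN_CHINA_GROUPS),
        years,
        seed=seed,
        groups=WESTERN_CHINA_GROUPS,
    )


def two_point_allocation(w: float) -> AllocationVector:
    """Two regions with weight shares (w, 1−w) and all resources in region 2.

    The Lorenz curve has vertices (0,0), (w,0), (1,1), so G = w exactly —
    the closed-form anchor for the numerical Gini routes.
    """
    if not 0 < w < 1:
        raise PanelValidationError("weight share w must lie in (0, 1)")
    return AllocationVector(
        region_ids=("have_not", "have"),
        weights=np.array([w, 1.0 - w]),
        amounts=np.array([0.0, 1.0]),
        dimension="population",
    )


def _equal_weight_gini_rows(y: np.ndarray) -> np.ndarray:
    """Per-row equal-weight Gini of a (replicates, n) positive array."""
    n = y.shape[1]
    ys = np.sort(y, axis=1)
    ranks = 2.0 * np.arange(1, n + 1) - n - 1.0
    return (ys * ranks).sum(axis=1) / (n * ys.sum(axis=1))


def mean_sample_gini(
    sigma: float, n: int, replicates: int, seed: int, base: float = 1.0
) -> float:
    """Mean equal-weight sample Gini of n lognormal(σ) densities, Monte Carlo."""
    rng = np.random.default_rng(seed)
    y = base * np.exp(sigma * rng.standard_normal((replicates, n)))
    return float(_equal_weight_gini_rows(y).mean())


def calibrate_dispersion(
    target_G: float,
    density_model: str = "lognormal",
    n: int = 12,
    seed: int = 0,
    replicates: int = 500,
    tol: float = 0.01,
    max_sigma: float = 8.0,
) -> float:
    """Dispersion σ whose mean sample Gini at panel size n hits ``target_G``.

    Solves for the *expected sample* Gini (estimated over ``replicates``
    panels with common random numbers, so the bisection objective is
    deterministic and monotone), not for per-draw exactness — the two-point
    construction provides the exact path.  Raises if the target is
    unattainable for the model.
    """
    if not 0 <= target_G < 0.9:
        raise PanelValidationError("target Gini must lie in [0, 0.9)")
    if density_model != "lognormal":
        raise PanelValidationError(
            f"calibration implemented for the lognormal model only, got {density_model!r}"
        )
    if target_G == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((replicates, n))

    def mean_g(sigma: float) -> float:
        return float(_equal_weight_gini_rows(np.exp(sigma * z)).mean())

    lo, hi = 0.0, max_sigma
    if mean_g(hi) < target_G:
        raise PanelValidationError(
            f"target Gini {target_G} unattainable at n={n} for the lognormal model"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_g(mid) < target_G:
            lo = mid
        else:
            hi = mid
    sigma = 0.5 * (lo + hi)
    if abs(mean_g(sigma) - target_G) > tol:
        raise PanelValidationError("bisection failed to reach the target within tolerance")
    return sigma
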