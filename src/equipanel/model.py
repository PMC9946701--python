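"""Panel-level equity model: the Gini/Theil grid, trends, benchmarks, export.

:class:`EquityModel` is constructed from a :class:`~equipanel.panel.ResourcePanel`
(densities joined with population/area/group attributes) and a requested grid
of years × indicators × weighting dimensions; :meth:`EquityModel.fit` computes
every cell — Lorenz curve, Gini coefficient with its equity grade, Theil-L
decomposition with contribution ratios — and returns an :class:`EquityResults`
carrying the tables, a text ``summary()`` and deterministic CSV export.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .inequality import GiniResult, LorenzCurve, gini, lorenz_curve
from .panel import (
    DIMENSIONS,
    GroupPartition,
    PanelValidationError,
    ResourcePanel,
    build_allocation,
    read_panel,
)
from .theil import TheilDecomposition, theil_decompose

__all__ = [
    "BenchmarkResult",
    "BenchmarkSpec",
    "EquityModel",
    "EquityResults",
    "benchmark_check",
    "run_grid",
]

#: National 2020 planning densities per 1,000 population used as pass/fail
#: benchmarks for the study window.
DEFAULT_BENCHMARKS: Mapping[str, float] = {"beds": 6.0, "physicians": 2.5, "nurses": 3.14}


@dataclass(frozen=True)
class BenchmarkSpec:
    """Per-indicator target densities (per 1,000 population)."""

    targets: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BENCHMARKS))

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.targets.values()):
            raise PanelValidationError("benchmark targets must be non-negative")


@dataclass(frozen=True)
class BenchmarkResult:
    """Pass/fail of each region against per-indicator density targets."""

    year: int
    table: pd.DataFrame  # region_id, indicator, density, target, passed

    def passing(self, indicator: str) -> tuple[str, ...]:
        t = self.table
        sel = t[(t["indicator"] == indicator) & t["passed"]]
        return tuple(sorted(sel["region_id"]))

    def counts(self) -> dict[str, int]:
        return {
            ind: int(grp["passed"].sum())
            for ind, grp in self.table.groupby("indicator", sort=True)
        }


def benchmark_check(
    panel: ResourcePanel, year: int, spec: BenchmarkSpec | None = None
) -> BenchmarkResult:
    """Check every region's densities against the planning targets (strict ≥)."""
    spec = spec or BenchmarkSpec()
    dens = panel.densities
    sel = dens[dens["year"] == year]
    if sel.empty:
        raise PanelValidationError(f"no densities for year {year}")
    rows = []
    for indicator, target in spec.targets.items():
        sub = sel[sel["indicator"] == indicator]
        for r in sub.itertuples():
            rows.append(
                {
                    "region_id": r.region_id,
                    "indicator": indicator,
                    "density": r.density_per_1000,
                    "target": target,
                    "passed": bool(r.density_per_1000 >= target),
                }
            )
    table = pd.DataFrame(rows).sort_values(["indicator", "region_id"], ignore_index=True)
    return BenchmarkResult(year=year, table=table)


def _trend_direction(values: np.ndarray) -> tuple[str, str]:
    steps = np.diff(values)
    signs = "".join("+" if s > 0 else "-" if s < 0 else "0" for s in steps)
    if np.all(steps == 0):
        return signs, "flat"
    if np.all(steps >= 0):
        return signs, "up"
    if np.all(steps <= 0):
        return signs, "down"
    return signs, "mixed"


class EquityModel:
    """Equity analysis of a resource panel over years × indicators × dimensions.

    Parameters
    ----------
    panel
        Panel with attributes (populations always; land areas if the
        geographic dimension is requested).
    indicators, years, dimensions
        Grid axes; default to everything the panel carries and both
        weighting dimensions.
    partition
        Group partition for the Theil decomposition.  Defaults to the
        panel's ``group`` labels, which must then form exactly two
        non-empty groups (the two-group study design); an explicit
        partition of any k ≥ 1 is accepted.
    benchmarks
        Target densities for :meth:`EquityResults.benchmark`.
    """

    def __init__(
        self,
        panel: ResourcePanel,
        indicators: Sequence[str] | None = None,
        years: Sequence[int] | None = None,
        dimensions: Sequence[str] = DIMENSIONS,
        partition: GroupPartition | None = None,
        benchmarks: BenchmarkSpec | None = None,
    ):
        if not panel.has_attributes:
            raise PanelValidationError(
                "EquityModel needs a panel with attributes (population, area, group)"
            )
        unknown = set(dimensions) - set(DIMENSIONS)
        if unknown:
            raise PanelValidationError(f"unknown dimensions {sorted(unknown)}")
        self.panel = panel
        self.indicators = tuple(indicators) if indicators is not None else panel.indicators
        self.years = tuple(years) if years is not None else panel.years
        self.dimensions = tuple(dimensions)
        if partition is None:
            partition = panel.partition()
            if partition.k != 2:
                raise PanelValidationError(
                    f"two-group decomposition requested but panel has {partition.k} group(s)"
                )
        self.partition = partition
        self.benchmarks = benchmarks or BenchmarkSpec()
        missing_y = set(self.years) - set(panel.years)
        missing_i = set(self.indicators) - set(panel.indicators)
        if missing_y or missing_i:
            raise PanelValidationError(
                f"panel lacks requested years {sorted(missing_y)} / indicators {sorted(missing_i)}"
            )

    @classmethod
    def from_csv(
        cls, densities_path, attributes_path, **kwargs
    ) -> "EquityModel":
        return cls(read_panel(densities_path, attributes_path), **kwargs)

    def fit(self) -> "EquityResults":
        """Compute every grid cell; deterministic given the inputs."""
        gini_cells: dict[tuple, GiniResult] = {}
        theil_cells: dict[tuple, TheilDecomposition] = {}
        lorenz_cells: dict[tuple, LorenzCurve] = {}
        for dimension in self.dimensions:
            for indicator in self.indicators:
                for year in self.years:
                    key = (dimension, indicator, year)
                    try:
                        alloc = build_allocation(self.panel, indicator, year, dimension)
                        gini_cells[key] = gini(alloc)
                        lorenz_cells[key] = lorenz_curve(alloc)
                        theil_cells[key] = theil_decompose(alloc, self.partition)
                    except PanelValidationError as exc:
                        raise PanelValidationError(
                            f"cell (year={year}, indicator={indicator!r}, "
                            f"dimension={dimension!r}): {exc}"
                        ) from exc
        return EquityResults(self, gini_cells, theil_cells, lorenz_cells)


class EquityResults:
    """Fitted equity grid with tables, trends, benchmarks and export."""

    def __init__(self, model, gini_cells, theil_cells, lorenz_cells):
        self.model = model
        self._gini = gini_cells
        self._theil = theil_cells
        self._lorenz = lorenz_cells
        self.gini_table = pd.DataFrame(
            {
                "dimension": d,
                "indicator": i,
                "year": y,
                "gini": res.value,
                "grade": res.grade.value,
            }
            for (d, i, y), res in sorted(gini_cells.items())
        ).reset_index(drop=True)
        rows = []
        for (d, i, y), dec in sorted(theil_cells.items()):
            r = dec.ratios
            rows.append(
                {
                    "dimension": d,
                    "indicator": i,
                    "year": y,
                    "theil_total": dec.total,
                    "theil_between": dec.between,
                    "theil_within": dec.within,
                    "between_pct": np.nan if r.perfect_equality else r.between_pct,
                    "within_pct": np.nan if r.perfect_equality else r.within_pct,
                    "perfect_equality": r.perfect_equality,
                }
            )
        self.theil_table = pd.DataFrame(rows)

    # -- cell access -----------------------------------------------------

    def gini(self, indicator: str, year: int, dimension: str = "population") -> GiniResult:
        return self._gini[(dimension, indicator, year)]

    def theil(
        self, indicator: str, year: int, dimension: str = "population"
    ) -> TheilDecomposition:
        return self._theil[(dimension, indicator, year)]

    def lorenz(
        self, indicator: str, year: int, dimension: str = "population"
    ) -> LorenzCurve:
        return self._lorenz[(dimension, indicator, year)]

    # -- derived tables --------------------------------------------------

    def trend(self) -> pd.DataFrame:
        """First-vs-last-year Gini change and per-step direction per series."""
        if len(self.model.years) < 2:
            raise PanelValidationError("trend summary needs at least two years")
        rows = []
        years = sorted(self.model.years)
        for dimension in self.model.dimensions:
            for indicator in self.model.indicators:
                values = np.array(
                    [self._gini[(dimension, indicator, y)].value for y in years]
                )
                signs, direction = _trend_direction(values)
                rows.append(
                    {
                        "dimension": dimension,
                        "indicator": indicator,
                        "first_year": years[0],
                        "last_year": years[-1],
                        "first": values[0],
                        "last": values[-1],
                        "delta": values[-1] - values[0],
                        "step_signs": signs,
                        "direction": direction,
                    }
                )
        return pd.DataFrame(rows)

    def benchmark(self, year: int | None = None, spec: BenchmarkSpec | None = None) -> BenchmarkResult:
        year = year if year is not None else max(self.model.years)
        return benchmark_check(self.model.panel, year, spec or self.model.benchmarks)

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of the fitted grid."""
        lines = []
        p = self.model.panel
        lines.append("Health-resource allocation equity analysis")
        lines.append("=" * 60)
        lines.append(
            f"Panel: {p.n_regions} regions × {len(self.model.years)} years × "
            f"{len(self.model.indicators)} indicators; "
            f"dimensions: {', '.join(self.model.dimensions)}"
        )
        lines.append("")
        gpivot = self.gini_table.pivot_table(
            index=["dimension", "year"], columns="indicator", values="gini"
        )
        lines.append("Gini coefficients")
        lines.append(gpivot.round(4).to_string())
        lines.append("")
        tpivot = self.theil_table.pivot_table(
            index=["dimension", "year"], columns="indicator", values="theil_total"
        )
        lines.append("Theil-L index (total)")
        lines.append(tpivot.round(3).to_string())
        lines.append("")
        wpivot = self.theil_table.pivot_table(
            index=["dimension", "year"], columns="indicator", values="within_pct"
        )
        lines.append("Within-group contribution to Theil-L (percent)")
        lines.append(wpivot.round(2).to_string())
        lines.append("")
        lines.append("Gini trends (first → last year)")
        trend = self.trend()
        lines.append(
            trend[["dimension", "indicator", "first", "last", "delta", "direction"]]
            .round(4)
            .to_string(index=False)
        )
        return "\n".join(lines)

    # -- export ----------------------------------------------------------

    def export(self, out_dir: str | Path, published_precision: bool = False) -> list[Path]:
        """Write the report CSVs; byte-identical across re-runs on equal input.

        ``published_precision`` rounds Ginis to 4 decimals, Theil components
        to 3 and percentages to 2, matching the typical reporting precision
        of published equity tables.
        """
        if self.gini_table.empty or self.theil_table.empty:
            raise PanelValidationError("nothing to export: empty results grid")
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        gini_df = self.gini_table.copy()
        theil_df = self.theil_table.drop(columns="perfect_equality").copy()
        ratio_df = self.theil_table[
            ["dimension", "indicator", "year", "between_pct", "within_pct"]
        ].copy()
        # both label conventions: standard (between = inter) and the swapped
        # convention used by the western-China report's tables
        ratio_df["swapped_label_T_intra_pct"] = ratio_df["between_pct"]
        ratio_df["swapped_label_T_inter_pct"] = ratio_df["within_pct"]
        if published_precision:
            gini_df["gini"] = gini_df["gini"].round(4)
            for c in ("theil_total", "theil_between", "theil_within"):
                theil_df[c] = theil_df[c].round(3)
            for c in ratio_df.columns[3:]:
                ratio_df[c] = ratio_df[c].round(2)

        def write(name: str, df: pd.DataFrame) -> None:
            path = out / name
            df.to_csv(path, index=False, lineterminator="\n")
            written.append(path)

        write("gini_coefficients.csv", gini_df)
        write("theil_decomposition.csv", theil_df)
        write("contribution_ratios.csv", ratio_df)

        for dimension in self.model.dimensions:
            rows = []
            for indicator in self.model.indicators:
                for year in self.model.years:
                    curve = self._lorenz[(dimension, indicator, year)]
                    regions = ("",) + curve.region_order
                    for k, (x, y) in enumerate(zip(curve.x, curve.y)):
                        rows.append(
                            {
                                "indicator": indicator,
                                "year": year,
                                "vertex": k,
                                "region_id": regions[k],
                                "cum_weight_share": x,
                                "cum_amount_share": y,
                            }
                        )
            write(f"lorenz_{dimension}.csv", pd.DataFrame(rows))

        trend = self.trend()
        for dimension in self.model.dimensions:
            write(
                f"trend_{dimension}.csv",
                trend[trend["dimension"] == dimension].reset_index(drop=True),
            )

        log = out / "run_log.txt"
        cfg = [
            f"equipanel {_version}",
            f"regions: {', '.join(self.model.panel.region_ids)}",
            f"years: {', '.join(map(str, self.model.years))}",
            f"indicators: {', '.join(self.model.indicators)}",
            f"dimensions: {', '.join(self.model.dimensions)}",
            f"groups: {self.model.partition.k}",
            f"published_precision: {published_precision}",
            f"files: {', '.join(p.name for p in written)}",
        ]
        log.write_text("\n".join(cfg) + "\n")
        written.append(log)
        return written


def run_grid(
    panel: ResourcePanel,
    dimensions: Sequence[str] = DIMENSIONS,
    indicators: Sequence[str] | None = None,
    years: Sequence[int] | None = None,
    partition: GroupPartition | None = None,
) -> EquityResults:
    """Convenience wrapper: fit the full equity grid in one call."""
    return EquityModel(
        panel,
        indicators=indicators,
        years=years,
        dimensions=dimensions,
        partition=partition,
    ).fit()
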