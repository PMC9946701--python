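"""Theil-L index (mean log deviation) and its subgroup decomposition.

For an allocation with weight shares Pᵢ and resource shares Yᵢ,

    T = Σᵢ Pᵢ ln(Pᵢ / Yᵢ)          (natural log)

is zero under perfect equality and additively decomposable: with groups j
holding weight shares Pⱼ and resource shares Yⱼ,

    T_between = Σⱼ Pⱼ ln(Pⱼ / Yⱼ)
    T_within  = Σⱼ Pⱼ Tⱼ            (Tⱼ on within-group renormalized shares)
    T         = T_between + T_within.

The log base rescales T and both components identically, so the contribution
ratios (each component as a percentage of T) are base-invariant — which makes
them the most robust quantity to compare across published analyses.

A naming caveat: the western-China reference study labels its tables with
"inter"/"intra" swapped relative to this standard usage (its text calls the
within-province comparison "intergroup").  :meth:`ContributionRatios.labelled`
can render either convention; all field names here are standard.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import AllocationVector, GroupPartition, PanelValidationError

__all__ = [
    "ContributionRatios",
    "TheilDecomposition",
    "contribution_ratios",
    "ratios_from_components",
    "theil_decompose",
    "theil_total",
]

_ADDITIVITY_TOL = 1e-9  # internal sanity bound; observed error is ~1e-16


def _theil_from_shares(P: np.ndarray, Y: np.ndarray) -> float:
    if np.any((P > 0) & (Y == 0)):
        raise PanelValidationError(
            "Theil-L undefined: a unit with positive weight holds zero resources"
        )
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / Y[mask])))


def theil_total(alloc: AllocationVector) -> float:
    """Total Theil-L index of an allocation."""
    P = alloc.weight_shares()
    Y = alloc.amount_shares()  # raises if total resources are zero
    return _theil_from_shares(P, Y)


@dataclass(frozen=True)
class ContributionRatios:
    """Each component's percentage of the total Theil index.

    ``perfect_equality`` marks the T = 0 case where ratios are undefined;
    the percentage fields are then ``None``.
    """

    between_pct: float | None
    within_pct: float | None
    perfect_equality: bool = False

    def labelled(self, convention: str = "standard") -> dict[str, float | None]:
        """Render under either label convention.

        ``"standard"`` maps between→``T_inter`` and within→``T_intra``;
        ``"swapped"`` reproduces the western-China report's table labels,
        where ``T_inter`` denotes the within-group (within-province) share.
        """
        if convention == "standard":
            return {"T_inter": self.between_pct, "T_intra": self.within_pct}
        if convention == "swapped":
            return {"T_inter": self.within_pct, "T_intra": self.between_pct}
        raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class TheilDecomposition:
    """Total Theil-L with its between- and within-group components."""

    total: float
    between: float
    within: float
    group_table: pd.DataFrame  # group, weight_share, resource_share, theil_within_group
    dimension: str = "population"
    indicator: str | None = None
    year: int | None = None

    @property
    def ratios(self) -> ContributionRatios:
        return contribution_ratios(self)


def theil_decompose(alloc: AllocationVector, partition: GroupPartition) -> TheilDecomposition:
    """Decompose the Theil-L index of an allocation over a group partition.

    Group components use group aggregate shares; each group's internal index
    Tⱼ is computed on shares renormalized within the group.  Additivity
    T = T_between + T_within is verified internally.
    """
    labels = partition.labels_for(alloc.region_ids)
    P = alloc.weight_shares()
    Y = alloc.amount_shares()
    total = _theil_from_shares(P, Y)

    groups = sorted(set(labels))
    rows = []
    between_terms = []
    within_terms = []
    for g in groups:
        mask = labels == g
        if not mask.any():
            raise PanelValidationError(f"empty group {g!r}")
        Pj = float(P[mask].sum())
        Yj = float(Y[mask].sum())
        if Pj > 0 and Yj == 0:
            raise PanelValidationError(
                f"group {g!r} has positive weight but zero resources"
            )
        between_terms.append(Pj * np.log(Pj / Yj) if Pj > 0 else 0.0)
        Tj = _theil_from_shares(P[mask] / Pj, Y[mask] / Yj) if Pj > 0 else 0.0
        within_terms.append(Pj * Tj)
        rows.append(
            {"group": g, "weight_share": Pj, "resource_share": Yj, "theil_within_group": Tj}
        )
    between = float(np.sum(between_terms))
    within = float(np.sum(within_terms))
    if abs(total - (between + within)) > _ADDITIVITY_TOL:
        raise AssertionError(
            f"Theil additivity violated: {total} != {between} + {within}"
        )
    return TheilDecomposition(
        total=total,
        between=between,
        within=within,
        group_table=pd.DataFrame(rows),
        dimension=alloc.dimension,
        indicator=alloc.indicator,
        year=alloc.year,
    )


def contribution_ratios(dec: TheilDecomposition) -> ContributionRatios:
    """Between/within shares of the total index, in percent.

    Accepts either a full :class:`TheilDecomposition` or anything exposing
    ``total``, ``between`` and ``within`` — published component triples can be
    re-expressed as ratios the same way.
    """
    if dec.total == 0:
        return ContributionRatios(between_pct=None, within_pct=None, perfect_equality=True)
    if dec.total < 0:
        raise PanelValidationError(f"negative Theil total {dec.total}")
    return ContributionRatios(
        between_pct=100.0 * dec.between / dec.total,
        within_pct=100.0 * dec.within / dec.total,
    )


def ratios_from_components(total: float, between: float, within: float) -> ContributionRatios:
    """Contribution ratios straight from (possibly published, rounded) components.

    Useful for re-expressing a reported component table as percentages; the
    ratios are invariant to the log base the components were computed in.
    """
    if total == 0:
        return ContributionRatios(between_pct=None, within_pct=None, perfect_equality=True)
    if total < 0 or between < 0 or within < 0:
        raise PanelValidationError("Theil components must be non-negative")
    return ContributionRatios(
        between_pct=100.0 * between / total, within_pct=100.0 * within / total
    )
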