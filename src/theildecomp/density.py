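"""Descriptive surfaces: density tables, extremal ratios, trend summaries.

Per-capita densities are amounts per 10,000 persons and per-area densities
amounts per 10,000 km² — the conventions of the Chinese yearbook tables
the packaged fixture transcribes (populations are stored in 10,000-person
units and areas in 10,000-km² units, so both densities are plain
quotients).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import RegionPartition, ResourcePanel, build_share_vector
from .errors import DegenerateInputError, TheildecompError, ValidationError
from .theil import decompose, theil_index


def per_capita_density(amount: float, population: float) -> float:
    """Resource amount per 10,000 persons (population given in 10,000s)."""
    if not population > 0:
        raise ValidationError(f"population must be positive, got {population!r}")
    if amount < 0:
        raise ValidationError(f"amount must be non-negative, got {amount!r}")
    return amount / population


def per_area_density(amount: float, area: float) -> float:
    """Resource amount per 10,000 km² (area given in 10,000-km² units)."""
    if not area > 0:
        raise ValidationError(f"area must be positive, got {area!r}")
    if amount < 0:
        raise ValidationError(f"amount must be non-negative, got {amount!r}")
    return amount / area


def percent_change(first: float, last: float) -> float:
    """Relative change 100·(last − first)/first, in percent."""
    if not first > 0:
        raise DegenerateInputError(
            f"percent change needs a positive baseline, got {first!r}"
        )
    return 100.0 * (last - first) / first


@dataclass(frozen=True)
class ExtremalRatio:
    """Max/min ratio of a positive density column, with the extremal units."""

    ratio: float
    max_unit: str | None = None
    min_unit: str | None = None

    def __float__(self) -> float:
        return self.ratio


def extremal_ratio(
    values: Sequence[float] | pd.Series, names: Iterable[str] | None = None
) -> ExtremalRatio:
    """Ratio of the largest to the smallest value in a positive list.

    When ``values`` is a pandas Series its index supplies the unit names;
    otherwise pass ``names`` explicitly to have the extremal units
    identified.
    """
    if isinstance(values, pd.Series) and names is None:
        names = values.index
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("extremal ratio of an empty list is undefined")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise DegenerateInputError(
            "extremal ratio requires strictly positive finite values"
        )
    i_max = int(arr.argmax())
    i_min = int(arr.argmin())
    labels = list(names) if names is not None else None
    return ExtremalRatio(
        ratio=float(arr[i_max] / arr[i_min]),
        max_unit=labels[i_max] if labels else None,
        min_unit=labels[i_min] if labels else None,
    )


def density_table(panel_slice: ResourcePanel) -> pd.DataFrame:
    """Tidy per-unit densities for one year slice.

    Columns: ``unit, indicator, per_capita, per_area``.
    """
    years = {r.year for r in panel_slice.records}
    if len(years) != 1:
        raise ValidationError(
            f"density tables are per-year; slice spans years {sorted(years)}"
        )
    rows = [
        {
            "unit": r.unit_name,
            "indicator": ind,
            "per_capita": per_capita_density(r.resources[ind], r.population),
            "per_area": per_area_density(r.resources[ind], r.area),
        }
        for r in panel_slice.records
        for ind in panel_slice.indicator_names
    ]
    return pd.DataFrame(rows)


@dataclass
class TrendResult:
    """Theil trend table plus any per-slice computation failures.

    ``table`` has one row per (year, indicator, scope); scope is
    ``"national"`` or a group name. ``errors`` maps a failing
    (year, indicator) pair to the error message; failing slices never
    abort the others.
    """

    table: pd.DataFrame
    errors: dict[tuple[int, str], str] = field(default_factory=dict)


_NATIONAL = "national"


def theil_trend(
    panel: ResourcePanel,
    partition: RegionPartition | None = None,
    indicators: Sequence[str] | None = None,
    *,
    totals: pd.DataFrame | None = None,
    epsilon_floor: bool = False,
) -> TrendResult:
    """Theil-L index by year and indicator, optionally decomposed by region.

    For every year × indicator slice one national row is emitted; with a
    partition, one row per group (its ``t_g`` and contribution) plus
    within/between columns on the national row. ``totals`` may supply
    published national denominators as a frame with a ``year`` column,
    a ``population_10k`` column and one column per indicator; years or
    indicators absent from it fall back to slice sums.

    Rows are sorted by year, then indicator, then scope (national first,
    then the partition's group order).
    """
    if indicators is None:
        indicators = panel.indicator_names
    unknown = set(indicators) - set(panel.indicator_names)
    if unknown:
        raise ValidationError(f"unknown indicator(s): {sorted(unknown)}")
    totals_by_year: dict[int, pd.Series] = {}
    if totals is not None:
        if "year" not in totals.columns:
            raise ValidationError("totals frame must carry a 'year' column")
        totals = totals.rename(columns={"investment_100m_yuan": "investment"})
        totals_by_year = {int(row["year"]): row for _, row in totals.iterrows()}

    rows: list[dict] = []
    errors: dict[tuple[int, str], str] = {}
    scopes = [_NATIONAL] + (list(partition.group_names) if partition else [])
    for year in panel.years:
        panel_slice = panel.year_slice(year)
        for ind in indicators:
            try:
                kwargs: dict[str, float] = {}
                t_row = totals_by_year.get(year)
                if t_row is not None:
                    if "population_10k" in t_row.index:
                        kwargs["population_total"] = float(t_row["population_10k"])
                    if ind in t_row.index:
                        kwargs["resource_total"] = float(t_row[ind])
                shares = build_share_vector(panel_slice, ind, **kwargs)
                if partition is None:
                    rows.append(
                        {
                            "year": year,
                            "indicator": ind,
                            "scope": _NATIONAL,
                            "theil": theil_index(shares, epsilon_floor=epsilon_floor),
                        }
                    )
                    continue
                dec = decompose(shares, partition, epsilon_floor=epsilon_floor)
                rows.append(
                    {
                        "year": year,
                        "indicator": ind,
                        "scope": _NATIONAL,
                        "theil": dec.total,
                        "within": dec.within,
                        "between": dec.between,
                        "contribution_within": _nan_if_none(dec.contribution_within),
                        "contribution_between": _nan_if_none(dec.contribution_between),
                    }
                )
                for g, term in dec.group_terms.items():
                    rows.append(
                        {
                            "year": year,
                            "indicator": ind,
                            "scope": g,
                            "theil": term.t_g,
                            "p_g": term.p_g,
                            "y_g": term.y_g,
                            "weighted_term": term.weighted_term,
                            "contribution": _nan_if_none(term.contribution),
                        }
                    )
            except TheildecompError as exc:
                errors[(year, ind)] = str(exc)
    if rows:
        table = pd.DataFrame(rows)
        table["scope"] = pd.Categorical(table["scope"], categories=scopes, ordered=True)
        table = table.sort_values(["year", "indicator", "scope"]).reset_index(drop=True)
        table["scope"] = table["scope"].astype(str)
    else:
        table = pd.DataFrame(columns=["year", "indicator", "scope", "theil"])
    return TrendResult(table=table, errors=errors)


def national_density_trend(
    totals: pd.DataFrame, *, prefer_published: bool = True
) -> pd.DataFrame:
    """Per-capita densities by year from a national totals table.

    ``totals`` needs a ``year`` and ``population_10k`` column plus one
    column per indicator. When a published per-capita companion column
    ``<indicator>_per_10k`` is present (the yearbook tables print one)
    and ``prefer_published`` is true, it is used for the density and the
    percent changes — published growth figures are arithmetic on those
    rounded columns, not on the raw counts. Otherwise densities are
    recomputed as amount / population.

    Output is tidy: ``year, indicator, per_capita, pct_change_from_first``.
    """
    totals = totals.rename(columns={"investment_100m_yuan": "investment"})
    needed = {"year", "population_10k"}
    if not needed <= set(totals.columns):
        raise ValidationError(f"totals frame must carry columns {sorted(needed)}")
    indicators = [
        c
        for c in totals.columns
        if c not in needed and not c.endswith("_per_10k")
    ]
    rows = []
    totals = totals.sort_values("year")
    for ind in indicators:
        published = f"{ind}_per_10k"
        if prefer_published and published in totals.columns:
            dens = totals[published].to_numpy(float)
        else:
            dens = (
                totals[ind].to_numpy(float)
                / totals["population_10k"].to_numpy(float)
            )
        for year, d in zip(totals["year"], dens):
            rows.append(
                {
                    "year": int(year),
                    "indicator": ind,
                    "per_capita": d,
                    "pct_change_from_first": percent_change(dens[0], d),
                }
            )
    return pd.DataFrame(rows)


def _nan_if_none(x: float | None) -> float:
    return np.nan if x is None else x
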