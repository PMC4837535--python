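"""Panel data structures: province records, panels, partitions, shares.

The unit conventions follow the Chinese health-statistics yearbooks the
analysis was designed around: populations are stored in units of 10,000
persons, land areas in units of 10,000 km², financial investment in
hundred-million yuan (亿元). Shares are dimensionless, so any consistent
unit choice gives identical inequality statistics.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DegenerateInputError,
    DuplicateAssignmentError,
    EmptyGroupError,
    ValidationError,
)

#: Canonical indicator order used by the packaged fixtures.
INDICATORS: tuple[str, ...] = ("institutions", "personnel", "beds", "investment")

#: Tolerance on share sums (|Σp − 1|) for normalized share vectors.
SHARE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ProvinceRecord:
    """One geographic unit's population, area and resource amounts for one year.

    Parameters
    ----------
    unit_name
        Non-empty identifier, unique within a year slice.
    year
        Calendar year.
    population
        Resident population in 10,000-person units; must be positive.
    area
        Land area in 10,000-km² units; must be positive.
    resources
        Mapping from indicator name to a non-negative amount.
    """

    unit_name: str
    year: int
    population: float
    area: float
    resources: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.unit_name:
            raise ValidationError("unit_name must be non-empty")
        if not (self.population > 0 and math.isfinite(self.population)):
            raise ValidationError(
                f"{self.unit_name} ({self.year}): population must be positive, "
                f"got {self.population!r}"
            )
        if not (self.area > 0 and math.isfinite(self.area)):
            raise ValidationError(
                f"{self.unit_name} ({self.year}): area must be positive, got {self.area!r}"
            )
        for name, amount in self.resources.items():
            if not (amount >= 0 and math.isfinite(amount)):
                raise ValidationError(
                    f"{self.unit_name} ({self.year}): resource {name!r} must be "
                    f"a finite non-negative amount, got {amount!r}"
                )
        object.__setattr__(self, "resources", dict(self.resources))


class ResourcePanel:
    """Validated collection of :class:`ProvinceRecord` spanning years.

    All records must carry the same indicator set, and unit names must be
    unique within each year.
    """

    def __init__(
        self,
        records: Iterable[ProvinceRecord],
        indicator_names: Sequence[str] | None = None,
    ) -> None:
        self.records: list[ProvinceRecord] = list(records)
        if not self.records:
            raise ValidationError("panel must contain at least one record")
        first = tuple(self.records[0].resources)
        for rec in self.records:
            if set(rec.resources) != set(first):
                raise ValidationError(
                    f"{rec.unit_name} ({rec.year}) carries indicators "
                    f"{sorted(rec.resources)} but the panel uses {sorted(first)}"
                )
        if indicator_names is None:
            indicator_names = first
        elif set(indicator_names) != set(first):
            raise ValidationError(
                f"indicator_names {list(indicator_names)} do not match record "
                f"indicators {sorted(first)}"
            )
        self.indicator_names: tuple[str, ...] = tuple(indicator_names)
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            key = (rec.year, rec.unit_name)
            if key in seen:
                raise ValidationError(
                    f"duplicate unit {rec.unit_name!r} in year {rec.year}"
                )
            seen.add(key)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResourcePanel":
        """Build a panel from a tidy frame in the panel CSV schema.

        Expected columns: ``unit, year, population_10k, area_10k_km2`` plus
        one column per indicator (``investment`` may appear under its unit-
        suffixed CSV name ``investment_100m_yuan``).
        """
        frame = frame.rename(columns={"investment_100m_yuan": "investment"})
        meta = {"unit", "year", "population_10k", "area_10k_km2"}
        missing = meta - set(frame.columns)
        if missing:
            raise ValidationError(f"panel frame missing columns: {sorted(missing)}")
        indicators = [c for c in frame.columns if c not in meta]
        if not indicators:
            raise ValidationError("panel frame has no indicator columns")
        records = [
            ProvinceRecord(
                unit_name=str(row.unit),
                year=int(row.year),
                population=float(row.population_10k),
                area=float(row.area_10k_km2),
                resources={k: float(getattr(row, k)) for k in indicators},
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records, indicator_names=indicators)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame, one row per (unit, year), full float precision."""
        rows = [
            {
                "unit": r.unit_name,
                "year": r.year,
                "population_10k": r.population,
                "area_10k_km2": r.area,
                **{k: r.resources[k] for k in self.indicator_names},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    # -- views -----------------------------------------------------------

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({r.year for r in self.records}))

    def units(self, year: int | None = None) -> tuple[str, ...]:
        if year is None:
            out: list[str] = []
            seen: set[str] = set()
            for r in self.records:
                if r.unit_name not in seen:
                    seen.add(r.unit_name)
                    out.append(r.unit_name)
            return tuple(out)
        return tuple(r.unit_name for r in self.records if r.year == year)

    def year_slice(self, year: int) -> "ResourcePanel":
        records = [r for r in self.records if r.year == year]
        if not records:
            raise ValidationError(f"panel has no records for year {year}")
        return ResourcePanel(records, indicator_names=self.indicator_names)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ResourcePanel({len(self.records)} records, years={list(self.years)}, "
            f"indicators={list(self.indicator_names)})"
        )


@dataclass(frozen=True)
class ShareVector:
    """Paired population shares ``p`` and resource shares ``y`` over units.

    By default both vectors are proportions of the slice totals and sum to
    one. When shares are taken against explicit (e.g. national yearbook)
    totals that exceed the slice sums, the sums fall below one; this is
    recorded in :attr:`is_normalized`. ``adjusted`` marks vectors whose
    zero resource shares were floored by the opt-in epsilon policy.
    """

    unit_names: tuple[str, ...]
    p: np.ndarray
    y: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "unit_names", tuple(self.unit_names))
        if len(self.unit_names) != p.size or p.size != y.size:
            raise ValidationError("unit_names, p and y must have equal length")
        if p.size == 0:
            raise ValidationError("share vector must be non-empty")
        if len(set(self.unit_names)) != len(self.unit_names):
            raise ValidationError("unit_names must be distinct")
        if not (np.isfinite(p).all() and np.isfinite(y).all()):
            raise ValidationError("shares must be finite")
        if (p < 0).any() or (y < 0).any():
            raise ValidationError("shares must be non-negative")
        for label, v in (("p", p), ("y", y)):
            s = float(v.sum())
            if not 0 < s <= 1 + SHARE_SUM_TOL:
                raise ValidationError(
                    f"sum of {label} must lie in (0, 1], got {s!r}"
                )

    @property
    def is_normalized(self) -> bool:
        """True when both share vectors sum to one (slice-total denominators)."""
        return (
            abs(float(self.p.sum()) - 1.0) <= SHARE_SUM_TOL
            and abs(float(self.y.sum()) - 1.0) <= SHARE_SUM_TOL
        )

    def __len__(self) -> int:
        return len(self.unit_names)

    def restrict(self, members: Iterable[str]) -> "ShareVector":
        """Renormalized shares over a subset of units (within-group view).

        p and y are divided by the group sums p_g, y_g, so the result is
        always normalized regardless of the parent vector's denominators.
        """
        wanted = set(members)
        if not wanted:
            raise ValidationError("member set must be non-empty")
        unknown = wanted - set(self.unit_names)
        if unknown:
            raise ValidationError(f"unknown units: {sorted(unknown)}")
        idx = [i for i, u in enumerate(self.unit_names) if u in wanted]
        p_g = float(self.p[idx].sum())
        y_g = float(self.y[idx].sum())
        if p_g <= 0:
            raise DegenerateInputError("group population share is zero")
        if y_g <= 0:
            raise DegenerateInputError("group resource share is zero")
        return ShareVector(
            tuple(self.unit_names[i] for i in idx),
            self.p[idx] / p_g,
            self.y[idx] / y_g,
            adjusted=self.adjusted,
        )

    def floor_zeros(self, epsilon: float = 1e-12) -> "ShareVector":
        """Opt-in epsilon policy: floor zero resource shares, renormalize y.

        Returns a vector flagged ``adjusted=True`` when any flooring took
        place, so downstream results can be marked as such. Population
        shares are untouched.
        """
        if epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        zero = self.y == 0
        if not zero.any():
            return self
        y = np.where(zero, epsilon, self.y)
        # rescale so the total resource share is preserved
        y = y * (float(self.y.sum()) / float(y.sum()))
        return ShareVector(self.unit_names, self.p.copy(), y, adjusted=True)


@dataclass(frozen=True)
class RegionPartition:
    """Assignment of every unit to exactly one named group.

    ``group_names`` fixes a stable reporting order; the packaged China
    partition orders groups east, central, west.
    """

    mapping: Mapping[str, str]
    group_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        mapping = dict(self.mapping)
        object.__setattr__(self, "mapping", mapping)
        groups = tuple(self.group_names) if self.group_names else tuple(
            dict.fromkeys(mapping.values())
        )
        object.__setattr__(self, "group_names", groups)
        declared = set(groups)
        used = set(mapping.values())
        if not used:
            raise ValidationError("partition mapping must be non-empty")
        if not used <= declared:
            raise ValidationError(
                f"mapping uses undeclared groups: {sorted(used - declared)}"
            )
        empty = declared - used
        if empty:
            raise EmptyGroupError(f"empty group(s): {sorted(empty)}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionPartition":
        """Build from a two-column ``unit,region`` frame."""
        missing = {"unit", "region"} - set(frame.columns)
        if missing:
            raise ValidationError(f"partition frame missing columns: {sorted(missing)}")
        dup = frame["unit"][frame["unit"].duplicated()]
        if not dup.empty:
            raise DuplicateAssignmentError(
                f"unit(s) assigned more than once: {sorted(set(dup))}"
            )
        mapping = dict(zip(frame["unit"].astype(str), frame["region"].astype(str)))
        return cls(mapping, tuple(dict.fromkeys(frame["region"].astype(str))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": list(self.mapping), "region": [self.mapping[u] for u in self.mapping]}
        )

    def members(self, group: str) -> tuple[str, ...]:
        if group not in self.group_names:
            raise ValidationError(f"unknown group {group!r}")
        return tuple(u for u, g in self.mapping.items() if g == group)

    def __len__(self) -> int:
        return len(self.group_names)


def build_share_vector(
    panel_slice: ResourcePanel,
    indicator: str,
    *,
    population_total: float | None = None,
    resource_total: float | None = None,
) -> ShareVector:
    """Population and resource shares for one year slice and one indicator.

    By default shares are proportions of the slice sums, so both vectors
    sum to one. Published yearbook analyses instead divide by national
    totals that exceed the sum over listed units (they include entities
    not attributable to any province); pass those as ``population_total``
    and ``resource_total`` to reproduce that convention. Totals must be
    at least the corresponding slice sums.

    Raises
    ------
    ValidationError
        Empty slice, multiple years, or unknown indicator.
    DegenerateInputError
        Total resource amount is zero: shares are undefined.
    """
    years = {r.year for r in panel_slice.records}
    if len(years) != 1:
        raise ValidationError(
            f"share vectors are per-year; slice spans years {sorted(years)}"
        )
    if indicator not in panel_slice.indicator_names:
        raise ValidationError(
            f"unknown indicator {indicator!r}; panel carries "
            f"{list(panel_slice.indicator_names)}"
        )
    units = tuple(r.unit_name for r in panel_slice.records)
    pop = np.array([r.population for r in panel_slice.records], dtype=float)
    amt = np.array([r.resources[indicator] for r in panel_slice.records], dtype=float)
    pop_sum = float(pop.sum())
    amt_sum = float(amt.sum())
    if amt_sum <= 0:
        raise DegenerateInputError(
            f"total {indicator!r} amount is zero; shares are undefined"
        )
    p_den = pop_sum if population_total is None else float(population_total)
    y_den = amt_sum if resource_total is None else float(resource_total)
    if p_den < pop_sum * (1 - SHARE_SUM_TOL) or p_den <= 0:
        raise ValidationError(
            f"population_total {p_den!r} is smaller than the slice sum {pop_sum!r}"
        )
    if y_den < amt_sum * (1 - SHARE_SUM_TOL) or y_den <= 0:
        raise ValidationError(
            f"resource_total {y_den!r} is smaller than the slice sum {amt_sum!r}"
        )
    return ShareVector(units, pop / p_den, amt / y_den)


def validate_partition(
    partition: RegionPartition, panel_slice: ResourcePanel | Iterable[str]
) -> RegionPartition:
    """Check that ``partition`` covers every unit of the slice exactly once.

    Returns the partition unchanged on success. Units present in the
    mapping but absent from the slice are tolerated (a national partition
    may cover more units than a filtered panel), but every slice unit must
    be assigned, and at least one member of every declared group must
    remain in the slice.
    """
    if isinstance(panel_slice, ResourcePanel):
        units = panel_slice.units()
    else:
        units = tuple(panel_slice)
    uncovered = [u for u in units if u not in partition.mapping]
    if uncovered:
        raise CoverageError(f"unit(s) not assigned to any group: {uncovered}")
    present = set(units)
    for g in partition.group_names:
        if not present.intersection(partition.members(g)):
            raise EmptyGroupError(f"group {g!r} has no members in this slice")
    return partition
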