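"""Theil-L index and its exact within/between-group decomposition.

The statistic implemented here is the population-share-weighted mean log
deviation (the "Theil-L" member of the generalized-entropy family),

    T = Σ_i p_i · ln(p_i / y_i),

where ``p_i`` is unit *i*'s share of total population and ``y_i`` its
share of the total resource. T is zero exactly when every unit's resource
share matches its population share (allocation proportional to need) and
grows as resources concentrate away from population. Unlike the Gini
coefficient, T decomposes *exactly* over any partition of the units into
groups:

    T = Σ_g p_g·t_g  +  Σ_g p_g·ln(p_g / y_g)  =  T_intra + T_inter,

with ``p_g = Σ_{i∈g} p_i``, ``y_g = Σ_{i∈g} y_i`` and ``t_g`` the same
index recomputed on shares renormalized within group *g*. The identity is
algebraic, so it holds to floating-point rounding regardless of the data
— a property the test suite exploits heavily. Dividing each component by
T yields contribution rates that add to one.

Note the index is weighted by population shares, not resource shares;
the resource-weighted "Theil-T" statistic has a different decomposition
(weights ``y_g``) and is deliberately not implemented here.

Although popular summaries describe the index as ranging from 0 to 1, it
is unbounded above (a vanishing resource share at fixed population share
drives T → ∞); no cap is applied, since capping would break additivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import RegionPartition, ShareVector, validate_partition
from .errors import DegenerateInputError, ValidationError, ZeroResourceError

#: Absolute tolerance for the additivity identity T = T_intra + T_inter.
ADDITIVITY_TOL = 1e-12

WITHIN_ROW = "__within__"
BETWEEN_ROW = "__between__"
TOTAL_ROW = "__total__"


def theil_index(
    shares: ShareVector,
    *,
    epsilon_floor: bool = False,
    epsilon: float = 1e-12,
) -> float:
    """Theil-L index T = Σ p_i ln(p_i / y_i) of a share vector.

    Terms with ``p_i = 0`` contribute zero (the continuous limit of
    p·ln p). A unit with ``p_i > 0`` and ``y_i = 0`` makes the index
    infinite; by default this raises :class:`ZeroResourceError`. With
    ``epsilon_floor=True`` zero resource shares are floored at
    ``epsilon`` (and y rescaled to its original sum) before evaluation —
    an exploratory device, not a fix for broken data.

    On normalized shares the result is non-negative (Gibbs' inequality).
    """
    sv = shares
    offending = [
        u for u, pi, yi in zip(sv.unit_names, sv.p, sv.y) if pi > 0 and yi == 0
    ]
    if offending:
        if not epsilon_floor:
            raise ZeroResourceError(
                "zero resource share with positive population share for "
                f"unit(s) {offending}; the index is undefined "
                "(pass epsilon_floor=True to floor and renormalize)"
            )
        sv = sv.floor_zeros(epsilon)
    mask = sv.p > 0
    p = sv.p[mask]
    y = sv.y[mask]
    return float(np.sum(p * np.log(p / y)))


def within_group_theil(
    shares: ShareVector,
    members,
    *,
    epsilon_floor: bool = False,
    epsilon: float = 1e-12,
) -> float:
    """Within-group index t_g: Theil-L of shares renormalized inside a group.

    ``members`` is any iterable of unit names drawn from ``shares``. The
    renormalization divides p and y by the group sums, so the result does
    not depend on the denominators used for the parent vector. A singleton
    group has t_g = 0.
    """
    return theil_index(
        shares.restrict(members), epsilon_floor=epsilon_floor, epsilon=epsilon
    )


@dataclass(frozen=True)
class GroupTerm:
    """One group's slice of a decomposition."""

    p_g: float
    y_g: float
    t_g: float
    weighted_term: float  # p_g · t_g
    contribution: float | None  # p_g · t_g / T, None when T == 0


@dataclass(frozen=True)
class TheilDecomposition:
    """Exact split of the Theil-L index over a region partition.

    ``total`` is recomputed independently from the un-partitioned shares;
    construction verifies |total − (within + between)| < 1e-12. The
    contribution fields are ``None`` when ``total == 0`` (0/0 has no
    meaningful value; a perfectly equitable allocation has no inequality
    to attribute).
    """

    total: float
    within: float
    between: float
    group_terms: Mapping[str, GroupTerm]
    contribution_within: float | None
    contribution_between: float | None
    adjusted: bool = False

    @property
    def contribution_by_group(self) -> dict[str, float | None]:
        return {g: term.contribution for g, term in self.group_terms.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per group plus within/between/total summary rows."""
        rows = [
            {
                "group": g,
                "p_g": t.p_g,
                "y_g": t.y_g,
                "t_g": t.t_g,
                "weighted_term": t.weighted_term,
                "contribution": np.nan if t.contribution is None else t.contribution,
            }
            for g, t in self.group_terms.items()
        ]
        for name, value, contrib in (
            (WITHIN_ROW, self.within, self.contribution_within),
            (BETWEEN_ROW, self.between, self.contribution_between),
            (TOTAL_ROW, self.total, None if self.total == 0 else 1.0),
        ):
            rows.append(
                {
                    "group": name,
                    "p_g": np.nan,
                    "y_g": np.nan,
                    "t_g": np.nan,
                    "weighted_term": value,
                    "contribution": np.nan if contrib is None else contrib,
                }
            )
        return pd.DataFrame(rows)


def decompose(
    shares: ShareVector,
    partition: RegionPartition,
    *,
    epsilon_floor: bool = False,
    epsilon: float = 1e-12,
) -> TheilDecomposition:
    """Within/between decomposition of the Theil-L index over a partition.

    Computes, per group g, the population share ``p_g``, resource share
    ``y_g`` and within-group index ``t_g``; then

    * between = Σ_g p_g ln(p_g / y_g)
    * within  = Σ_g p_g t_g
    * total   = Σ_i p_i ln(p_i / y_i), evaluated independently.

    The additivity identity is asserted at :data:`ADDITIVITY_TOL`.
    Contribution rates divide each component by ``total`` and are ``None``
    when ``total`` is zero.
    """
    validate_partition(partition, shares.unit_names)
    sv = shares
    if epsilon_floor and any(pi > 0 and yi == 0 for pi, yi in zip(sv.p, sv.y)):
        sv = sv.floor_zeros(epsilon)
    total = theil_index(sv)

    index_of = {u: i for i, u in enumerate(sv.unit_names)}
    group_terms: dict[str, GroupTerm] = {}
    between = 0.0
    within = 0.0
    for g in partition.group_names:
        members = [u for u in partition.members(g) if u in index_of]
        idx = [index_of[u] for u in members]
        p_g = float(sv.p[idx].sum())
        y_g = float(sv.y[idx].sum())
        if p_g <= 0:
            raise DegenerateInputError(f"group {g!r} has zero population share")
        if y_g <= 0:
            raise DegenerateInputError(f"group {g!r} has zero resource share")
        t_g = theil_index(sv.restrict(members))
        weighted = p_g * t_g
        within += weighted
        between += p_g * np.log(p_g / y_g)
        group_terms[g] = GroupTerm(
            p_g=p_g,
            y_g=y_g,
            t_g=t_g,
            weighted_term=weighted,
            contribution=None,
        )
    residual = abs(total - (within + between))
    if residual >= ADDITIVITY_TOL:
        raise AssertionError(
            f"decomposition additivity violated: |T - (Tw + Tb)| = {residual:.3e}"
        )
    if total != 0.0:
        group_terms = {
            g: GroupTerm(t.p_g, t.y_g, t.t_g, t.weighted_term, t.weighted_term / total)
            for g, t in group_terms.items()
        }
        c_within: float | None = within / total
        c_between: float | None = between / total
    else:
        c_within = c_between = None
    return TheilDecomposition(
        total=total,
        within=within,
        between=float(between),
        group_terms=group_terms,
        contribution_within=c_within,
        contribution_between=c_between,
        adjusted=sv.adjusted,
    )
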