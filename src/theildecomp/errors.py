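"""Exception taxonomy.

All errors raised by this package derive from :class:`TheildecompError`,
so callers can catch one base class. Validation failures (bad panel rows,
broken partitions, malformed CSV) and degenerate statistical inputs
(zero totals, zero resource shares) are kept distinct: the former mean
the data are malformed, the latter mean the statistic is undefined on
otherwise well-formed data.
"""

from __future__ import annotations


class TheildecompError(Exception):
    """Base class for all errors raised by theildecomp."""


class ValidationError(TheildecompError, ValueError):
    """Input data violate a structural invariant (bad record, bad panel)."""


class PanelParseError(ValidationError):
    """A panel or partition CSV is malformed; message names row/column."""


class PartitionError(ValidationError):
    """A region partition is inconsistent with the panel it should cover."""


class CoverageError(PartitionError):
    """A unit in the panel slice is not assigned to any group."""


class DuplicateAssignmentError(PartitionError):
    """A unit is assigned to more than one group."""


class EmptyGroupError(PartitionError):
    """A declared group has no members."""


class DegenerateInputError(TheildecompError, ValueError):
    """Well-formed data on which the requested statistic is undefined."""


class ZeroResourceError(DegenerateInputError):
    """A unit holds population but zero resources, so ln(p/y) diverges.

    Raised by :func:`theildecomp.theil.theil_index` unless the caller
    opts into the epsilon-floor policy.
    """
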