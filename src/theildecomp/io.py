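"""CSV/YAML reading and writing, and access to the packaged fixtures.

Panel CSV schema (header required, UTF-8, period decimal separator)::

    unit,year,population_10k,area_10k_km2,institutions,personnel,beds,investment_100m_yuan

Partition CSV schema::

    unit,region

Unit conventions are encoded in the column names so a fixture file is
self-describing. All numeric output keeps full double precision; rounding
for display is a presentation concern only.
"""

from __future__ import annotations

from importlib import resources
from os import PathLike
from pathlib import Path

import pandas as pd
import yaml

from .data_model import RegionPartition, ResourcePanel
from .errors import PanelParseError, ValidationError
from .synthetic import ScenarioConfig

PANEL_META_COLUMNS = ("unit", "year", "population_10k", "area_10k_km2")

#: Canonical fixture column order (investment carries its unit suffix).
PANEL_COLUMNS = PANEL_META_COLUMNS + (
    "institutions",
    "personnel",
    "beds",
    "investment_100m_yuan",
)

#: Name accepted by the CLI for the built-in east/central/west partition.
CHINA_PARTITION_NAME = "china3"
CHINA_PANEL_NAME = "china2013"


def _read_csv(path: str | PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise PanelParseError(f"no such file: {path}")
    try:
        return pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # pandas raises several parser error types
        raise PanelParseError(f"{path}: {exc}") from exc


def read_panel(path: str | PathLike) -> ResourcePanel:
    """Read and validate a panel CSV.

    Malformed cells are reported with their file line number (header is
    line 1) and column name.
    """
    frame = _read_csv(path)
    missing = set(PANEL_META_COLUMNS) - set(frame.columns)
    if missing:
        raise PanelParseError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"expected header {','.join(PANEL_COLUMNS)}"
        )
    if frame.empty:
        raise PanelParseError(f"{path}: no data rows (empty panel)")
    numeric_cols = [c for c in frame.columns if c != "unit"]
    for col in numeric_cols:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[parsed.isna()]
        if len(bad):
            line = int(bad[0]) + 2
            raise PanelParseError(
                f"{path}: non-numeric value {frame.loc[bad[0], col]!r} "
                f"in column {col!r} at line {line}"
            )
        # builtin float() is correctly rounded, unlike pandas' fast parser,
        # so written panels read back bit-identically
        frame[col] = frame[col].map(float)
    dup = frame.duplicated(subset=["unit", "year"])
    if dup.any():
        i = int(frame.index[dup][0])
        raise PanelParseError(
            f"{path}: duplicate (unit, year) = "
            f"({frame.loc[i, 'unit']!r}, {int(frame.loc[i, 'year'])}) at line {i + 2}"
        )
    try:
        return ResourcePanel.from_frame(frame)
    except ValidationError as exc:
        raise PanelParseError(f"{path}: {exc}") from exc


def write_panel(panel: ResourcePanel, path: str | PathLike) -> Path:
    """Write a panel in the panel CSV schema at full float precision."""
    path = Path(path)
    frame = panel.to_frame().rename(columns={"investment": "investment_100m_yuan"})
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_partition(path: str | PathLike) -> RegionPartition:
    """Read a ``unit,region`` CSV into a :class:`RegionPartition`."""
    frame = _read_csv(path)
    missing = {"unit", "region"} - set(frame.columns)
    if missing:
        raise PanelParseError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            "expected header unit,region"
        )
    if frame.empty:
        raise PanelParseError(f"{path}: no data rows (empty partition)")
    return RegionPartition.from_frame(frame)


def write_partition(partition: RegionPartition, path: str | PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    partition.to_frame().to_csv(path, index=False)
    return path


# -- packaged fixtures -----------------------------------------------------


def _dataset(name: str):
    return resources.files("theildecomp") / "datasets" / name


def load_china_2013_panel() -> ResourcePanel:
    """The 31-unit 2013 cross-section reconstructed from the published tables.

    Absolute amounts are per-capita printed values × population, so the
    per-capita densities recomputed from this panel reproduce the printed
    table exactly; the absolute counts inherit the tables' rounding.
    """
    with resources.as_file(_dataset("china_2013_panel.csv")) as p:
        return read_panel(p)


def load_china_regions() -> RegionPartition:
    """East/central/west partition of the 31 units (11/8/12)."""
    with resources.as_file(_dataset("china_regions.csv")) as p:
        return read_partition(p)


def load_china_national_totals() -> pd.DataFrame:
    """National yearbook totals 2009–2013, one row per year.

    These national figures exceed the sums over the 31 listed units
    (yearbook totals include entities not attributed to any province);
    they are the denominators behind the published national Theil series.
    """
    with resources.as_file(_dataset("china_national_totals.csv")) as p:
        return pd.read_csv(p)


def resolve_partition(source: str | PathLike) -> RegionPartition:
    """Resolve a CLI partition argument: builtin name or CSV path."""
    if str(source) == CHINA_PARTITION_NAME:
        return load_china_regions()
    return read_partition(source)


def resolve_panel(source: str | PathLike) -> ResourcePanel:
    """Resolve a CLI panel argument: builtin name or CSV path."""
    if str(source) == CHINA_PANEL_NAME:
        return load_china_2013_panel()
    return read_panel(source)


# -- scenario configs ------------------------------------------------------


def read_scenario(path: str | PathLike) -> ScenarioConfig:
    """Read a YAML scenario file into a :class:`ScenarioConfig`."""
    path = Path(path)
    if not path.exists():
        raise PanelParseError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PanelParseError(f"{path}: scenario file must be a YAML mapping")
    try:
        return ScenarioConfig.from_dict(data)
    except TypeError as exc:
        raise PanelParseError(f"{path}: {exc}") from exc


def write_scenario(config: ScenarioConfig, path: str | PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path
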