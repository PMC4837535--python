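"""Optional matplotlib views of trend tables (line chart + stacked bars).

matplotlib is imported lazily so the rest of the package has no hard
dependency on it; install the ``plots`` extra to use this module.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path

import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_theil_trend(table: pd.DataFrame, path: str | PathLike) -> Path:
    """Line chart of the Theil index by year, one panel per indicator.

    ``table`` is a :func:`theildecomp.density.theil_trend` table; every
    scope (national and each group) becomes one line.
    """
    plt = _pyplot()
    indicators = list(dict.fromkeys(table["indicator"]))
    fig, axes = plt.subplots(
        1, len(indicators), figsize=(4 * len(indicators), 3.2), squeeze=False
    )
    for ax, ind in zip(axes[0], indicators):
        sub = table[table["indicator"] == ind]
        for scope, grp in sub.groupby("scope", sort=False):
            ax.plot(grp["year"], grp["theil"], marker="o", label=str(scope))
        ax.set_title(ind)
        ax.set_xlabel("year")
        ax.set_ylabel("Theil-L")
    axes[0][0].legend(fontsize="small")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_contribution_rates(table: pd.DataFrame, path: str | PathLike) -> Path:
    """Stacked bars of group contribution rates plus the between share.

    Requires a trend table produced with a partition, so group rows carry
    ``contribution`` and national rows ``contribution_between``.
    """
    if "contribution" not in table.columns:
        raise ValueError("trend table has no contribution columns (no partition?)")
    plt = _pyplot()
    indicators = list(dict.fromkeys(table["indicator"]))
    groups = [s for s in dict.fromkeys(table["scope"]) if s != "national"]
    fig, axes = plt.subplots(
        1, len(indicators), figsize=(4 * len(indicators), 3.2), squeeze=False
    )
    for ax, ind in zip(axes[0], indicators):
        sub = table[table["indicator"] == ind]
        years = sorted(set(sub["year"]))
        bottom = [0.0] * len(years)
        for scope in groups + ["between"]:
            if scope == "between":
                vals = [
                    float(
                        sub[(sub["year"] == y) & (sub["scope"] == "national")][
                            "contribution_between"
                        ].iloc[0]
                    )
                    for y in years
                ]
            else:
                vals = [
                    float(
                        sub[(sub["year"] == y) & (sub["scope"] == scope)][
                            "contribution"
                        ].iloc[0]
                    )
                    for y in years
                ]
            ax.bar(years, vals, bottom=bottom, label=scope)
            bottom = [b + v for b, v in zip(bottom, vals)]
        ax.set_title(ind)
        ax.set_xlabel("year")
        ax.set_ylabel("contribution rate")
    axes[0][0].legend(fontsize="small")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
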