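"""Minimal static figures for adequacy gaps under the scenarios."""

from __future__ import annotations

import pandas as pd


def plot_adequacy_gaps(results, series: pd.DataFrame | None = None, ax=None):
    """Grouped bars of mean adequacy gap per (sex, age class).

    With a scenario ``series`` (from a projection) each scenario becomes a
    bar series; the zero line marks intake equal to the reference level,
    negative bars inadequacy.
    """
    import matplotlib.pyplot as plt

    if series is None:
        adequacy = results.adequacy()
        series = adequacy.assign(series="current")[
            ["sex", "age_class", "series", "mean_gap_mg_day"]
        ]
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4.5))
    wide = series.pivot_table(
        index=["sex", "age_class"],
        columns="series",
        values="mean_gap_mg_day",
        sort=False,
    )
    wide.plot.bar(ax=ax, width=0.8)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel("mean iron intake - PRI (mg/day)")
    ax.set_xlabel("")
    ax.legend(title="scenario", fontsize=8)
    ax.figure.tight_layout()
    return ax
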