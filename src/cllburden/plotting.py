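"""Optional plots: prevalence/cost trends and the tornado diagram.

Matplotlib is imported lazily; plots are conveniences, the CSV outputs are
the canonical results.
"""

from __future__ import annotations

import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_prevalence(results, ax=None):
    """Annual prevalence (excluding watchful waiting) per scenario."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for sc, sub in results.prevalence.groupby("scenario"):
        ax.plot(sub["year"], sub["alive_excl_ww"], marker="o", label=sc)
    ax.set_xlabel("Year")
    ax.set_ylabel("Patients living with CLL (excl. WW)")
    ax.legend(title="Scenario")
    return ax


def plot_costs(results, ax=None):
    """Total annual cost of CLL management per scenario."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    costs = results.costs
    for sc, sub in costs.groupby("scenario"):
        ax.plot(sub["year"], sub["total_cost"] / 1e6, marker="o", label=sc)
    ax.set_xlabel("Year")
    ax.set_ylabel("Total annual cost (million 2019 CAD)")
    ax.legend(title="Scenario")
    return ax


def plot_tornado(tornado: pd.DataFrame, top: int = 15, ax=None):
    """Horizontal-bar tornado diagram from a sensitivity sweep table."""
    plt = _plt()
    df = tornado.dropna(subset=["spread"]).head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.4 * len(df) + 1.5))
    base = df["base_total"].iloc[0] if len(df) else 0.0
    for i, (_, row) in enumerate(df.iterrows()):
        lo = min(row["low_total"], row["high_total"])
        hi = max(row["low_total"], row["high_total"])
        ax.barh(i, (hi - lo) / 1e6, left=(lo - base) / 1e6, color="#4878d0")
    ax.axvline(0.0, color="k", lw=1)
    ax.set_yticks(range(len(df)))
    ax.set_yticklabels(df["parameter"])
    ax.set_xlabel("Change in total cost vs baseline (million 2019 CAD)")
    return ax
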