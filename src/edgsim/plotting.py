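"""Diagnostic plots for simulation results and scenario aggregates."""

from __future__ import annotations

import numpy as np


def plot_richness_trajectory(result, ax=None):
    """Species accumulation curves (regional and per band) for one run."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    tr = result.trajectory
    nb = result.state.landscape.n_bands
    for b in range(nb):
        ax.plot(tr["time"], tr[f"richness_band{b}"], label=f"band {b}")
    ax.plot(tr["time"], tr["regional_richness"], "k-", lw=2, label="regional")
    if result.equilibrium:
        ax.axvline(result.equilibrium_time, ls="--", c="gray",
                   label="equilibrium")
    ax.set_xlabel("time")
    ax.set_ylabel("species richness")
    ax.legend(fontsize=8)
    return ax


def plot_edg_bars(aggregate, scenario: str, ax=None):
    """Mean per-band richness bars for one scenario of an aggregate table."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    row = aggregate.loc[aggregate["scenario"] == scenario].iloc[0]
    bands = [c for c in aggregate.columns if c.startswith("mean_richness_band")]
    vals = [row[c] for c in bands]
    ax.bar(np.arange(len(vals)), vals)
    ax.set_xticks(np.arange(len(vals)))
    ax.set_xticklabels([f"band {i}" for i in range(len(vals))])
    ax.set_ylabel("mean richness")
    ax.set_title(scenario, fontsize=9)
    return ax
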