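"""Matplotlib figures for the standard outputs."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_survivorship", "plot_prr_violin", "plot_relatedness"]


def plot_survivorship(env_female: pd.DataFrame, env_male: pd.DataFrame = None,
                      ax=None):
    """Survivorship with a 95% credible envelope per sex."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(env_female["age"], env_female["median"], color="crimson",
            label="female")
    ax.fill_between(env_female["age"], env_female["lo"], env_female["hi"],
                    color="crimson", alpha=0.2)
    if env_male is not None:
        ax.plot(env_male["age"], env_male["median"], color="steelblue",
                label="male")
        ax.fill_between(env_male["age"], env_male["lo"], env_male["hi"],
                        color="steelblue", alpha=0.2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("survivorship $l_x$")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_prr_violin(prr_values: dict, ax=None):
    """Violin plot of PrR values, one violin per labelled trajectory."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = list(prr_values)
    data = [np.atleast_1d(prr_values[k]) for k in labels]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("postreproductive representation")
    ax.axhline(0, color="grey", lw=0.8, ls=":")
    return ax


def plot_relatedness(trajectories: pd.DataFrame, ax=None):
    """Relatedness-by-age curves per scenario with Monte Carlo bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, df in trajectories.groupby("scenario"):
        ax.plot(df["age"], df["r_mean"], label=label)
        ax.fill_between(df["age"], df["r_mean"] - 2 * df["r_mc_se"],
                        df["r_mean"] + 2 * df["r_mc_se"], alpha=0.2)
    ax.set_xlabel("female age (years)")
    ax.set_ylabel("mean relatedness to group")
    ax.legend()
    return ax
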