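"""Small matplotlib helpers for the standard temperature-sweep curves."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_observable_vs_tstar(results: pd.DataFrame, observable: str, ax=None,
                             by: str = "unit"):
    """Plot ``mean`` vs T* of one observable from the long-format results
    table, one line per ``by`` group, with +/- 1 SE error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = results[results["observable"] == observable]
    for key, grp in sub.groupby(by):
        agg = grp.groupby("tstar")["mean"].agg(["mean", "sem"]).reset_index()
        ax.errorbar(agg["tstar"], agg["mean"], yerr=agg["sem"].fillna(0.0),
                    marker="o", capsize=2, label=str(key))
    ax.set_xlabel("T*")
    ax.set_ylabel(observable)
    ax.legend()
    return ax


def plot_stem_distribution(stems: pd.DataFrame, ax=None):
    """Stem-length histograms on a log10 probability axis, one line per T*."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tstar, grp in stems.groupby("tstar"):
        grp = grp.sort_values("n_tr")
        ax.plot(grp["n_tr"], grp["probability"], marker="o", label=f"T*={tstar:g}")
    ax.set_yscale("log")
    ax.set_xlabel("stem length (dihedral bonds)")
    ax.set_ylabel("P(Ntr)")
    ax.legend()
    return ax
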