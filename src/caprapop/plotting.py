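"""Basic charts: LD decay, Ne trajectory and the ROH length spectrum."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_ld_decay(pairs: pd.DataFrame, path: str, n_bins: int = 25):
    binned = pairs.groupby(pd.cut(pairs["dist_bp"], n_bins),
                           observed=True)["r2"].mean()
    mids = [iv.mid for iv in binned.index]
    fig, ax = plt.subplots()
    ax.plot(mids, binned.values, "o-")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel("mean $r^2$")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ne_trajectory(ne: pd.DataFrame, path: str):
    fig, ax = plt.subplots()
    ok = ne[~ne["flagged"]]
    ax.plot(ok["t"], ok["Ne"], "o-")
    ax.set_xlabel("generations ago")
    ax.set_ylabel("Ne")
    ax.set_xscale("log")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roh_spectrum(spectrum: pd.DataFrame, path: str):
    fig, ax = plt.subplots()
    ax.bar(spectrum["class_mbp"], spectrum["freq"])
    ax.set_xlabel("ROH length class (Mbp)")
    ax.set_ylabel("share of total ROH length")
    fig.savefig(path, dpi=120)
    plt.close(fig)
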