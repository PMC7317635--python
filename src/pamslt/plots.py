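"""Plots for uncertainty outputs: acceptability curve and tornado diagram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_ceac(ceac_table: pd.DataFrame, path) -> Path:
    """Probability of cost-effectiveness against willingness-to-pay threshold."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_table["threshold"] / 1000.0, ceac_table["probability_cost_effective"])
    ax.set_xlabel("Cost-effectiveness threshold (NZ$ thousands per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_tornado(tornado_table: pd.DataFrame, path, output: str = "icer") -> Path:
    """Horizontal bars of one-way parameter ranges, widest at the top."""
    df = tornado_table.sort_values(f"{output}_range")
    base = df[[f"{output}_low", f"{output}_high"]].to_numpy().mean()
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(df) + 1.5))
    lows = df[f"{output}_low"].to_numpy()
    highs = df[f"{output}_high"].to_numpy()
    y = range(len(df))
    ax.barh(y, highs - lows, left=lows, color="#4878b0")
    ax.axvline(base, color="k", lw=0.8)
    ax.set_yticks(list(y))
    ax.set_yticklabels(df["parameter"])
    ax.set_xlabel(output.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
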