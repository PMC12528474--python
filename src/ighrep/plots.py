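"""Optional plotting helpers (files only, no interactive backends)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def frequency_scatter(freq_a: pd.Series, freq_b: pd.Series, path: str | Path,
                      label_a: str = "repertoire A", label_b: str = "repertoire B") -> None:
    """Per-V frequency scatter with the line of equivalence."""
    plt = _pyplot()
    keys = freq_a.index.union(freq_b.index)
    x = freq_a.reindex(keys, fill_value=0.0)
    y = freq_b.reindex(keys, fill_value=0.0)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12, alpha=0.7)
    lim = max(x.max(), y.max()) * 1.05 or 1.0
    ax.plot([0, lim], [0, lim], lw=1, color="grey")
    ax.set_xlabel(label_a)
    ax.set_ylabel(label_b)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def locus_position_bars(values: pd.Series, ranks: dict, path: str | Path,
                        ylabel: str = "") -> None:
    """Bar chart of a per-V statistic ordered by locus position."""
    plt = _pyplot()
    order = sorted(values.index, key=lambda v: ranks.get(v, 0))
    fig, ax = plt.subplots(figsize=(max(4, len(order) * 0.25), 3))
    ax.bar(range(len(order)), values.reindex(order))
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=6)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def positional_delta_heatmap(delta: pd.DataFrame, family: str, path: str | Path) -> None:
    """Heatmap of residue-frequency change by CDR3 position for one family."""
    plt = _pyplot()
    sub = delta[delta["family"] == family]
    mat = sub.pivot_table(index="aa", columns="position", values="delta",
                          fill_value=0.0)
    fig, ax = plt.subplots(figsize=(4, max(3, 0.2 * len(mat))))
    vmax = np.abs(mat.values).max() or 1.0
    im = ax.imshow(mat.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(mat.columns)
    ax.set_yticks(range(mat.shape[0]))
    ax.set_yticklabels(mat.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="freq change")
    ax.set_title(family, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
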