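"""Minimal plotting helpers: Manhattan-style scans and MDS scatter."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popstruct import MdsResult


def manhattan(
    df: pd.DataFrame,
    value_col: str,
    ax=None,
    threshold: float | None = None,
    pos_col: str = "pos_bp",
):
    """Chromosome-concatenated scatter of a per-SNP or per-window statistic.

    ``df`` needs ``chrom``, a position column and ``value_col``; chromosomes
    are laid end to end in input order and alternately shaded.  An optional
    horizontal ``threshold`` line marks the significance cut-off.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, tick_labels = [], []
    for i, (chrom, sub) in enumerate(df.groupby("chrom", sort=False)):
        pos = sub[pos_col].to_numpy(dtype=float)
        ax.scatter(
            pos + offset,
            sub[value_col],
            s=4,
            color="C0" if i % 2 == 0 else "C1",
            rasterized=True,
        )
        ticks.append(offset + pos.mean() if len(pos) else offset)
        tick_labels.append(str(chrom))
        offset += pos.max() if len(pos) else 0
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1)
    ax.set_xticks(ticks, tick_labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(value_col)
    return ax


def mds_scatter(result: MdsResult, populations=None, ax=None):
    """First two principal coordinates, optionally coloured by population."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xy = result.coordinates
    if xy.shape[1] < 2:
        raise ValueError("need at least two MDS dimensions to scatter")
    if populations is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=12)
    else:
        populations = np.asarray(populations)
        for pop in dict.fromkeys(populations):
            sel = populations == pop
            ax.scatter(xy[sel, 0], xy[sel, 1], s=12, label=str(pop))
        ax.legend(fontsize=8)
    ve = result.variance_explained
    ax.set_xlabel(f"dim 1 ({ve[0]:.1%})" if len(ve) > 0 else "dim 1")
    ax.set_ylabel(f"dim 2 ({ve[1]:.1%})" if len(ve) > 1 else "dim 2")
    return ax
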