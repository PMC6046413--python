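"""Host-specificity scoring: which genera associate with ticks vs voles.

Within one biotope, each genus's mean read count per carrier is transformed
as log10(0.1 + mean); the difference of the transformed means (voles minus
ticks) ranks genera from strongly vole-associated (large positive) to
strongly tick-associated (large negative).  Plotted against the genus's
weighted degree in the biotope network, high-|score| genera far from the
network core are candidates for carrier specificity.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .sample_io import ReadMatrix
from .taxon_network import CooccurrenceNetwork, weighted_degree


def log_transform(mean_reads: float) -> float:
    """log10(0.1 + mean_reads); the 0.1 offset keeps zero means finite."""
    if mean_reads < 0:
        raise ValueError("mean_reads must be nonnegative")
    return math.log10(0.1 + mean_reads)


def specificity_table(
    matrix: ReadMatrix,
    network: CooccurrenceNetwork,
    biotope: str,
    positive_samples_only: bool = False,
) -> pd.DataFrame:
    """Per-genus host-specificity records for one biotope.

    Columns: mean_reads_voles, mean_reads_ticks (means over *all* of the
    carrier's samples in the biotope, zeros included, unless
    ``positive_samples_only``), log_score = log10(0.1+mean_voles) -
    log10(0.1+mean_ticks), raw_ratio = summed vole reads / summed tick reads
    (inf when only voles carry it, NaN when neither does), and wd = weighted
    degree in the supplied network (0 for genera absent from it).  Rows are
    sorted by decreasing |log_score|.
    """
    voles = matrix.subset(carrier="vole", biotope=biotope)
    ticks = matrix.subset(carrier="tick", biotope=biotope)
    if len(voles.sample_ids) == 0 or len(ticks.sample_ids) == 0:
        raise ValueError(f"biotope {biotope!r} lacks one of the carriers")

    def carrier_mean(sub: ReadMatrix) -> pd.Series:
        if positive_samples_only:
            pos = sub.counts.where(sub.counts > 0)
            return pos.mean(axis=0).fillna(0.0)
        return sub.counts.mean(axis=0)

    mean_v = carrier_mean(voles)
    mean_t = carrier_mean(ticks)
    sum_v = voles.counts.sum(axis=0).astype(float)
    sum_t = ticks.counts.sum(axis=0).astype(float)
    wd = weighted_degree(network)

    rows = []
    for genus in matrix.taxa:
        if sum_v[genus] == 0 and sum_t[genus] == 0:
            ratio = float("nan")
        elif sum_t[genus] == 0:
            ratio = float("inf")
        else:
            ratio = float(sum_v[genus] / sum_t[genus])
        rows.append(
            {
                "genus": genus,
                "biotope": biotope,
                "mean_reads_voles": float(mean_v[genus]),
                "mean_reads_ticks": float(mean_t[genus]),
                "log_score": log_transform(mean_v[genus]) - log_transform(mean_t[genus]),
                "raw_ratio": ratio,
                "wd": float(wd.get(genus, 0.0)),
            }
        )
    table = pd.DataFrame(rows)
    table["abs_score"] = table["log_score"].abs()
    table = table.sort_values(["abs_score", "genus"], ascending=[False, True]).drop(columns="abs_score")
    return table.reset_index(drop=True)


def plot_specificity(table: pd.DataFrame, path, title: str | None = None) -> None:
    """Scatter of log_score vs WD (the host-specificity chart layout)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    score = table["log_score"]
    sizes = 20 + 60 * (score.abs() / max(score.abs().max(), 1e-9))
    sc = ax.scatter(table["wd"], score, c=score, cmap="coolwarm", s=sizes, edgecolor="k", lw=0.3)
    fig.colorbar(sc, ax=ax, label="log10 read-ratio (voles/ticks)")
    top = table.reindex(score.abs().sort_values(ascending=False).index).head(10)
    for _, r in top.iterrows():
        ax.annotate(r["genus"], (r["wd"], r["log_score"]), fontsize=7)
    ax.set_xlabel("weighted degree (WD)")
    ax.set_ylabel("log10(0.1+mean voles) - log10(0.1+mean ticks)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
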