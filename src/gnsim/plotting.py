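"""Optional static plots (requires matplotlib).

Two views only: expression trajectories over time, and the per-gene count
distribution of a steady-state ensemble.
"""

from __future__ import annotations

from .sampling import ExpressionMatrix

__all__ = ["plot_trajectories", "plot_ensemble_histograms"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_trajectories(matrix: ExpressionMatrix, ax=None, genes: list[str] | None = None):
    """Line plot of molecule counts per readout time (time-series matrices)."""
    if matrix.kind != "timeseries":
        raise ValueError("plot_trajectories expects a time-series matrix")
    ax = _axes(ax)
    times = [float(c) for c in matrix.columns]
    for gene in genes or matrix.genes:
        ax.plot(times, matrix.values[matrix.genes.index(gene)], label=gene, drawstyle="steps-post")
    ax.set_xlabel("time")
    ax.set_ylabel("molecule count")
    ax.legend(fontsize="small")
    return ax


def plot_ensemble_histograms(matrix: ExpressionMatrix, ax=None, genes: list[str] | None = None):
    """Overlaid endpoint-count histograms, one per gene (ensemble matrices)."""
    if matrix.kind != "ensemble":
        raise ValueError("plot_ensemble_histograms expects an ensemble matrix")
    ax = _axes(ax)
    for gene in genes or matrix.genes:
        row = matrix.values[matrix.genes.index(gene)]
        ax.hist(row, bins="auto", alpha=0.5, label=gene)
    ax.set_xlabel("molecule count at stop time")
    ax.set_ylabel("replicates")
    ax.legend(fontsize="small")
    return ax
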