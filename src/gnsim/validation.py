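"""Analytic oracles and the network-inference separation diagnostic.

The separation experiment checks that simulated expression encodes the
generating topology: mutual-information weights of gene pairs connected by
an edge should exceed those of unconnected pairs.  A plain equal-width
binned plug-in MI estimator is used on purpose — the claim under test is a
property of the simulator's output, not of any particular inference method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .compiler import compile_network
from .network import GeneNetwork, generate_network
from .reactions import DelayParams, RateParams
from .sampling import ExpressionMatrix, run_ensemble
from .ssa import SimulationConfig

__all__ = [
    "WeightMatrix",
    "birth_death_stationary",
    "mutual_information_matrix",
    "edge_separation",
    "separation_experiment",
]


def birth_death_stationary(k: float, gamma: float) -> tuple[float, float]:
    """Stationary (mean, variance) of the linear birth–death process.

    Production at rate ``k`` and first-order decay at rate ``gamma`` give a
    Poisson stationary law with mean and variance both ``k / gamma``.
    """
    if gamma <= 0:
        raise ValueError(f"decay rate gamma must be > 0, got {gamma}")
    if k < 0:
        raise ValueError(f"birth rate k must be >= 0, got {k}")
    mean = k / gamma
    return mean, mean


@dataclass
class WeightMatrix:
    """Symmetric non-negative gene × gene association weights (zero diagonal)."""

    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError(f"weight matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("weight matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("weights must be non-negative")

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.genes.index(a), self.genes.index(b)])


def _bin_row(row: np.ndarray, n_bins: int) -> np.ndarray | None:
    """Equal-width bin indices in [0, n_bins), or None for a constant row."""
    lo, hi = row.min(), row.max()
    if lo == hi:
        return None
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.searchsorted(edges, row, side="right") - 1
    return np.clip(idx, 0, n_bins - 1)


def _mi_bits(bi: np.ndarray, bj: np.ndarray, n_bins: int) -> float:
    """Plug-in mutual information (bits) of two binned samples."""
    joint = np.bincount(bi * n_bins + bj, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins)
    joint /= joint.sum()
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(pi, pj)
    return float(np.sum(joint[mask] * np.log2(joint[mask] / outer[mask])))


def mutual_information_matrix(expr: ExpressionMatrix, n_bins: int | None = None) -> WeightMatrix:
    """Binned plug-in MI (bits) for every unordered gene pair.

    ``n_bins`` defaults to ``ceil(sqrt(samples))`` equal-width bins.
    Constant rows contribute zero weight (their MI is undefined under the
    plug-in estimator, and a constant gene carries no association signal).
    """
    n_samples = len(expr.columns)
    if n_samples < 30:
        raise ValueError(f"need an ensemble of >= 30 samples, got {n_samples}")
    if n_bins is None:
        n_bins = math.ceil(math.sqrt(n_samples))
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    data = np.asarray(expr.values, dtype=float)
    binned = [_bin_row(row, n_bins) for row in data]
    n = len(expr.genes)
    weights = np.zeros((n, n))
    for i in range(n):
        if binned[i] is None:
            continue
        for j in range(i + 1, n):
            if binned[j] is None:
                continue
            w = max(0.0, _mi_bits(binned[i], binned[j], n_bins))
            weights[i, j] = weights[j, i] = w
    return WeightMatrix(genes=list(expr.genes), values=weights)


def edge_separation(weights: WeightMatrix, network: GeneNetwork) -> dict:
    """Compare weights of edge pairs against non-edge pairs.

    Pairs are unordered; a pair counts as an edge pair when the network
    links the two genes in either direction.  The effect size is the
    rank-sum AUC: the probability that a random edge pair outweighs a
    random non-edge pair (ties counted half).
    """
    genes = weights.genes
    if set(genes) != set(network.nodes):
        raise ValueError("weight matrix and network must share the same gene ids")
    linked = {frozenset((s, t)) for s, t, _ in network.edges}
    edge_weights: list[float] = []
    nonedge_weights: list[float] = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            w = float(weights.values[i, j])
            if frozenset((genes[i], genes[j])) in linked:
                edge_weights.append(w)
            else:
                nonedge_weights.append(w)
    if not edge_weights or not nonedge_weights:
        raise ValueError("network must have at least one edge pair and one non-edge pair")
    u_stat, _ = stats.mannwhitneyu(edge_weights, nonedge_weights, alternative="two-sided")
    return {
        "median_edge": float(np.median(edge_weights)),
        "median_nonedge": float(np.median(nonedge_weights)),
        "effect_size": float(u_stat / (len(edge_weights) * len(nonedge_weights))),
        "n_edge_pairs": len(edge_weights),
        "n_nonedge_pairs": len(nonedge_weights),
    }


def separation_experiment(
    seed: int,
    n_nodes: int = 20,
    n_samples: int = 200,
    *,
    network_kind: str = "scale_free",
    network_params: dict | None = None,
    rates: RateParams | None = None,
    delays: DelayParams | None = None,
    stop_time: float = 60.0,
    n_bins: int | None = None,
) -> dict:
    """One seeded repetition of the scaled-down edge-separation experiment.

    Generates a signed network, compiles it, draws a steady-state ensemble,
    computes binned-MI weights and returns the :func:`edge_separation`
    summary (plus the network size actually used).
    """
    network = generate_network(network_kind, n_nodes, network_params or {"m": 1}, seed=seed)
    system = compile_network(network, rates or RateParams(), delays or DelayParams())
    config = SimulationConfig(
        stop_time=stop_time,
        readout_interval=stop_time / 2,
        seed=seed,
        sample=n_samples,
    )
    expr = run_ensemble(system, config)
    weights = mutual_information_matrix(expr, n_bins=n_bins)
    summary = edge_separation(weights, network)
    summary["n_nodes"] = n_nodes
    summary["n_samples"] = n_samples
    summary["seed"] = seed
    return summary
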