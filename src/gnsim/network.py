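"""Signed directed gene regulatory networks: generation, I/O and annotation.

Edges carry a regulation sign: ``"+"`` (activation) or ``"-"`` (repression).
Node attributes hold the initial RNA/protein populations used when the
network is compiled into a reaction system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ACTIVATION",
    "REPRESSION",
    "GeneNetwork",
    "generate_network",
    "assign_edge_signs",
    "load_network",
    "save_network",
]

ACTIVATION = "+"
REPRESSION = "-"
_SIGNS = (ACTIVATION, REPRESSION)

NETWORK_FORMATS = ("edge_list", "adjacency", "graphml")


class NetworkError(ValueError):
    """Invalid network structure or unparsable network file."""


@dataclass
class GeneNetwork:
    """A directed, signed gene network.

    Parameters
    ----------
    nodes
        Gene identifiers, order-preserving (compilation follows this order).
    edges
        ``(source, target, sign)`` triples; ``sign`` is ``"+"``, ``"-"`` or
        ``None`` for a not-yet-signed edge (only valid transiently, see
        :func:`assign_edge_signs`).
    node_attrs
        Per-gene ``{"init_rna": int, "init_protein": int}`` initial counts.
    """

    nodes: list[str]
    edges: list[tuple[str, str, str | None]]
    node_attrs: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        self.edges = [(str(s), str(t), g) for s, t, g in self.edges]
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkError("duplicate node identifiers")
        node_set = set(self.nodes)
        seen_pairs: set[tuple[str, str]] = set()
        for source, target, sign in self.edges:
            if source == target:
                raise NetworkError(f"self-loop on {source!r} is not allowed")
            if (source, target) in seen_pairs:
                raise NetworkError(f"duplicate edge ({source!r}, {target!r})")
            seen_pairs.add((source, target))
            if source not in node_set or target not in node_set:
                raise NetworkError(f"edge ({source!r}, {target!r}) references undeclared node")
            if sign is not None and sign not in _SIGNS:
                raise NetworkError(f"edge sign must be '+' or '-', got {sign!r}")
        for gene, attrs in self.node_attrs.items():
            if gene not in node_set:
                raise NetworkError(f"node_attrs references undeclared node {gene!r}")
            for key in ("init_rna", "init_protein"):
                if int(attrs.get(key, 0)) < 0:
                    raise NetworkError(f"{key} of {gene!r} must be >= 0")

    # -- queries -----------------------------------------------------------
    @property
    def is_signed(self) -> bool:
        return all(sign is not None for _, _, sign in self.edges)

    def require_signed(self) -> None:
        if not self.is_signed:
            raise NetworkError("network has unsigned edges; run assign_edge_signs first")

    def regulators(self, gene: str) -> list[tuple[str, str | None]]:
        """Incoming ``(regulator, sign)`` pairs of ``gene``, in edge order."""
        return [(s, g) for s, t, g in self.edges if t == gene]

    def activators(self, gene: str) -> list[str]:
        return [s for s, t, g in self.edges if t == gene and g == ACTIVATION]

    def repressors(self, gene: str) -> list[str]:
        return [s for s, t, g in self.edges if t == gene and g == REPRESSION]

    def in_degree(self, gene: str) -> int:
        return sum(1 for _, t, _ in self.edges if t == gene)

    def init_counts(self, gene: str) -> tuple[int, int]:
        attrs = self.node_attrs.get(gene, {})
        return int(attrs.get("init_rna", 0)), int(attrs.get("init_protein", 0))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            init_rna, init_protein = self.init_counts(node)
            g.add_node(node, init_rna=init_rna, init_protein=init_protein)
        for source, target, sign in self.edges:
            g.add_edge(source, target, sign=sign if sign is not None else "")
        return g


def _gene_names(n_nodes: int) -> list[str]:
    width = len(str(n_nodes))
    return [f"G{i + 1:0{width}d}" for i in range(n_nodes)]


def generate_network(
    kind: str,
    n_nodes: int,
    params: Mapping | None = None,
    seed: int = 0,
) -> GeneNetwork:
    """Generate a signed directed network topology.

    Parameters
    ----------
    kind
        ``"scale_free"`` (preferential attachment; each undirected edge is
        oriented from the earlier-attached node to the later one, so the
        result is deterministic for a fixed seed) or ``"erdos_renyi"``
        (directed G(n, p) over ordered node pairs).
    n_nodes
        Number of genes, at least 2.
    params
        Generator knobs: ``m`` (edges per new node, scale-free, default 2),
        ``p`` (edge probability, Erdős–Rényi, required), and
        ``activation_prob`` (Bernoulli probability that an edge is
        activating, default 1.0).
    seed
        Controls both topology and sign draws; fixed seed gives a
        bit-identical network.
    """
    params = dict(params or {})
    if n_nodes < 2:
        raise NetworkError(f"n_nodes must be >= 2, got {n_nodes}")
    topo_seed, sign_seed = (int(s) for s in np.random.SeedSequence(seed).generate_state(2))

    if kind == "scale_free":
        m = int(params.get("m", 2))
        if not 1 <= m < n_nodes:
            raise NetworkError(f"scale_free parameter m must be in [1, n_nodes), got {m}")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=topo_seed)
        # BA adds nodes in index order: orient low index -> high index
        raw_edges = [(min(u, v), max(u, v)) for u, v in sorted(g.edges())]
    elif kind == "erdos_renyi":
        if "p" not in params:
            raise NetworkError("erdos_renyi requires params['p']")
        p = float(params["p"])
        if not 0.0 <= p <= 1.0:
            raise NetworkError(f"edge probability must be in [0, 1], got {p}")
        g = nx.gnp_random_graph(n_nodes, p, seed=topo_seed, directed=True)
        raw_edges = sorted(g.edges())
    else:
        raise NetworkError(f"unknown network kind {kind!r}")

    names = _gene_names(n_nodes)
    edges = [(names[u], names[v], None) for u, v in raw_edges]
    network = GeneNetwork(nodes=names, edges=edges)
    activation_prob = float(params.get("activation_prob", 1.0))
    return assign_edge_signs(network, activation_prob, seed=sign_seed)


def assign_edge_signs(network: GeneNetwork, activation_prob: float, seed: int = 0) -> GeneNetwork:
    """Return a copy of ``network`` with every edge signed.

    Each edge independently draws activation with probability
    ``activation_prob`` and repression otherwise; existing signs are
    overwritten.
    """
    if not 0.0 <= activation_prob <= 1.0:
        raise NetworkError(f"activation_prob must be in [0, 1], got {activation_prob}")
    rng = np.random.default_rng(seed)
    draws = rng.random(len(network.edges))
    edges = [
        (s, t, ACTIVATION if u < activation_prob else REPRESSION)
        for (s, t, _), u in zip(network.edges, draws)
    ]
    return GeneNetwork(
        nodes=list(network.nodes),
        edges=edges,
        node_attrs={g: dict(a) for g, a in network.node_attrs.items()},
    )


# ---------------------------------------------------------------------------
# File I/O


def load_network(path: str | Path, format: str = "edge_list") -> GeneNetwork:
    """Load a network from ``path``.

    Formats: ``edge_list`` (whitespace-separated ``source target sign`` lines,
    ``#`` comments), ``adjacency`` (square TSV with node names as header row
    and first column, entries in {0, 1, -1}; rows are sources), ``graphml``.
    """
    path = Path(path)
    if format == "edge_list":
        return _load_edge_list(path)
    if format == "adjacency":
        return _load_adjacency(path)
    if format == "graphml":
        return _load_graphml(path)
    raise NetworkError(f"unknown network format {format!r}")


def save_network(network: GeneNetwork, path: str | Path, format: str = "edge_list") -> None:
    path = Path(path)
    if format == "edge_list":
        lines = [f"{s}\t{t}\t{g}" for s, t, g in network.edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "adjacency":
        nodes = network.nodes
        index = {n: i for i, n in enumerate(nodes)}
        matrix = np.zeros((len(nodes), len(nodes)), dtype=int)
        for s, t, g in network.edges:
            matrix[index[s], index[t]] = 1 if g == ACTIVATION else -1
        header = "\t".join([""] + nodes)
        rows = [header]
        for i, n in enumerate(nodes):
            rows.append("\t".join([n] + [str(v) for v in matrix[i]]))
        path.write_text("\n".join(rows) + "\n")
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise NetworkError(f"unknown network format {format!r}")


def _load_edge_list(path: Path) -> GeneNetwork:
    text = path.read_text()
    nodes: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str, str | None]] = []

    def _declare(name: str) -> None:
        if name not in seen:
            seen.add(name)
            nodes.append(name)

    n_meaningful = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        n_meaningful += 1
        parts = line.split()
        if len(parts) != 3:
            raise NetworkError(
                f"{path}:{lineno}: expected 'source target sign', got {line!r}"
            )
        source, target, sign = parts
        if sign not in _SIGNS:
            raise NetworkError(f"{path}:{lineno}: sign must be '+' or '-', got {sign!r}")
        _declare(source)
        _declare(target)
        edges.append((source, target, sign))
    if n_meaningful == 0:
        raise NetworkError(f"{path}: no edges found (empty edge-list file)")
    return GeneNetwork(nodes=nodes, edges=edges)


def _load_adjacency(path: Path) -> GeneNetwork:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise NetworkError(f"{path}: empty adjacency file")
    header = lines[0].split("\t")
    names = [h for h in header if h != ""]
    if len(lines) - 1 != len(names):
        raise NetworkError(f"{path}: adjacency matrix is not square ({len(names)} columns, {len(lines) - 1} rows)")
    edges: list[tuple[str, str, str | None]] = []
    for i, row_text in enumerate(lines[1:]):
        cells = row_text.split("\t")
        row_name = cells[0]
        values = cells[1:]
        if row_name != names[i]:
            raise NetworkError(f"{path}: row label {row_name!r} does not match column order")
        if len(values) != len(names):
            raise NetworkError(f"{path}: row {row_name!r} has {len(values)} entries, expected {len(names)}")
        for j, cell in enumerate(values):
            try:
                value = int(cell)
            except ValueError as exc:
                raise NetworkError(f"{path}: non-integer adjacency entry {cell!r}") from exc
            if value == 0:
                continue
            if value == 1:
                edges.append((row_name, names[j], ACTIVATION))
            elif value == -1:
                edges.append((row_name, names[j], REPRESSION))
            else:
                raise NetworkError(f"{path}: adjacency entries must be 0, 1 or -1, got {value}")
    return GeneNetwork(nodes=names, edges=edges)


def _load_graphml(path: Path) -> GeneNetwork:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:
        raise NetworkError(f"{path}: failed to parse GraphML ({exc})") from exc
    if not g.is_directed():
        raise NetworkError(f"{path}: GraphML network must be directed")
    nodes = [str(n) for n in g.nodes()]
    edges: list[tuple[str, str, str | None]] = []
    for u, v, data in g.edges(data=True):
        sign = data.get("sign", "")
        if sign not in _SIGNS:
            raise NetworkError(
                f"{path}: edge ({u}, {v}) has no 'sign' attribute; "
                "sign edges in-file or use assign_edge_signs on an unsigned load"
            )
        edges.append((str(u), str(v), sign))
    node_attrs = {}
    for n, data in g.nodes(data=True):
        if "init_rna" in data or "init_protein" in data:
            node_attrs[str(n)] = {
                "init_rna": int(data.get("init_rna", 0)),
                "init_protein": int(data.get("init_protein", 0)),
            }
    return GeneNetwork(nodes=nodes, edges=edges, node_attrs=node_attrs)
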