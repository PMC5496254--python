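"""Expression-matrix products: time series and steady-state ensembles.

``run_timeseries`` records per-gene molecule counts on the readout grid of a
single replicate; ``run_ensemble`` repeats the simulation ``n`` times from
the same initial values and keeps each replicate's endpoint as one sample
column ("steady state" is operationalized as endpoint-at-stop-time; choosing
a stop time past the transient is the caller's responsibility, and a warning
is logged when the trajectory still moves near the end).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reactions import ReactionSystem
from .ssa import DelayedSSA, SimulationConfig, replicate_rngs, simulate

__all__ = ["ExpressionMatrix", "run_timeseries", "run_ensemble", "write_matrix", "read_matrix"]

logger = logging.getLogger(__name__)

MATRIX_FORMATS = ("tsv", "csv")


@dataclass
class ExpressionMatrix:
    """Genes × readout-points (or × replicates) matrix of molecule counts."""

    genes: list[str]
    columns: list[str]
    values: np.ndarray  # shape (len(genes), len(columns)), int64
    kind: str = "timeseries"  # or "ensemble"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.genes), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.columns)} columns"
            )
        if (self.values < 0).any():
            raise ValueError("expression counts must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.genes, columns=self.columns)
        frame.index.name = "gene"
        return frame


def _recorded_rows(system: ReactionSystem, record: str) -> tuple[list[str], list[str]]:
    """(row labels, species names) to record, honouring gene metadata."""
    if not system.gene_species:
        # hand-written system: every species is reported under its own name
        names = list(system.species)
        return names, names
    labels: list[str] = []
    names: list[str] = []
    for gene, (rna, prot) in system.gene_species.items():
        labels.append(gene)
        names.append(rna)
    if record == "rna_and_protein":
        for gene, (rna, prot) in system.gene_species.items():
            labels.append(f"{gene}.protein")
            names.append(prot)
    return labels, names


def _config_echo(config: SimulationConfig, kind: str) -> dict:
    return {
        "kind": kind,
        "start_time": config.start_time,
        "stop_time": config.stop_time,
        "readout_interval": config.readout_interval,
        "seed": config.seed,
        "sample": config.sample,
        "record": config.record,
    }


def _format_time(t: float) -> str:
    return f"{t:.10g}"


def run_timeseries(system: ReactionSystem, config: SimulationConfig) -> ExpressionMatrix:
    """One replicate, one column per readout time."""
    labels, names = _recorded_rows(system, config.record)
    trajectory = simulate(system, config)
    picks = [trajectory.species.index(n) for n in names]
    values = trajectory.counts[:, picks].T
    columns = [_format_time(t) for t in trajectory.times]
    return ExpressionMatrix(
        genes=labels,
        columns=columns,
        values=values,
        kind="timeseries",
        metadata=_config_echo(config, "timeseries"),
    )


def run_ensemble(system: ReactionSystem, config: SimulationConfig) -> ExpressionMatrix:
    """``config.sample`` replicates; column r is replicate r's endpoint.

    Replicate r consumes an independent child stream spawned from
    ``config.seed``, so the matrix is reproducible and the columns are
    statistically independent.
    """
    labels, names = _recorded_rows(system, config.record)
    n = config.sample
    rngs = replicate_rngs(config.seed, n)
    engine = DelayedSSA(system, rngs[0])
    picks = None
    values = np.empty((len(labels), n), dtype=np.int64)
    # two-point grid so the first replicate can check late-time drift
    check_grid = np.array(
        [max(config.start_time, config.stop_time - config.readout_interval), config.stop_time]
    )
    endpoint_grid = np.array([config.stop_time])
    for r in range(n):
        engine.reset(rng=rngs[r])
        if picks is None:
            picks = [engine.species.index(name) for name in names]
        grid = check_grid if r == 0 else endpoint_grid
        counts = engine.run(grid, config.stop_time)
        if r == 0:
            _warn_if_drifting(counts, picks)
        values[:, r] = counts[-1][picks]
    columns = [f"s{r + 1}" for r in range(n)]
    return ExpressionMatrix(
        genes=labels,
        columns=columns,
        values=values,
        kind="ensemble",
        metadata=_config_echo(config, "ensemble"),
    )


def _warn_if_drifting(counts: np.ndarray, picks: list[int]) -> None:
    before, after = counts[0][picks].sum(), counts[-1][picks].sum()
    reference = max(before, after)
    if reference > 0 and abs(int(after) - int(before)) > 0.2 * reference:
        logger.warning(
            "last two readout snapshots differ by >20%% in total count "
            "(%d -> %d); the ensemble endpoint may not be at steady state",
            before,
            after,
        )


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: str = "tsv",
    *,
    sidecar: bool = False,
) -> None:
    """Write the matrix as TSV/CSV (header = column labels, first column = gene ids).

    With ``sidecar=True`` a ``<path>.json`` provenance file echoing the run
    configuration is written next to it.
    """
    if format not in MATRIX_FORMATS:
        raise ValueError(f"format must be one of {MATRIX_FORMATS}, got {format!r}")
    path = Path(path)
    sep = "\t" if format == "tsv" else ","
    matrix.to_dataframe().to_csv(path, sep=sep)
    if sidecar:
        payload = {"kind": matrix.kind, "genes": len(matrix.genes), **matrix.metadata}
        Path(str(path) + ".json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_matrix(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    if format not in MATRIX_FORMATS:
        raise ValueError(f"format must be one of {MATRIX_FORMATS}, got {format!r}")
    sep = "\t" if format == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if frame.size:
        values = frame.to_numpy(dtype=np.int64)
    else:
        values = np.empty((len(frame.index), len(frame.columns)), dtype=np.int64)
    return ExpressionMatrix(
        genes=[str(g) for g in frame.index],
        columns=[str(c) for c in frame.columns],
        values=values,
    )
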