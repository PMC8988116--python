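"""Score an assembled read ordering against the simulated ground truth.

An edge of the ordering is *correct* when its two reads genuinely overlap on
the source.  For a circular source the closing edge (last read back to the
first) is scored too, since on a circle the true ordering is itself a closed
chain; with that convention a perfect ordering of n reads recovers all n true
consecutive adjacencies and scores accuracy 1.0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

from .contigs import Contig, breakpoint_count
from .overlap import CostMatrix
from .simdata import GroundTruthLayout


@dataclass
class EvaluationReport:
    path_cost: int
    real_contig_breaks: int
    calculated_contig_breaks: int
    correct_overlaps: int
    incorrect_overlaps: int
    accuracy: float | None
    n_true_adjacent_edges: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        return cls(**json.loads(Path(path).read_text()))


def _path_edges(path_read_ids: Sequence[str], circular: bool) -> list[tuple[str, str]]:
    edges = list(zip(path_read_ids, path_read_ids[1:]))
    if circular and len(path_read_ids) > 1:
        edges.append((path_read_ids[-1], path_read_ids[0]))
    return edges


def classify_edges(
    path_read_ids: Sequence[str], truth: GroundTruthLayout
) -> tuple[int, int, int]:
    """Count (correct, incorrect, real_breaks) over the ordering's edges.

    ``real_breaks`` equals the incorrect count: every junction between reads
    that do not truly overlap is a break the downstream split should find.
    """
    known = {r.read_id for r in truth.reads}
    for rid in path_read_ids:
        if rid not in known:
            raise ValueError(f"read id {rid!r} not present in ground truth")
    correct = incorrect = 0
    for a, b in _path_edges(path_read_ids, truth.circular):
        if truth.is_adjacent(a, b):
            correct += 1
        else:
            incorrect += 1
    return correct, incorrect, incorrect


def true_chain_edge_count(truth: GroundTruthLayout) -> int:
    """Number of consecutive true adjacencies along the source ordering.

    Reads are sorted by true start; each pair of consecutive reads (wrapping
    if circular) that genuinely overlaps contributes one edge.  This is the
    maximum number of correct edges any single ordering can recover.
    """
    ordered = sorted(truth.reads, key=lambda r: (r.true_start, r.read_id))
    ids = [r.read_id for r in ordered]
    return sum(truth.is_adjacent(a, b) for a, b in _path_edges(ids, truth.circular))


def accuracy(correct: int, incorrect: int, n_true_adjacent_edges: int) -> float | None:
    """Fraction of the true adjacency chain recovered, capped at 1.0.

    Returns None when there are no true adjacent edges to recover.
    """
    if min(correct, incorrect, n_true_adjacent_edges) < 0:
        raise ValueError("counts must be non-negative")
    if n_true_adjacent_edges == 0:
        return None
    return min(correct / n_true_adjacent_edges, 1.0)


def report(
    path_read_ids: Sequence[str],
    contigs: Sequence[Contig],
    cost_matrix: CostMatrix,
    truth: GroundTruthLayout,
    path_cost: int | None = None,
) -> EvaluationReport:
    """Assemble one results row: cost, break counts, overlap counts, accuracy."""
    if path_cost is None:
        path_cost = sum(
            cost_matrix.edge_cost(a, b)
            for a, b in zip(path_read_ids, path_read_ids[1:])
        )
    correct, incorrect, real_breaks = classify_edges(path_read_ids, truth)
    n_true = true_chain_edge_count(truth)
    return EvaluationReport(
        path_cost=int(path_cost),
        real_contig_breaks=real_breaks,
        calculated_contig_breaks=breakpoint_count(contigs),
        correct_overlaps=correct,
        incorrect_overlaps=incorrect,
        accuracy=accuracy(correct, incorrect, n_true),
        n_true_adjacent_edges=n_true,
    )
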