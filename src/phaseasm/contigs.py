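"""Split a read ordering into contigs wherever the joining cost looks like a break.

The threshold comes from the sequencing coverage: with mean depth COV, a read
should genuinely overlap about COV - 1 other reads, so per read the
(COV - 1)-th smallest off-diagonal cost marks the edge of its true
neighbourhood.  The global threshold is a quantile (default: median) of these
per-read values, times a safety factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .overlap import CostMatrix


@dataclass
class Contig:
    """An ordered run of reads, each consecutive pair asserted overlapping."""

    contig_id: str
    read_ids: list[str]

    def __len__(self) -> int:
        return len(self.read_ids)


@dataclass
class SplitConfig:
    coverage: float
    threshold: float | None = None  # explicit cutoff overrides the coverage rule
    quantile: float = 0.5
    safety: float = 1.0

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def coverage_threshold(
    cost: CostMatrix,
    coverage: float,
    quantile: float = 0.5,
    safety: float = 1.0,
) -> float:
    """Cost cutoff below which an edge is considered a genuine overlap.

    Per read, take the (COV - 1)-th smallest cost to any other read; pool
    those over all reads and return the requested quantile scaled by
    ``safety``.  Needs COV >= 2 (with fewer, there is no neighbour count to
    anchor on and an explicit threshold must be supplied).
    """
    if coverage < 2:
        raise ValueError("coverage must be >= 2 for the coverage-derived threshold")
    c = cost.cost[1:, 1:]  # read-read block
    n = c.shape[0]
    k = min(int(round(coverage)) - 1, n - 1)
    per_read = []
    for i in range(n):
        row = np.sort(np.delete(c[i], i))
        per_read.append(row[k - 1])
    return float(np.quantile(per_read, quantile) * safety)


def split_path(
    path_read_ids: Sequence[str],
    cost: CostMatrix,
    cfg: SplitConfig,
) -> list[Contig]:
    """Cut the ordering at every edge whose cost exceeds the threshold."""
    if not path_read_ids:
        return []
    if cfg.threshold is not None:
        threshold = cfg.threshold
    else:
        threshold = coverage_threshold(cost, cfg.coverage, cfg.quantile, cfg.safety)
    contigs: list[list[str]] = [[path_read_ids[0]]]
    for prev, cur in zip(path_read_ids, path_read_ids[1:]):
        if cost.edge_cost(prev, cur) > threshold:
            contigs.append([cur])
        else:
            contigs[-1].append(cur)
    return [Contig(contig_id=f"contig_{k}", read_ids=ids) for k, ids in enumerate(contigs)]


def breakpoint_count(contigs: Sequence[Contig]) -> int:
    """Number of cuts made; 0 for a single perfect contig."""
    return max(len(contigs) - 1, 0)


def contigs_to_tsv(contigs: Sequence[Contig], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("contig_id\trank\tread_id\n")
        for contig in contigs:
            for rank, rid in enumerate(contig.read_ids):
                fh.write(f"{contig.contig_id}\t{rank}\t{rid}\n")


def contigs_from_tsv(path: str | Path) -> list[Contig]:
    order: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig_id"):
            raise ValueError(f"unexpected contig TSV header: {header!r}")
        for line in fh:
            cid, _rank, rid = line.rstrip("\n").split("\t")
            order.setdefault(cid, []).append(rid)
    return [Contig(contig_id=cid, read_ids=ids) for cid, ids in order.items()]
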