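"""Pairwise max-shift Pearson correlation of phase signals and the TSP cost matrix.

For every pair of reads the two cumulated-phase signals are slid against each
other; for each shift the Pearson coefficient of the overlapping windows is
computed, and the maximum over shifts goes into the overlap matrix.  The
overlap matrix is then turned into a symmetric integer cost matrix with an
artificial zero-cost vertex at index 0, which is what the TSP solvers consume.

The per-shift sweep is evaluated in O(L log L) per pair: the cross products
for all shifts come from one FFT cross-correlation and the window moments
from prefix sums.  A naive per-shift implementation is kept as an
independent oracle for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _spsignal

from .encoding import encode_cumulated_phase
from .simdata import Read

DEPOT_ID = "@depot"
DEFAULT_MIN_OVERLAP = 100
DEFAULT_SCALE_MAX = 1000


@dataclass
class OverlapMatrix:
    """Symmetric matrix of maximum sliding-window Pearson coefficients.

    ``best_shift[i, j]`` is the signed shift at which the maximum was
    attained: positive s means read j starts s positions into read i.
    """

    read_ids: list[str]
    rho: np.ndarray
    best_shift: np.ndarray

    @property
    def n(self) -> int:
        return len(self.read_ids)


@dataclass
class CostMatrix:
    """(N+1) x (N+1) integer cost matrix; vertex 0 is the artificial depot."""

    read_ids: list[str]
    cost: np.ndarray

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def index_of(self, read_id: str) -> int:
        """Vertex index (1-based; 0 is the depot) of a read."""
        return self.read_ids.index(read_id) + 1

    def edge_cost(self, id_a: str, id_b: str) -> int:
        return int(self.cost[self.index_of(id_a), self.index_of(id_b)])


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of two equal-length windows.

    Zero variance in either window yields 0.0 (no evidence of relation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("windows must have equal length")
    if x.size < 2:
        raise ValueError("windows must have length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float((xc @ yc) / denom)


def _shift_range(la: int, lb: int, min_overlap: int) -> tuple[int, int]:
    # shift s: read B starts s positions into read A; overlap n(s) must be >= min_overlap
    return -(lb - min_overlap), la - min_overlap


def sliding_pearson(sig_a: np.ndarray, sig_b: np.ndarray, min_overlap: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson coefficient of the overlapping windows at every admissible shift.

    Returns ``(shifts, rho)`` where ``shifts`` runs from ``-(len_b - min_overlap)``
    to ``len_a - min_overlap`` inclusive.  Zero-variance windows get rho 0.
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    la, lb = a.size, b.size
    if min_overlap < 2:
        raise ValueError("min_overlap must be >= 2")
    if min(la, lb) < min_overlap:
        raise ValueError(
            f"min_overlap={min_overlap} exceeds a signal length ({la}, {lb})"
        )
    # Pearson is invariant to an additive constant on either full signal;
    # centring shrinks magnitudes and improves FFT conditioning.
    a = a - a.mean()
    b = b - b.mean()

    lo, hi = _shift_range(la, lb, min_overlap)
    shifts = np.arange(lo, hi + 1)

    # cross-products for all lags: c[s + lb - 1] = sum_n a[n] * b[n - s]
    cross = _spsignal.correlate(a, b, mode="full", method="auto")
    sxy = cross[shifts + lb - 1]

    pa = np.concatenate(([0.0], np.cumsum(a)))
    pa2 = np.concatenate(([0.0], np.cumsum(a * a)))
    pb = np.concatenate(([0.0], np.cumsum(b)))
    pb2 = np.concatenate(([0.0], np.cumsum(b * b)))

    a0 = np.maximum(0, shifts)
    a1 = np.minimum(la, shifts + lb)
    n = (a1 - a0).astype(float)
    b0, b1 = a0 - shifts, a1 - shifts

    sx = pa[a1] - pa[a0]
    sxx = pa2[a1] - pa2[a0]
    sy = pb[b1] - pb[b0]
    syy = pb2[b1] - pb2[b0]

    num = n * sxy - sx * sy
    var_x = n * sxx - sx * sx
    var_y = n * syy - sy * sy
    denom = np.sqrt(np.maximum(var_x, 0.0) * np.maximum(var_y, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0.0, num / denom, 0.0)
    return shifts, np.clip(rho, -1.0, 1.0)


def sliding_pearson_naive(sig_a: np.ndarray, sig_b: np.ndarray, min_overlap: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-shift direct evaluation; the independent oracle for :func:`sliding_pearson`."""
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    la, lb = a.size, b.size
    lo, hi = _shift_range(la, lb, min_overlap)
    shifts = np.arange(lo, hi + 1)
    rho = np.empty(shifts.size)
    for k, s in enumerate(shifts):
        a0, a1 = max(0, s), min(la, s + lb)
        rho[k] = pearson(a[a0:a1], b[a0 - s : a1 - s])
    return shifts, rho


def max_shift_correlation(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    stride: int = 1,
) -> tuple[float, int]:
    """Maximum Pearson coefficient over all admissible shifts, and its shift.

    With ``stride > 1`` only every stride-th shift is considered initially
    and the best candidate is refined exhaustively within +-(stride-1).
    """
    shifts, rho = sliding_pearson(sig_a, sig_b, min_overlap)
    if stride > 1:
        coarse = np.arange(0, shifts.size, stride)
        k = coarse[int(np.argmax(rho[coarse]))]
        lo = max(0, k - stride + 1)
        hi = min(shifts.size, k + stride)
        k = lo + int(np.argmax(rho[lo:hi]))
    else:
        k = int(np.argmax(rho))
    return float(rho[k]), int(shifts[k])


def build_overlap_matrix(
    reads: Sequence[Read],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    stride: int = 1,
) -> OverlapMatrix:
    """Max-shift correlation for every unordered read pair (diagonal = 1)."""
    if len(reads) < 2:
        raise ValueError("need at least 2 reads")
    ids = [r.read_id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("read ids must be unique")
    signals = []
    for r in reads:
        try:
            signals.append(encode_cumulated_phase(r.sequence))
        except ValueError as exc:
            raise ValueError(f"read {r.read_id!r}: {exc}") from exc
    n = len(reads)
    rho = np.eye(n)
    shift = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            r, s = max_shift_correlation(signals[i], signals[j], min_overlap, stride)
            rho[i, j] = rho[j, i] = r
            shift[i, j] = s
            shift[j, i] = -s
    return OverlapMatrix(read_ids=ids, rho=rho, best_shift=shift)


def intermediate_cost(rho: float | np.ndarray) -> float | np.ndarray:
    """Rescaled cost before the min-max step: subtract from 1, multiply by 1000."""
    return (1.0 - rho) * 1000.0


def to_cost_matrix(om: OverlapMatrix, scale_max: int = DEFAULT_SCALE_MAX) -> CostMatrix:
    """Derive the integer TSP cost matrix with the artificial vertex at index 0.

    Off-diagonal correlations are rescaled as ``(1 - rho) * 1000``, then
    min-max scaled over the off-diagonal entries to ``[0, scale_max]`` and
    rounded half-up to integers.  The artificial vertex has zero cost to and
    from every read, and the diagonal is zero.
    """
    n = om.n
    v = intermediate_cost(om.rho)
    off = ~np.eye(n, dtype=bool)
    vmin, vmax = v[off].min(), v[off].max()
    if vmax == vmin:
        warnings.warn("all off-diagonal costs identical; scaling them all to 0", stacklevel=2)
        scaled = np.zeros((n, n))
    else:
        scaled = (v - vmin) / (vmax - vmin) * scale_max
    cost = np.zeros((n + 1, n + 1), dtype=np.int64)
    cost[1:, 1:] = np.floor(scaled + 0.5).astype(np.int64)  # round half-up
    np.fill_diagonal(cost, 0)
    return CostMatrix(read_ids=list(om.read_ids), cost=cost)


# ---------------------------------------------------------------------------
# TSV serialisation
# ---------------------------------------------------------------------------

def overlap_matrix_to_tsv(om: OverlapMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(["rho"] + om.read_ids) + "\n")
        for rid, row in zip(om.read_ids, om.rho):
            fh.write(rid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def cost_matrix_to_tsv(cm: CostMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = [DEPOT_ID] + cm.read_ids
    with open(path, "w") as fh:
        fh.write("\t".join(["cost"] + labels) + "\n")
        for label, row in zip(labels, cm.cost):
            fh.write(label + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def cost_matrix_from_tsv(path: str | Path) -> CostMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "cost" or header[1] != DEPOT_ID:
            raise ValueError(f"not a cost-matrix TSV: {path}")
        ids = header[2:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([int(v) for v in parts[1:]])
    cost = np.array(rows, dtype=np.int64)
    if cost.shape != (len(ids) + 1, len(ids) + 1):
        raise ValueError(f"cost matrix shape {cost.shape} inconsistent with {len(ids)} reads")
    return CostMatrix(read_ids=ids, cost=cost)
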