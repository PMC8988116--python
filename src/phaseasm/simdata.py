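"""Synthetic read-set generation with ground truth, plus FASTA/TSV/JSON I/O.

A random circular source sequence is tiled with fixed-length reads at a
prescribed consecutive overlap, then optionally corrupted with point
mutations (insertion, deletion, substitution, duplication).  The ground
truth (true start of every read and the set of genuinely overlapping read
pairs) is kept alongside so downstream ordering can be scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"

# IUPAC ambiguity codes -> concrete candidate bases (used by iupac_to_random)
_IUPAC = {
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

MUTATION_OPERATORS = ("insertion", "deletion", "substitution", "duplication")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class SourceSequence:
    """A source DNA sequence, circular by default."""

    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("source sequence must have length >= 1")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"source sequence contains non-ACGT symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Read:
    """A single read; ``true_start`` is set for simulated reads only."""

    read_id: str
    sequence: str
    true_start: int | None = None
    pre_mutation_length: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GroundTruthLayout:
    """Reads with known origins plus the derived true-overlap pair set.

    ``adjacency`` maps a sorted ``(read_id, read_id)`` tuple to the number
    of bases the two reads share on the (circular) source.
    """

    reads: list[Read]
    source_length: int
    circular: bool = True
    adjacency: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def true_adjacencies(self) -> set[tuple[str, str]]:
        return set(self.adjacency)

    def read_by_id(self, read_id: str) -> Read:
        for r in self.reads:
            if r.read_id == read_id:
                return r
        raise KeyError(read_id)

    def is_adjacent(self, id_a: str, id_b: str) -> bool:
        return tuple(sorted((id_a, id_b))) in self.adjacency


@dataclass(frozen=True)
class MutationSpec:
    """How many point mutations to apply per read and with which operators."""

    error_pct: float
    operator_weights: Mapping[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.error_pct < 0:
            raise ValueError("error_pct must be >= 0")
        if self.error_pct > 1.5:
            warnings.warn(
                f"error_pct={self.error_pct} exceeds the 1.5% regime the method assumes",
                stacklevel=2,
            )
        w = self.weights
        if any(v < 0 for v in w.values()):
            raise ValueError("operator weights must be non-negative")
        if sum(w.values()) <= 0:
            raise ValueError("operator weights must not all be zero")
        unknown = set(w) - set(MUTATION_OPERATORS)
        if unknown:
            raise ValueError(f"unknown mutation operators: {sorted(unknown)}")

    @property
    def weights(self) -> dict[str, float]:
        if self.operator_weights is None:
            return {op: 1.0 for op in MUTATION_OPERATORS}
        return dict(self.operator_weights)


def generate_source(length: int, seed: int | None = None) -> SourceSequence:
    """Generate a uniform random circular DNA sequence.

    Parameters
    ----------
    length : int
        Number of bases, >= 1.
    seed : int, optional
        Seed for reproducibility.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    bases = rng.choice(list(ALPHABET), size=length)
    return SourceSequence("".join(bases), circular=True)


def circular_overlap(start_a: int, len_a: int, start_b: int, len_b: int, L: int) -> int:
    """Number of source positions covered by both reads on a circle of size ``L``.

    Intervals are ``[start, start+len)`` taken modulo ``L``.  When the two
    arcs intersect on both sides of the circle the overlap of both parts is
    counted.
    """
    a, b = start_a % L, start_b % L
    if a == b:
        return min(len_a, len_b, L)
    d_ab = (b - a) % L  # distance forward from a to b
    d_ba = (a - b) % L
    ov = max(0, min(len_a, L) - d_ab) + max(0, min(len_b, L) - d_ba)
    return min(ov, min(len_a, len_b, L))


def _layout_adjacency(reads: Sequence[Read], L: int) -> dict[tuple[str, str], int]:
    adj: dict[tuple[str, str], int] = {}
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            ri, rj = reads[i], reads[j]
            ov = circular_overlap(
                ri.true_start, ri.pre_mutation_length, rj.true_start, rj.pre_mutation_length, L
            )
            if ov > 0:
                adj[tuple(sorted((ri.read_id, rj.read_id)))] = ov
    return adj


def extract_reads(
    src: SourceSequence, n_reads: int, read_len: int, overlap: int
) -> GroundTruthLayout:
    """Tile the circular source with evenly spaced fixed-length reads.

    Consecutive reads start ``read_len - overlap`` bases apart, wrapping
    around the source end.  Every read records its true start, and all read
    pairs whose source intervals intersect are recorded as true adjacencies.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= overlap < read_len:
        raise ValueError(f"need read_len > overlap >= 0, got read_len={read_len} overlap={overlap}")
    L = src.length
    step = read_len - overlap
    if (n_reads * step) % L != 0:
        warnings.warn(
            f"n_reads*step = {n_reads * step} does not tile the source of length {L}; "
            "the layout wraps with a residual mismatch",
            stacklevel=2,
        )
    # Enough copies of the source that any read window is a plain slice.
    doubled = src.sequence * (read_len // L + 2)
    width = len(str(n_reads - 1))
    reads = []
    for i in range(n_reads):
        start = (i * step) % L
        reads.append(
            Read(
                read_id=f"read_{i:0{width}d}",
                sequence=doubled[start : start + read_len],
                true_start=start,
                pre_mutation_length=read_len,
            )
        )
    return GroundTruthLayout(
        reads=reads,
        source_length=L,
        circular=src.circular,
        adjacency=_layout_adjacency(reads, L),
    )


def _mutate_sequence(seq: str, n_events: int, weights: dict[str, float], rng: np.random.Generator) -> str:
    ops = list(weights)
    p = np.array([weights[o] for o in ops], dtype=float)
    p /= p.sum()
    chars = list(seq)
    for _ in range(n_events):
        op = ops[rng.choice(len(ops), p=p)]
        if op == "deletion" and len(chars) <= 1:
            op = "substitution"  # never delete a read away entirely
        pos = int(rng.integers(len(chars)))
        if op == "substitution":
            alternatives = [b for b in ALPHABET if b != chars[pos]]
            chars[pos] = alternatives[int(rng.integers(3))]
        elif op == "insertion":
            chars.insert(pos, ALPHABET[int(rng.integers(4))])
        elif op == "deletion":
            del chars[pos]
        elif op == "duplication":
            chars.insert(pos, chars[pos])
    return "".join(chars)


def mutate_reads(layout: GroundTruthLayout, spec: MutationSpec) -> GroundTruthLayout:
    """Apply point mutations to each read; ground truth is unchanged.

    The number of events per read is ``round(error_pct/100 * pre-mutation
    length)``.  Mutations do not move reads, so true starts and the
    adjacency set carry over verbatim.

    Each read draws from its own seeded stream, so for a fixed seed a higher
    error percentage applies a superset of the events of a lower one
    (corruption levels are nested, which makes degradation comparisons
    paired rather than independently noisy).
    """
    base = spec.seed if isinstance(spec.seed, np.random.SeedSequence) else np.random.SeedSequence(spec.seed)
    per_read = base.spawn(len(layout.reads))
    weights = spec.weights
    new_reads = []
    for r, child in zip(layout.reads, per_read):
        n_events = int(round(spec.error_pct / 100.0 * len(r.sequence)))
        seq = (
            _mutate_sequence(r.sequence, n_events, weights, np.random.default_rng(child))
            if n_events
            else r.sequence
        )
        new_reads.append(replace(r, sequence=seq))
    return GroundTruthLayout(
        reads=new_reads,
        source_length=layout.source_length,
        circular=layout.circular,
        adjacency=dict(layout.adjacency),
    )


def simulate_dataset(
    length: int,
    n_reads: int,
    read_len: int,
    overlap: int,
    error_pct: float = 0.0,
    seed: int | None = None,
    operator_weights: Mapping[str, float] | None = None,
) -> GroundTruthLayout:
    """Convenience wrapper: source -> tiling -> mutations, all from one seed."""
    ss = np.random.SeedSequence(seed)
    src_seed, mut_seed = ss.spawn(2)
    src = generate_source(length, seed=src_seed)
    layout = extract_reads(src, n_reads=n_reads, read_len=read_len, overlap=overlap)
    if error_pct > 0:
        layout = mutate_reads(layout, MutationSpec(error_pct, operator_weights, seed=mut_seed))
    return layout


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path,
    strict: bool = True,
    iupac_to_random: bool = False,
    seed: int | None = None,
) -> list[Read]:
    """Read a FASTA file into ``Read`` records (sequences upper-cased).

    With ``strict`` (default) any non-ACGT symbol raises ``FastaParseError``
    naming the offending record.  With ``iupac_to_random`` ambiguity codes
    are resolved to a random concrete base (seeded).
    """
    rng = np.random.default_rng(seed)
    reads = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FastaParseError(f"cannot parse FASTA file {path}: {exc}") from exc
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - set(ALPHABET)
        if bad:
            if iupac_to_random and bad <= set(_IUPAC):
                seq = "".join(
                    b if b in ALPHABET else _IUPAC[b][int(rng.integers(len(_IUPAC[b])))]
                    for b in seq
                )
            elif strict:
                raise FastaParseError(
                    f"record {rec.id!r} contains non-ACGT symbols: {sorted(bad)}"
                )
        reads.append(Read(read_id=rec.id, sequence=seq))
    return reads


def write_fasta(reads: Iterable[Read], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_truth(layout: GroundTruthLayout, tsv_path: str | Path, adjacency_path: str | Path) -> None:
    """Ground truth as a TSV (read_id, true_start, length) + JSON adjacency list."""
    tsv_path, adjacency_path = Path(tsv_path), Path(adjacency_path)
    tsv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(tsv_path, "w") as fh:
        fh.write("read_id\ttrue_start\tlength\n")
        for r in layout.reads:
            fh.write(f"{r.read_id}\t{r.true_start}\t{r.pre_mutation_length}\n")
    payload = {
        "source_length": layout.source_length,
        "circular": layout.circular,
        "adjacencies": [[a, b, ov] for (a, b), ov in sorted(layout.adjacency.items())],
    }
    with open(adjacency_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(
    tsv_path: str | Path, adjacency_path: str | Path, reads: Sequence[Read] | None = None
) -> GroundTruthLayout:
    """Load ground truth written by :func:`write_truth`.

    If ``reads`` is given (e.g. loaded from the accompanying FASTA) their
    sequences are attached; otherwise sequences are left empty.
    """
    by_id = {r.read_id: r for r in reads} if reads else {}
    loaded: list[Read] = []
    with open(tsv_path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"unexpected truth TSV header in {tsv_path}: {header!r}")
        for line in fh:
            rid, start, length = line.rstrip("\n").split("\t")
            seq = by_id[rid].sequence if rid in by_id else ""
            loaded.append(Read(rid, seq, true_start=int(start), pre_mutation_length=int(length)))
    with open(adjacency_path) as fh:
        payload = json.load(fh)
    adjacency = {tuple(sorted((a, b))): int(ov) for a, b, ov in payload["adjacencies"]}
    return GroundTruthLayout(
        reads=loaded,
        source_length=int(payload["source_length"]),
        circular=bool(payload["circular"]),
        adjacency=adjacency,
    )
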