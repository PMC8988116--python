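"""End-to-end orchestration: simulate -> overlap -> order -> contigs -> evaluate."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .contigs import SplitConfig, contigs_to_tsv, split_path
from .evaluate import EvaluationReport, report
from .overlap import (
    build_overlap_matrix,
    cost_matrix_to_tsv,
    overlap_matrix_to_tsv,
    to_cost_matrix,
)
from .simdata import simulate_dataset, write_fasta, write_truth
from .tsp_classic import solve_classic
from .tsp_qubo import solve_hybrid


@dataclass
class PipelineConfig:
    """Every knob of a full run; identical config + seed => identical artifacts
    (the annealing solver reports its best-of-n_experiments, also seeded)."""

    length: int = 15000
    n_reads: int = 50
    read_len: int = 3000
    overlap: int = 2700
    error_pct: float = 0.0
    seed: int = 0
    min_overlap: int = 100
    stride: int = 1
    solver: str = "classic"  # "classic" | "qubo-sa"
    a1: float = 1.0
    a2: float = 1e7
    max_cluster: int = 7
    sa_sweeps: int = 1000
    sa_restarts: int = 10
    n_experiments: int = 5
    coverage: float | None = None  # defaults to n_reads*read_len/length
    threshold: float | None = None
    quantile: float = 0.5
    safety: float = 1.0
    extra: dict = field(default_factory=dict)

    @property
    def effective_coverage(self) -> float:
        if self.coverage is not None:
            return self.coverage
        return self.n_reads * self.read_len / self.length

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    layout: object
    cost_matrix: object
    solution: object
    contigs: list
    report: EvaluationReport


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage; when ``out_dir`` is given, write all artifacts there."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        meta = {"config": asdict(cfg), "config_hash": cfg.config_hash(), "version": __version__}
        (out / "run_meta.json").write_text(json.dumps(meta, indent=1, default=str))

    layout = simulate_dataset(
        length=cfg.length, n_reads=cfg.n_reads, read_len=cfg.read_len,
        overlap=cfg.overlap, error_pct=cfg.error_pct, seed=cfg.seed,
    )
    if out is not None:
        write_fasta(layout.reads, out / "reads.fasta")
        write_truth(layout, out / "truth.tsv", out / "adjacency.json")

    om = build_overlap_matrix(layout.reads, min_overlap=cfg.min_overlap, stride=cfg.stride)
    cm = to_cost_matrix(om)
    if out is not None:
        overlap_matrix_to_tsv(om, out / "rho.tsv")
        cost_matrix_to_tsv(cm, out / "cost.tsv")

    if cfg.solver == "classic":
        sol = solve_classic(cm)
    elif cfg.solver == "qubo-sa":
        sol = solve_hybrid(
            cm, max_cluster=cfg.max_cluster, seed=cfg.seed, a1=cfg.a1, a2=cfg.a2,
            n_sweeps=cfg.sa_sweeps, n_restarts=cfg.sa_restarts,
            n_experiments=cfg.n_experiments,
        )
    else:
        raise ValueError(f"unknown solver {cfg.solver!r}")
    order = sol.read_order(cm)
    if out is not None:
        (out / "path.json").write_text(json.dumps({
            "cycle": sol.cycle, "cost": sol.cost, "read_order": order, "meta": sol.meta,
        }, indent=1, default=str))

    split_cfg = SplitConfig(
        coverage=max(cfg.effective_coverage, 1.0), threshold=cfg.threshold,
        quantile=cfg.quantile, safety=cfg.safety,
    )
    contig_list = split_path(order, cm, split_cfg)
    if out is not None:
        contigs_to_tsv(contig_list, out / "contigs.tsv")

    rep = report(order, contig_list, cm, layout, path_cost=sol.cost)
    if out is not None:
        rep.to_json(out / "report.json")

    return PipelineResult(
        config=cfg, layout=layout, cost_matrix=cm,
        solution=sol, contigs=contig_list, report=rep,
    )
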