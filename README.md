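# phaseasm

Proof-of-concept read-ordering pipeline for de novo assembly experiments:

1. **simulate** — generate a random circular DNA source, tile it with
   fixed-length reads at a prescribed overlap, and optionally corrupt them
   with point mutations (insertion / deletion / substitution / duplication),
   keeping full ground truth.
2. **encode** — map each read to its cumulated-phase signal
   (A: 1+j, C: −1−j, G: −1+j, T: 1−j; arguments accumulated along the read).
3. **overlap** — for every read pair, slide the two signals against each
   other and record the maximum windowed Pearson correlation
   (FFT + prefix-sum implementation, with a naive per-shift oracle kept for
   testing); convert the correlation matrix to an integer cost matrix
   ((1−ρ)·1000, min–max scaled) with an artificial zero-cost start vertex.
4. **order** — solve the resulting TSP either with a classical heuristic
   (nearest neighbour + 2-opt + or-opt) or with a QUBO formulation sampled
   by simulated annealing; instances above the direct-embedding size are
   decomposed by density-based clustering on the cost matrix and the
   per-cluster sub-tours merged at cheapest junctions.
5. **contigs** — split the tour into contigs wherever an edge cost exceeds a
   coverage-derived threshold (per read, the (COV−1)-th smallest cost).
6. **evaluate** — score an ordering against the ground truth: path cost,
   correct/incorrect overlap counts, contig breakpoints, accuracy.

## CLI

Every stage is a subcommand operating on plain-text artifacts
(FASTA, TSV matrices, JSON paths/reports):

```bash
phaseasm simulate --length 15000 --n-reads 50 --read-len 3000 \
    --overlap 2700 --error-pct 0.5 --seed 1 --out-dir run/
phaseasm overlap  --reads run/reads.fasta --out run/rho.tsv --cost-out run/cost.tsv
phaseasm order    --matrix run/cost.tsv --solver classic --out run/path.json
phaseasm contigs  --path run/path.json --matrix run/cost.tsv --coverage 10 \
    --out run/contigs.tsv
phaseasm evaluate --path run/path.json --contigs run/contigs.tsv \
    --matrix run/cost.tsv --truth run/truth.tsv --adjacency run/adjacency.json

# or everything at once:
phaseasm run-all --length 15000 --overlap 2700 --seed 1 --out-dir run/
```

`--solver qubo-sa` switches the ordering stage to the QUBO /
simulated-annealing path (`--max-cluster` caps the direct-solve size).

## Layout

```
src/phaseasm/
  simdata.py     synthetic datasets, ground truth, FASTA/TSV/JSON I/O
  encoding.py    cumulated-phase signal encoding
  overlap.py     sliding Pearson correlation, cost matrix
  tsp_classic.py nearest-neighbour + 2-opt/or-opt heuristic
  tsp_qubo.py    QUBO build, simulated annealing, decomposition hybrid
  contigs.py     coverage-threshold path splitting
  evaluate.py    ground-truth scoring
  pipeline.py    end-to-end orchestration
  cli.py         click command group
```
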