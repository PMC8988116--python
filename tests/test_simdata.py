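import json

import numpy as np
import pytest

from phaseasm.simdata import (
    FastaParseError,
    MutationSpec,
    Read,
    circular_overlap,
    extract_reads,
    generate_source,
    mutate_reads,
    read_fasta,
    read_truth,
    simulate_dataset,
    write_fasta,
    write_truth,
)


class TestGenerateSource:
    def test_length_and_alphabet(self):
        src = generate_source(30000, seed=3)
        assert src.length == 30000
        assert set(src.sequence) <= set("ACGT")
        assert src.circular

    def test_single_base(self):
        assert generate_source(1, seed=0).length == 1

    def test_deterministic(self):
        assert generate_source(10000, seed=5).sequence == generate_source(10000, seed=5).sequence

    def test_roughly_uniform(self):
        seq = generate_source(40000, seed=1).sequence
        counts = np.array([seq.count(b) for b in "ACGT"])
        assert counts.min() > 0.22 * 40000  # ~binomial 5 sigma slack

    def test_nonpositive_length(self):
        with pytest.raises(ValueError):
            generate_source(0)


class TestCircularOverlap:
    # oracle: explicit position-set intersection on the circle
    @staticmethod
    def _oracle(a, la, b, lb, L):
        pa = {(a + k) % L for k in range(la)}
        pb = {(b + k) % L for k in range(lb)}
        return len(pa & pb)

    def test_against_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            L = int(rng.integers(10, 60))
            la, lb = int(rng.integers(1, L)), int(rng.integers(1, L))
            a, b = int(rng.integers(L)), int(rng.integers(L))
            assert circular_overlap(a, la, b, lb, L) == self._oracle(a, la, b, lb, L)


class TestExtractReads:
    def test_table_configuration(self):
        src = generate_source(30000, seed=2)
        layout = extract_reads(src, n_reads=50, read_len=3000, overlap=2400)
        assert len(layout.reads) == 50
        assert all(len(r.sequence) == 3000 for r in layout.reads)
        doubled = src.sequence * 2
        for r in layout.reads:
            assert doubled[r.true_start : r.true_start + 3000] == r.sequence
        # consecutive reads (step 600, overlap 2400) are all adjacent, circularly
        ids = [r.read_id for r in layout.reads]
        assert all(layout.is_adjacent(ids[i], ids[(i + 1) % 50]) for i in range(50))

    def test_adjacency_count_by_interval_arithmetic(self):
        src = generate_source(30000, seed=2)
        layout = extract_reads(src, n_reads=50, read_len=3000, overlap=2400)
        # step 600: read i overlaps i+1..i+4 on each side => 50*4/2... each pair
        # (i, i+d) with d in 1..4 overlaps by 3000 - 600d > 0; d=5 exactly abuts.
        assert len(layout.adjacency) == 50 * 4
        assert layout.adjacency[("read_00", "read_01")] == 2400
        assert layout.adjacency[("read_00", "read_04")] == 600

    @pytest.mark.filterwarnings("ignore:.*does not tile.*")
    def test_single_read(self):
        layout = extract_reads(generate_source(100, seed=0), 1, 40, 10)
        assert len(layout.reads) == 1 and layout.adjacency == {}

    def test_zero_overlap(self):
        layout = extract_reads(generate_source(400, seed=0), 4, 100, 0)
        ids = [r.read_id for r in layout.reads]
        assert not any(layout.is_adjacent(ids[i], ids[i + 1]) for i in range(3))

    def test_overlap_ge_read_len_rejected(self):
        with pytest.raises(ValueError):
            extract_reads(generate_source(100, seed=0), 4, 50, 50)

    def test_mismatched_tiling_warns(self):
        with pytest.warns(UserWarning, match="does not tile"):
            extract_reads(generate_source(30000, seed=0), 50, 3000, 2300)


class TestMutateReads:
    def _layout(self, seed=4):
        return extract_reads(generate_source(3000, seed=seed), 10, 600, 300)

    def test_zero_errors_identity(self):
        layout = self._layout()
        out = mutate_reads(layout, MutationSpec(0.0, seed=1))
        assert [r.sequence for r in out.reads] == [r.sequence for r in layout.reads]

    def test_event_count_via_substitutions(self):
        # substitution-only: each event changes exactly one base, so the
        # Hamming distance equals round(error_pct/100 * length)
        layout = self._layout()
        spec = MutationSpec(1.0, {"substitution": 1.0}, seed=9)
        out = mutate_reads(layout, spec)
        for before, after in zip(layout.reads, out.reads):
            assert len(after.sequence) == 600
            diff = sum(a != b for a, b in zip(before.sequence, after.sequence))
            assert diff == round(1.0 / 100 * 600) == 6

    def test_truth_unchanged(self):
        layout = self._layout()
        out = mutate_reads(layout, MutationSpec(1.5, seed=2))
        assert out.adjacency == layout.adjacency
        assert [r.true_start for r in out.reads] == [r.true_start for r in layout.reads]

    def test_deterministic(self):
        layout = self._layout()
        a = mutate_reads(layout, MutationSpec(1.0, seed=5))
        b = mutate_reads(layout, MutationSpec(1.0, seed=5))
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]

    def test_high_error_warns(self):
        with pytest.warns(UserWarning, match="1.5"):
            MutationSpec(5.0)

    def test_bad_weights(self):
        with pytest.raises(ValueError):
            MutationSpec(1.0, {"substitution": 0.0})
        with pytest.raises(ValueError):
            MutationSpec(1.0, {"inversion": 1.0})


class TestFastaIO:
    def test_round_trip(self, tmp_path):
        layout = simulate_dataset(3000, 10, 600, 300, seed=0)
        p = tmp_path / "reads.fasta"
        write_fasta(layout.reads, p)
        back = read_fasta(p)
        assert [r.read_id for r in back] == [r.read_id for r in layout.reads]
        assert [r.sequence for r in back] == [r.sequence for r in layout.reads]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_strict_rejects_n(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">r1\nACGNT\n")
        with pytest.raises(FastaParseError, match="r1"):
            read_fasta(p)

    def test_iupac_to_random(self, tmp_path):
        p = tmp_path / "amb.fasta"
        p.write_text(">r1\nACGNTR\n")
        reads = read_fasta(p, iupac_to_random=True, seed=0)
        assert len(reads[0].sequence) == 6
        assert set(reads[0].sequence) <= set("ACGT")
        assert reads[0].sequence[:3] == "ACG"

    def test_wrapped_and_lowercase(self, tmp_path):
        p = tmp_path / "wrap.fasta"
        p.write_text(">r1 desc\nacgt\nACGT\n")
        (r,) = read_fasta(p)
        assert r.sequence == "ACGTACGT"


class TestTruthIO:
    def test_round_trip(self, tmp_path):
        layout = simulate_dataset(3000, 10, 600, 300, seed=0)
        write_truth(layout, tmp_path / "truth.tsv", tmp_path / "adj.json")
        back = read_truth(tmp_path / "truth.tsv", tmp_path / "adj.json", reads=layout.reads)
        assert back.adjacency == layout.adjacency
        assert back.source_length == layout.source_length
        assert [r.true_start for r in back.reads] == [r.true_start for r in layout.reads]
        # adjacency file is valid JSON with sorted pairs
        payload = json.loads((tmp_path / "adj.json").read_text())
        assert all(a < b for a, b, _ in payload["adjacencies"])


class TestSimulateDataset:
    def test_coverage_identity(self):
        layout = simulate_dataset(30000, 50, 3000, 2400, seed=0)
        cov = len(layout.reads) * 3000 / layout.source_length
        assert cov == 5.0

    def test_seed_reproducibility(self):
        a = simulate_dataset(6000, 20, 600, 300, error_pct=1.0, seed=123)
        b = simulate_dataset(6000, 20, 600, 300, error_pct=1.0, seed=123)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]

    def test_error_free_reads_substrings_of_doubled_source(self):
        layout = simulate_dataset(3000, 10, 600, 300, seed=8)
        # reconstruct the source from read 0's true window is not possible here,
        # but every read must appear in every other overlapping read consistently
        for (a, b), ov in layout.adjacency.items():
            ra = layout.read_by_id(a)
            rb = layout.read_by_id(b)
            assert ov > 0
            assert ra.sequence != "" and rb.sequence != ""
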