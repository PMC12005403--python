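"""Alignment and assembly backends: the naive aligner against independent
oracles, threshold behaviour, and the external-adapter contracts."""

from __future__ import annotations

import numpy as np
import pytest

from magtrack.backends import (
    BackendError,
    CoverageAssembler,
    ExternalAligner,
    FixtureAssembler,
    MetaSpadesAssembler,
    Minimap2Aligner,
    NaiveAligner,
    Scaffold,
    align,
    align_naive,
    assemble,
    build_index,
    revcomp,
)
from magtrack.io_formats import ReadRecord, ReadSet
from magtrack.simulate import SyntheticCohortParams, generate_synthetic_cohort

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng, n):
    return BASES[rng.integers(0, 4, n)].tobytes().decode()


def _readset(seqs):
    return ReadSet("t", [ReadRecord(f"r{i}", s) for i, s in enumerate(seqs)])


@pytest.fixture(scope="module")
def scaffold_1kb(rng=np.random.default_rng(7)):
    return Scaffold("scaf1", _random_seq(np.random.default_rng(7), 1000))


@pytest.fixture(scope="module")
def db_1kb(scaffold_1kb):
    return build_index([scaffold_1kb], "donor")


class TestNaiveAligner:
    def test_exact_substring_aligns_at_full_identity(self, scaffold_1kb, db_1kb):
        reads = _readset([scaffold_1kb.sequence[200:300]])
        table = align_naive(reads, db_1kb, 1.0)
        hit = table.hits["r0"]
        assert hit.aligned and hit.identity == 1.0 and hit.scaffold_id == "scaf1"

    def test_one_mismatch_respects_threshold(self, scaffold_1kb, db_1kb):
        seq = list(scaffold_1kb.sequence[500:600])
        seq[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[50]]
        reads = _readset(["".join(seq)])
        assert not align_naive(reads, db_1kb, 1.0).hits["r0"].aligned
        hit = align_naive(reads, db_1kb, 0.98).hits["r0"]
        assert hit.aligned
        assert hit.identity == pytest.approx(0.99)

    def test_reverse_complement_read_aligns(self, scaffold_1kb, db_1kb):
        reads = _readset([revcomp(scaffold_1kb.sequence[100:200])])
        assert align_naive(reads, db_1kb, 1.0).hits["r0"].aligned

    def test_random_reads_do_not_align(self, db_1kb, rng):
        reads = _readset([_random_seq(rng, 100) for _ in range(1000)])
        table = align_naive(reads, db_1kb, 0.98)
        assert table.n_aligned == 0

    def test_n_only_read_is_unaligned_not_error(self, db_1kb):
        table = align_naive(_readset(["N" * 100]), db_1kb, 0.98)
        assert not table.hits["r0"].aligned

    def test_conservation(self, db_1kb, rng, scaffold_1kb):
        seqs = [_random_seq(rng, 100) for _ in range(50)]
        seqs += [scaffold_1kb.sequence[i : i + 100] for i in range(0, 500, 50)]
        table = align_naive(_readset(seqs), db_1kb, 1.0)
        assert table.n_aligned + table.n_unaligned == table.total_reads_queried == 60

    def test_threshold_monotonicity(self, noisy_bundle):
        """Lowering min_identity never unmaps a previously mapped read."""
        reads = noisy_bundle.reads.donor.subset(range(500))
        strict = align(reads, noisy_bundle.donor_db, 1.0)
        relaxed = align(reads, noisy_bundle.donor_db, 0.98)
        assert strict.aligned_ids() <= relaxed.aligned_ids()

    def test_self_alignment_rate_is_one_for_error_free_reads(self, small_bundle):
        reads = small_bundle.reads.donor.subset(range(500))
        table = align(reads, small_bundle.donor_db, 1.0)
        assert table.n_aligned == 500
        assert all(h.identity == 1.0 for h in table.hits.values())

    def test_seeded_path_matches_exhaustive_oracle(self, rng):
        """The pigeonhole-seeded aligner must equal a literal full scan."""
        scafs = [Scaffold(f"s{i}", _random_seq(rng, 400)) for i in range(3)]
        db = build_index(scafs, "donor")
        seqs = []
        for _ in range(40):
            si = int(rng.integers(0, 3))
            pos = int(rng.integers(0, 300))
            seq = list(scafs[si].sequence[pos : pos + 100])
            for j in rng.integers(0, 100, size=int(rng.integers(0, 4))):
                seq[j] = "ACGT"[int(rng.integers(0, 4))]
            seqs.append("".join(seq))
        seqs += [_random_seq(rng, 100) for _ in range(10)]
        reads = _readset(seqs)
        for identity in (1.0, 0.99, 0.98):
            fast = NaiveAligner().align(reads, db, identity)
            slow = NaiveAligner(exhaustive=True).align(reads, db, identity)
            for rid in reads.read_ids():
                f, s = fast.hits[rid], slow.hits[rid]
                assert (f.aligned, f.scaffold_id, f.identity) == (
                    s.aligned, s.scaffold_id, s.identity
                )

    def test_identity_threshold_nesting(self, noisy_bundle):
        """Aligned set at 1.00 is a subset of the aligned set at 0.98."""
        reads = noisy_bundle.reads.donor.subset(range(1000))
        at_100 = align(reads, noisy_bundle.donor_db, 1.00).aligned_ids()
        at_099 = align(reads, noisy_bundle.donor_db, 0.99).aligned_ids()
        at_098 = align(reads, noisy_bundle.donor_db, 0.98).aligned_ids()
        assert at_100 <= at_099 <= at_098

    def test_bad_identity_rejected(self, db_1kb):
        with pytest.raises(ValueError, match="min_identity"):
            align_naive(_readset(["ACGT" * 25]), db_1kb, 0.0)


class TestDatabase:
    def test_duplicate_scaffold_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_index([Scaffold("s", "ACGT"), Scaffold("s", "TTTT")])

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            build_index([])

    def test_deterministic_downstream(self, scaffold_1kb):
        reads = _readset([scaffold_1kb.sequence[i : i + 100] for i in range(0, 800, 80)])
        results = []
        for _ in range(2):
            db = build_index([scaffold_1kb], "donor")
            t = align_naive(reads, db, 1.0)
            results.append([(h.aligned, h.scaffold_id, h.identity) for h in t.hits.values()])
        assert results[0] == results[1]


class TestCrossBackend:
    def test_minimap2_agrees_with_naive_on_exact_reads(self, rng):
        """External and built-in aligners give the same aligned/unaligned
        partition for exact-match reads at identity 1.0."""
        genome = _random_seq(rng, 10_000)
        db = build_index([Scaffold("g", genome)], "donor")
        seqs = []
        for _ in range(250):
            pos = int(rng.integers(0, 10_000 - 150))
            s = genome[pos : pos + 150]
            seqs.append(s if rng.random() < 0.5 else revcomp(s))
        seqs += [_random_seq(rng, 150) for _ in range(250)]
        reads = _readset(seqs)
        naive = align_naive(reads, db, 1.0)
        external = Minimap2Aligner().align(reads, db, 1.0)
        assert naive.aligned_ids() == external.aligned_ids()

    def test_missing_executable_raises_backend_error(self, db_1kb):
        class Fake(ExternalAligner):
            executable = "definitely-not-a-real-aligner"

        with pytest.raises(BackendError, match="not found"):
            Fake().align(_readset(["ACGT" * 25]), db_1kb, 1.0)


class TestAssembly:
    def test_fixture_assembler_passthrough(self):
        scafs = [Scaffold(f"s{i}", "ACGT" * 100) for i in range(3)]
        reads = _readset(["ACGT" * 25])
        assert assemble(reads, FixtureAssembler(scafs)) == scafs

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assemble(ReadSet("s", []), FixtureAssembler([Scaffold("s", "A")]))

    def test_no_scaffolds_is_backend_error(self):
        with pytest.raises(BackendError, match="no scaffolds"):
            assemble(_readset(["ACGT" * 25]), FixtureAssembler([]))

    def test_missing_assembler_executable(self):
        with pytest.raises(BackendError, match="not found"):
            assemble(_readset(["ACGT" * 25]),
                     MetaSpadesAssembler(executable="not-a-real-assembler"))

    def test_coverage_assembler_covers_genome_at_30x(self):
        """Reads tiling a 10 kb genome at ~30x yield scaffolds covering >=90%,
        verified by mapping scaffolds back to the known genome."""
        params = SyntheticCohortParams(
            n_genomes=1, genome_length=10_000, read_length=100,
            n_reads=3_000, seed=9,  # 3000 * 100 / 10000 = 30x
        )
        reads = generate_synthetic_cohort(params)
        genome = reads.cohort.donor_genomes["donorG0"]
        scaffolds = assemble(reads.donor, CoverageAssembler({"donorG0": genome}))
        covered = np.zeros(len(genome), dtype=bool)
        for s in scaffolds:
            start = genome.find(s.sequence)
            assert start >= 0, "scaffold is not a verbatim genome segment"
            covered[start : start + len(s.sequence)] = True
        assert covered.mean() >= 0.90

    def test_coverage_assembler_requires_provenance(self):
        asm = CoverageAssembler({"g": "ACGT" * 100})
        with pytest.raises(ValueError, match="provenance"):
            asm.assemble(_readset(["ACGT" * 25]))
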