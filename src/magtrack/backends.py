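"""Assembly and alignment backends.

The pipeline needs two heavy operations from outside tools: metagenomic
assembly of the source samples into scaffolds (a MAG database), and alignment
of reads against those scaffolds.  Both are exposed through small adapter
contracts so that the production path can shell out to the usual external
binaries (metaSPAdes, Bowtie 2, minimap2) while tests and simulations run a
built-in naive aligner that needs no executables at all.

Alignment identity is defined as ``1 - edit_distance / read_length`` and a
read counts as aligned to a database iff its best hit reaches the configured
minimum identity (default 1.00, i.e. perfect matches only; 0.98 and 0.99 are
the usual relaxed settings).  Only the single best hit per read per database
is retained — classification needs the aligned/unaligned flag plus one
representative scaffold, nothing more.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pysam

from .io_formats import ReadSet, read_fasta, write_fasta, write_fastq

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


class BackendError(RuntimeError):
    """An external backend failed (missing executable, nonzero exit, bad output)."""


@dataclass(frozen=True)
class Scaffold:
    """One assembled scaffold: the unit of a MAG database."""

    scaffold_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"scaffold {self.scaffold_id!r}: empty sequence")


class MagDatabase:
    """A source sample's scaffolds plus cached alignment-index structures.

    ``source_label`` is "donor" or "patient".  The k-mer indexes used by the
    naive aligner are built lazily per k and cached; external aligners instead
    use :meth:`to_fasta` to materialise the scaffolds on disk.
    """

    def __init__(self, source_label: str, scaffolds: Sequence[Scaffold]):
        if source_label not in ("donor", "patient"):
            raise ValueError(f"bad source label {source_label!r}")
        scaffolds = list(scaffolds)
        if not scaffolds:
            raise ValueError("a MAG database needs at least one scaffold")
        ids = [s.scaffold_id for s in scaffolds]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scaffold ids in database")
        self.source_label = source_label
        self.scaffolds = scaffolds
        self._arrays = [
            np.frombuffer(s.sequence.upper().encode(), dtype=np.uint8)
            for s in scaffolds
        ]
        self._kmer_indexes: dict[int, dict[bytes, list[tuple[int, int]]]] = {}

    def __len__(self) -> int:
        return len(self.scaffolds)

    @property
    def total_length(self) -> int:
        return sum(len(s.sequence) for s in self.scaffolds)

    def kmer_index(self, k: int) -> dict[bytes, list[tuple[int, int]]]:
        """Exact k-mer → [(scaffold index, offset), ...] lookup, cached per k."""
        idx = self._kmer_indexes.get(k)
        if idx is None:
            idx = {}
            for si, scaf in enumerate(self.scaffolds):
                b = scaf.sequence.upper().encode()
                for pos in range(len(b) - k + 1):
                    idx.setdefault(b[pos : pos + k], []).append((si, pos))
            self._kmer_indexes[k] = idx
        return idx

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        write_fasta(((s.scaffold_id, s.sequence) for s in self.scaffolds), path)
        return path


@dataclass(slots=True)
class AlignmentHit:
    """Best retained hit (or explicit non-hit) for one read against one database."""

    read_id: str
    scaffold_id: str | None
    identity: float | None
    aligned: bool


@dataclass
class AlignmentTable:
    """Per-read best-hit results of one read set against one database.

    Every queried read appears exactly once, aligned or not.
    """

    database_label: str
    hits: dict[str, AlignmentHit]
    total_reads_queried: int

    def __post_init__(self) -> None:
        if len(self.hits) != self.total_reads_queried:
            raise ValueError(
                f"{len(self.hits)} hits for {self.total_reads_queried} queried reads"
            )

    @property
    def n_aligned(self) -> int:
        return sum(1 for h in self.hits.values() if h.aligned)

    @property
    def n_unaligned(self) -> int:
        return self.total_reads_queried - self.n_aligned

    def aligned_ids(self) -> set[str]:
        return {rid for rid, h in self.hits.items() if h.aligned}


def build_index(scaffolds: Sequence[Scaffold], source_label: str = "donor") -> MagDatabase:
    """Build an alignment database from scaffolds (deterministic for fixed input)."""
    return MagDatabase(source_label=source_label, scaffolds=scaffolds)


def _max_mismatches(read_len: int, min_identity: float) -> int:
    # identity >= min_identity  <=>  mismatches <= floor(L * (1 - min_identity))
    return int(np.floor(read_len * (1.0 - min_identity) + 1e-12))


class AlignerBackend(Protocol):
    def align(self, reads: ReadSet, db: MagDatabase, min_identity: float) -> AlignmentTable: ...


class NaiveAligner:
    """Built-in ungapped aligner; no external binaries.

    Finds, for each read, the best ungapped end-to-end placement by Hamming
    distance over both strands of every scaffold.  The default path seeds with
    m+1 disjoint k-mers (m = allowed mismatches at the identity threshold) and
    verifies candidates with vectorised byte comparison; by the pigeonhole
    principle every placement with <= m mismatches contains at least one exact
    seed, so the thresholded aligned/unaligned decision and the best retained
    hit are identical to a full exhaustive scan.  ``exhaustive=True`` forces
    the literal scan (slow; used as the oracle in equivalence tests).

    Ties are broken toward the first scaffold in database order, then the
    leftmost position, then the forward strand.
    """

    def __init__(self, exhaustive: bool = False):
        self.exhaustive = exhaustive

    def align(self, reads: ReadSet, db: MagDatabase, min_identity: float) -> AlignmentTable:
        if not (0.0 < min_identity <= 1.0):
            raise ValueError(f"min_identity must be in (0, 1], got {min_identity}")
        hits: dict[str, AlignmentHit] = {}
        if self.exhaustive:
            for rec in reads:
                hits[rec.read_id] = self._align_exhaustive(rec.read_id, rec.sequence, db, min_identity)
            return AlignmentTable(db.source_label, hits, len(reads))

        lengths = {len(r.sequence) for r in reads.records}
        k = self._choose_k(lengths, min_identity) if lengths else 31
        if k < 8:
            # too little seed specificity (very short reads or very low identity)
            for rec in reads:
                hits[rec.read_id] = self._align_exhaustive(rec.read_id, rec.sequence, db, min_identity)
            return AlignmentTable(db.source_label, hits, len(reads))
        index = db.kmer_index(k)
        arrays = db._arrays
        scaf_lens = [len(a) for a in arrays]
        for rec in reads:
            seq = rec.sequence.upper()
            L = len(seq)
            m = _max_mismatches(L, min_identity)
            fwd = seq.encode()
            rev = revcomp(seq).encode()
            fwd_arr = np.frombuffer(fwd, dtype=np.uint8)
            rev_arr = np.frombuffer(rev, dtype=np.uint8)
            candidates: set[tuple[int, int, int]] = set()
            for strand, b in ((0, fwd), (1, rev)):
                for j in range(m + 1):
                    off = j * k
                    for si, pos in index.get(b[off : off + k], ()):
                        start = pos - off
                        if 0 <= start <= scaf_lens[si] - L:
                            candidates.add((si, start, strand))
            best: tuple[int, int, int, int] | None = None  # (mm, si, start, strand)
            for si, start, strand in sorted(candidates):
                arr = fwd_arr if strand == 0 else rev_arr
                mm = int(np.count_nonzero(arrays[si][start : start + L] != arr))
                if best is None or (mm, si, start, strand) < best:
                    best = (mm, si, start, strand)
            if best is not None and best[0] <= m:
                mm, si, _, _ = best
                hits[rec.read_id] = AlignmentHit(
                    rec.read_id, db.scaffolds[si].scaffold_id, (L - mm) / L, True
                )
            else:
                hits[rec.read_id] = AlignmentHit(rec.read_id, None, None, False)
        return AlignmentTable(db.source_label, hits, len(reads))

    @staticmethod
    def _choose_k(lengths: set[int], min_identity: float) -> int:
        k = min(L // (_max_mismatches(L, min_identity) + 1) for L in lengths)
        return min(k, 31)

    @staticmethod
    def _align_exhaustive(read_id: str, seq: str, db: MagDatabase, min_identity: float) -> AlignmentHit:
        seq = seq.upper()
        L = len(seq)
        m = _max_mismatches(L, min_identity)
        best: tuple[int, int, int, int] | None = None
        for strand, s in ((0, seq), (1, revcomp(seq))):
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            for si, scaf in enumerate(db._arrays):
                if len(scaf) < L:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(scaf, L)
                mms = np.count_nonzero(windows != arr, axis=1)
                start = int(np.argmin(mms))
                mm = int(mms[start])
                if best is None or (mm, si, start, strand) < best:
                    best = (mm, si, start, strand)
        if best is not None and best[0] <= m:
            mm, si, _, _ = best
            return AlignmentHit(read_id, db.scaffolds[si].scaffold_id, (L - mm) / L, True)
        return AlignmentHit(read_id, None, None, False)


def align(
    reads: ReadSet,
    db: MagDatabase,
    min_identity: float = 1.0,
    backend: AlignerBackend | None = None,
) -> AlignmentTable:
    """Align every read against ``db``; one AlignmentHit per read, best hit only."""
    backend = backend or NaiveAligner()
    return backend.align(reads, db, min_identity)


def align_naive(reads: ReadSet, db: MagDatabase, min_identity: float = 1.0) -> AlignmentTable:
    """The built-in aligner as a plain function (the test/simulation backend)."""
    return NaiveAligner().align(reads, db, min_identity)


# ---------------------------------------------------------------------------
# external aligner adapters (SAM-producing command-line tools)


class ExternalAligner:
    """Base adapter for a command-line aligner that emits SAM.

    Subclasses define :meth:`_command`.  End-to-end identity semantics are
    enforced at parse time: soft/hard-clipped bases count as edits, so
    identity = (read_length - NM - clipped) / read_length.
    """

    executable: str = ""

    def _command(self, fasta: Path, fastq: Path, sam: Path) -> list[str]:
        raise NotImplementedError

    def _prepare(self, fasta: Path, workdir: Path) -> None:
        """Hook for backends that need an explicit index-build step."""

    def align(self, reads: ReadSet, db: MagDatabase, min_identity: float) -> AlignmentTable:
        if shutil.which(self.executable) is None:
            raise BackendError(f"external aligner executable not found: {self.executable!r}")
        with tempfile.TemporaryDirectory(prefix="magtrack_aln_") as tmp:
            tmpdir = Path(tmp)
            fasta = db.to_fasta(tmpdir / "db.fasta")
            fastq = tmpdir / "reads.fastq"
            write_fastq(reads, fastq)
            sam = tmpdir / "out.sam"
            self._prepare(fasta, tmpdir)
            cmd = self._command(fasta, fastq, sam)
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise BackendError(
                    f"{self.executable} exited {proc.returncode}: {proc.stderr[-2000:]}"
                )
            return self._parse_sam(sam, reads, db, min_identity)

    @staticmethod
    def _parse_sam(
        sam: Path, reads: ReadSet, db: MagDatabase, min_identity: float
    ) -> AlignmentTable:
        lengths = {r.read_id: len(r.sequence) for r in reads}
        best: dict[str, tuple[float, str]] = {}
        with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_supplementary:
                    continue
                rid = rec.query_name
                if rid not in lengths:
                    continue
                L = lengths[rid]
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                clipped = sum(
                    n for op, n in (rec.cigartuples or []) if op in (4, 5)  # S, H
                )
                identity = (L - nm - clipped) / L
                if rid not in best or identity > best[rid][0]:
                    best[rid] = (identity, rec.reference_name)
        hits = {}
        for rec in reads:
            entry = best.get(rec.read_id)
            if entry is not None and entry[0] >= min_identity - 1e-12:
                hits[rec.read_id] = AlignmentHit(rec.read_id, entry[1], entry[0], True)
            else:
                hits[rec.read_id] = AlignmentHit(rec.read_id, None, None, False)
        return AlignmentTable(db.source_label, hits, len(reads))


class Minimap2Aligner(ExternalAligner):
    """minimap2 short-read adapter (``-x sr``), best primary alignment per read."""

    executable = "minimap2"

    def _command(self, fasta: Path, fastq: Path, sam: Path) -> list[str]:
        return [
            "minimap2", "-a", "-x", "sr", "--secondary=no",
            "-o", str(sam), str(fasta), str(fastq),
        ]


class Bowtie2Aligner(ExternalAligner):
    """Bowtie 2 adapter: bowtie2-build then end-to-end alignment, default sensitivity."""

    executable = "bowtie2"

    def _prepare(self, fasta: Path, workdir: Path) -> None:
        if shutil.which("bowtie2-build") is None:
            raise BackendError("external aligner executable not found: 'bowtie2-build'")
        proc = subprocess.run(
            ["bowtie2-build", "-q", str(fasta), str(workdir / "index")],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise BackendError(f"bowtie2-build exited {proc.returncode}: {proc.stderr[-2000:]}")

    def _command(self, fasta: Path, fastq: Path, sam: Path) -> list[str]:
        return [
            "bowtie2", "--end-to-end", "-x", str(fasta.parent / "index"),
            "-U", str(fastq), "-S", str(sam),
        ]


# ---------------------------------------------------------------------------
# assembler adapters


class AssemblerBackend(Protocol):
    def assemble(self, reads: ReadSet) -> list[Scaffold]: ...


class FixtureAssembler:
    """Returns caller-supplied scaffolds; the assembly stand-in for tests."""

    def __init__(self, scaffolds: Sequence[Scaffold]):
        self.scaffolds = list(scaffolds)

    def assemble(self, reads: ReadSet) -> list[Scaffold]:
        return list(self.scaffolds)


class CoverageAssembler:
    """Synthetic oracle assembler driven by read coverage of known truth genomes.

    Emulates the one property of metagenomic assembly that matters for the
    pipeline's depth behaviour: only genome regions actually covered by reads
    can end up in the database.  Requires reads carrying simulation provenance
    (``genome_id``/``position``); it unions the covered intervals per genome
    and emits each maximal covered segment of at least ``min_segment_length``
    bases, taken verbatim from the truth genome.  It performs no graph
    assembly and is only meaningful on simulated data.
    """

    def __init__(self, genomes: dict[str, str], min_segment_length: int = 200):
        self.genomes = genomes
        self.min_segment_length = min_segment_length

    def assemble(self, reads: ReadSet) -> list[Scaffold]:
        intervals: dict[str, list[tuple[int, int]]] = {}
        for rec in reads:
            if rec.genome_id is None or rec.position is None:
                raise ValueError(
                    f"read {rec.read_id!r} lacks simulation provenance; "
                    "CoverageAssembler only works on simulated reads"
                )
            intervals.setdefault(rec.genome_id, []).append(
                (rec.position, rec.position + len(rec.sequence))
            )
        scaffolds: list[Scaffold] = []
        for genome_id in sorted(intervals):
            genome = self.genomes[genome_id]
            merged: list[list[int]] = []
            for start, end in sorted(intervals[genome_id]):
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            for n, (start, end) in enumerate(merged):
                end = min(end, len(genome))
                if end - start >= self.min_segment_length:
                    scaffolds.append(
                        Scaffold(f"{genome_id}_seg{n}", genome[start:end])
                    )
        return scaffolds


class MetaSpadesAssembler:
    """Adapter shelling out to the metaSPAdes executable."""

    def __init__(self, executable: str = "metaspades.py", extra_args: Sequence[str] = ()):
        self.executable = executable
        self.extra_args = list(extra_args)

    def assemble(self, reads: ReadSet) -> list[Scaffold]:
        if shutil.which(self.executable) is None:
            raise BackendError(f"assembler executable not found: {self.executable!r}")
        with tempfile.TemporaryDirectory(prefix="magtrack_asm_") as tmp:
            tmpdir = Path(tmp)
            fastq = tmpdir / "reads.fastq"
            write_fastq(reads, fastq)
            outdir = tmpdir / "out"
            cmd = [self.executable, "-s", str(fastq), "-o", str(outdir), *self.extra_args]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise BackendError(
                    f"{self.executable} exited {proc.returncode}: {proc.stderr[-2000:]}"
                )
            scaffolds_fasta = outdir / "scaffolds.fasta"
            if not scaffolds_fasta.exists():
                raise BackendError(f"{self.executable} produced no scaffolds.fasta")
            return [Scaffold(name, seq) for name, seq in read_fasta(scaffolds_fasta)]


def assemble(reads: ReadSet, backend: AssemblerBackend) -> list[Scaffold]:
    """Assemble a source sample's reads into scaffolds via the given backend."""
    if len(reads) == 0:
        raise ValueError("cannot assemble an empty read set")
    scaffolds = backend.assemble(reads)
    if not scaffolds:
        raise BackendError("no scaffolds produced")
    return scaffolds


def load_scaffolds(path: str | Path) -> list[Scaffold]:
    return [Scaffold(name, seq) for name, seq in read_fasta(path)]
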