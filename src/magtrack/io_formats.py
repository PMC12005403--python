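"""Readers and writers for the formats the pipeline touches.

Shotgun reads come in as FASTQ (plain or gzipped, detected by magic bytes),
scaffolds as FASTA, and results go out as flat TSV tables.  A study manifest
(YAML) wires one patient's donor / baseline / post-treatment samples together.

Multiple FASTQ files for one role (e.g. several sequenced preparations of the
same donor's material) are concatenated into a single read set, mirroring how
a multi-donation donor sample is handled in practice.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MATES = ("r1", "r2", "unpaired")
SOURCES = ("donor", "patient", "contaminant", "unknown")

#: placeholder quality character for simulated reads (Q40)
DEFAULT_QUALITY_CHAR = "I"


class FastqParseError(ValueError):
    """A FASTQ file could not be parsed (truncated or malformed record)."""


@dataclass(slots=True)
class ReadRecord:
    """One sequencing read.

    ``true_source`` carries simulation provenance ("unknown" for real data);
    ``genome_id``/``position``/``strand`` are additional provenance fields the
    simulator fills in so that oracle checks (and the coverage-based fixture
    assembler) can see where a read truly came from.
    """

    read_id: str
    sequence: str
    quality: str | None = None
    mate: str = "unpaired"
    true_source: str = "unknown"
    genome_id: str | None = None
    position: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.mate not in MATES:
            raise ValueError(f"read {self.read_id!r}: bad mate {self.mate!r}")
        if self.true_source not in SOURCES:
            raise ValueError(
                f"read {self.read_id!r}: bad true_source {self.true_source!r}"
            )


@dataclass
class ReadSet:
    """An ordered collection of reads from one sample, unique read ids."""

    sample_id: str
    records: list[ReadRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {r.read_id for r in self.records}
        if len(ids) != len(self.records):
            raise ValueError(f"sample {self.sample_id!r}: duplicate read ids")

    @property
    def depth(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReadRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ReadRecord:
        return self.records[i]

    def read_ids(self) -> list[str]:
        return [r.read_id for r in self.records]

    def subset(self, indices: Sequence[int], sample_id: str | None = None) -> "ReadSet":
        """New ReadSet containing ``records[i]`` for i in ``indices`` (in order)."""
        return ReadSet(
            sample_id=sample_id or self.sample_id,
            records=[self.records[i] for i in indices],
        )


def _is_gzip(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _open_text(path: Path) -> io.TextIOBase:
    if _is_gzip(path):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _infer_mate(title: str) -> str:
    """Infer the mate from a FASTQ title line (old ``/1`` or Casava ``1:N:0:...``)."""
    head, _, comment = title.partition(" ")
    if head.endswith("/1"):
        return "r1"
    if head.endswith("/2"):
        return "r2"
    if comment[:2] in ("1:", "2:"):
        return "r1" if comment[0] == "1" else "r2"
    return "unpaired"


def read_fastq(paths: Sequence[str | Path], sample_id: str | None = None) -> ReadSet:
    """Parse one or more FASTQ files (optionally gzipped) into a single ReadSet.

    Files are concatenated in list order, so several sequencing files for one
    donor or baseline sample become one read set.  Read ids that collide
    across mates (r1/r2 sharing an id) are disambiguated by a mate suffix.
    """
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
    records: list[ReadRecord] = []
    seen: set[str] = set()
    for path in paths:
        with _open_text(path) as fh:
            it = FastqGeneralIterator(fh)
            idx = 0
            while True:
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise FastqParseError(
                        f"{path}: record {idx}: {exc}"
                    ) from exc
                mate = _infer_mate(title)
                read_id = title.split(None, 1)[0]
                if read_id in seen:
                    suffix = {"r1": "/1", "r2": "/2"}.get(mate, "")
                    candidate = read_id + suffix
                    n = 1
                    while candidate in seen or candidate == read_id:
                        candidate = f"{read_id}{suffix}#{n}"
                        n += 1
                    read_id = candidate
                seen.add(read_id)
                records.append(
                    ReadRecord(read_id=read_id, sequence=seq, quality=qual, mate=mate)
                )
                idx += 1
    if sample_id is None:
        sample_id = paths[0].name.split(".")[0] if paths else "sample"
    return ReadSet(sample_id=sample_id, records=records)


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """Write a ReadSet as 4-line FASTQ; gzipped when the path ends in ``.gz``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in reads:
            qual = rec.quality or DEFAULT_QUALITY_CHAR * len(rec.sequence)
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into ``(id, sequence)`` pairs (id = first token of header)."""
    with _open_text(Path(path)) as fh:
        return [(title.split(None, 1)[0], seq.upper()) for title, seq in SimpleFastaParser(fh)]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular outputs

REPORT_COLUMNS = [
    "sample_id",
    "engrafted",
    "persistent",
    "novel",
    "posterior_donor",
    "n_unique_donor",
    "n_unique_patient",
    "n_ambiguous",
    "n_unmapped",
]

ENGRAFTED_READ_COLUMNS = ["read_id", "scaffold_id", "call", "posterior_donor"]


def write_report(estimates, path: str | Path) -> None:
    """Write one row per engraftment estimate (proportions at 8 decimals).

    ``estimates`` is a single estimate or an iterable of estimates; each needs
    the attributes named in :data:`REPORT_COLUMNS` (counts live on
    ``estimate.counts``).
    """
    if not isinstance(estimates, (list, tuple)):
        estimates = [estimates]
    rows = []
    for est in estimates:
        c = est.counts
        rows.append(
            {
                "sample_id": est.sample_id,
                "engrafted": f"{est.engrafted:.8f}",
                "persistent": f"{est.persistent:.8f}",
                "novel": f"{est.novel:.8f}",
                "posterior_donor": f"{est.posterior_donor:.8f}",
                "n_unique_donor": c.n_unique_donor,
                "n_unique_patient": c.n_unique_patient,
                "n_ambiguous": c.n_ambiguous,
                "n_unmapped": c.n_unmapped,
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_engrafted_reads(assignments: Iterable[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write the engrafted-read table (read id, best donor scaffold, call, posterior)."""
    df = pd.DataFrame(assignments, columns=ENGRAFTED_READ_COLUMNS)
    bad = set(df["call"].unique()) - {"unique_donor", "ambiguous_donor"}
    if bad:
        raise ValueError(f"invalid engrafted-read calls: {sorted(bad)}")
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")


# ---------------------------------------------------------------------------
# study manifest


@dataclass
class StudyManifest:
    """Wires one patient's samples together: donor + baseline + post samples."""

    patient_id: str
    donor_fastqs: list[str]
    baseline_fastqs: list[str]
    post_samples: list[tuple[str, list[str]]]
    min_identity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.donor_fastqs or not self.baseline_fastqs:
            raise ValueError("manifest needs at least one donor and one baseline FASTQ")
        all_paths = [*self.donor_fastqs, *self.baseline_fastqs]
        for _, paths in self.post_samples:
            all_paths.extend(paths)
        if len(set(all_paths)) != len(all_paths):
            raise ValueError("manifest paths must be distinct")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError(f"min_identity must be in (0, 1], got {self.min_identity}")


def load_manifest(path: str | Path) -> StudyManifest:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: manifest must be a mapping")
    post = [(str(label), [str(p) for p in paths]) for label, paths in data.get("post_samples", {}).items()]
    return StudyManifest(
        patient_id=str(data["patient_id"]),
        donor_fastqs=[str(p) for p in data["donor_fastqs"]],
        baseline_fastqs=[str(p) for p in data["baseline_fastqs"]],
        post_samples=post,
        min_identity=float(data.get("min_identity", 1.0)),
        seed=int(data.get("seed", 0)),
    )


def save_manifest(manifest: StudyManifest, path: str | Path) -> None:
    data = {
        "patient_id": manifest.patient_id,
        "donor_fastqs": list(manifest.donor_fastqs),
        "baseline_fastqs": list(manifest.baseline_fastqs),
        "post_samples": {label: list(paths) for label, paths in manifest.post_samples},
        "min_identity": manifest.min_identity,
        "seed": manifest.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
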