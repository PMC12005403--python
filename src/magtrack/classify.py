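"""Four-way read classification and self-alignment rate estimation.

Every post-treatment read is aligned against both source databases and lands
in exactly one of four bins: uniquely donor-aligned (candidate engrafted),
uniquely patient-aligned (persistent baseline strains), ambiguous (aligned to
both; resolved downstream by the Bayes posterior), or unmapped.

The self-alignment profile is estimated by aligning each source sample's own
reads against both databases.  Its both-aligned rates are the likelihood
terms of the posterior — how often a read truly from one source looks
ambiguous — and its self-unmapped rates give the expected unmapped fraction
used to separate genuinely novel strains from assembly/sequencing dropout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .backends import AlignerBackend, AlignmentTable, MagDatabase, align
from .io_formats import ReadSet


@dataclass(frozen=True, slots=True)
class ReadFlags:
    """Alignment observations for one read: p = patient DB hit, d = donor DB hit."""

    p: bool
    d: bool

    @property
    def bin(self) -> str:
        if self.d and not self.p:
            return "unique_donor"
        if self.p and not self.d:
            return "unique_patient"
        if self.p and self.d:
            return "ambiguous"
        return "unmapped"


class PerRead(NamedTuple):
    flags: ReadFlags
    donor_scaffold: str | None
    patient_scaffold: str | None


@dataclass
class ClassificationResult:
    """Four-way bin counts plus per-read flags for one post-treatment sample."""

    sample_id: str
    n_total: int
    n_unique_donor: int
    n_unique_patient: int
    n_ambiguous: int
    n_unmapped: int
    per_read: dict[str, PerRead]

    def __post_init__(self) -> None:
        counts = (self.n_unique_donor, self.n_unique_patient, self.n_ambiguous, self.n_unmapped)
        if any(c < 0 for c in counts):
            raise ValueError("negative bin count")
        if sum(counts) != self.n_total:
            raise ValueError(
                f"bins {counts} do not partition n_total={self.n_total}"
            )


def classify_reads(
    donor_table: AlignmentTable,
    patient_table: AlignmentTable,
    sample_id: str = "sample",
) -> ClassificationResult:
    """Bin each read by its (donor hit, patient hit) flag pair.

    Both tables must have queried the identical read set.
    """
    if set(donor_table.hits) != set(patient_table.hits):
        raise ValueError("donor and patient alignment tables queried different read sets")
    per_read: dict[str, PerRead] = {}
    counts = {"unique_donor": 0, "unique_patient": 0, "ambiguous": 0, "unmapped": 0}
    for read_id, dhit in donor_table.hits.items():
        phit = patient_table.hits[read_id]
        flags = ReadFlags(p=phit.aligned, d=dhit.aligned)
        per_read[read_id] = PerRead(flags, dhit.scaffold_id, phit.scaffold_id)
        counts[flags.bin] += 1
    return ClassificationResult(
        sample_id=sample_id,
        n_total=len(per_read),
        n_unique_donor=counts["unique_donor"],
        n_unique_patient=counts["unique_patient"],
        n_ambiguous=counts["ambiguous"],
        n_unmapped=counts["unmapped"],
        per_read=per_read,
    )


@dataclass(frozen=True)
class SelfAlignmentProfile:
    """Empirical alignment rates of each source sample against both databases.

    ``donor_both_rate``   — P(aligned to both DBs | read truly from donor)
    ``patient_both_rate`` — P(aligned to both DBs | read truly from patient)
    ``*_self_unmapped_rate`` — fraction of a source's own reads missing from
    its own database (sequencing error + unassembled rare strains).
    Denominators are all reads of the source sample.
    """

    donor_both_rate: float
    patient_both_rate: float
    donor_self_unmapped_rate: float
    patient_self_unmapped_rate: float

    def __post_init__(self) -> None:
        for name in (
            "donor_both_rate",
            "patient_both_rate",
            "donor_self_unmapped_rate",
            "patient_self_unmapped_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def profile_from_tables(
    donor_vs_donor: AlignmentTable,
    donor_vs_patient: AlignmentTable,
    patient_vs_patient: AlignmentTable,
    patient_vs_donor: AlignmentTable,
) -> SelfAlignmentProfile:
    """Compute the profile from the four source-sample alignment tables."""
    n_donor = donor_vs_donor.total_reads_queried
    n_patient = patient_vs_patient.total_reads_queried
    if n_donor == 0 or n_patient == 0:
        raise ValueError("source read sets must be non-empty")
    donor_both = len(donor_vs_donor.aligned_ids() & donor_vs_patient.aligned_ids())
    patient_both = len(patient_vs_patient.aligned_ids() & patient_vs_donor.aligned_ids())
    return SelfAlignmentProfile(
        donor_both_rate=donor_both / n_donor,
        patient_both_rate=patient_both / n_patient,
        donor_self_unmapped_rate=donor_vs_donor.n_unaligned / n_donor,
        patient_self_unmapped_rate=patient_vs_patient.n_unaligned / n_patient,
    )


def estimate_self_profile(
    donor_reads: ReadSet,
    patient_reads: ReadSet,
    donor_db: MagDatabase,
    patient_db: MagDatabase,
    min_identity: float = 1.0,
    backend: AlignerBackend | None = None,
) -> SelfAlignmentProfile:
    """Align each source's reads against both databases and tally the rates.

    The same identity threshold is used as for post-sample classification.
    """
    if len(donor_reads) == 0 or len(patient_reads) == 0:
        raise ValueError("source read sets must be non-empty")
    dd = align(donor_reads, donor_db, min_identity, backend)
    dp = align(donor_reads, patient_db, min_identity, backend)
    pp = align(patient_reads, patient_db, min_identity, backend)
    pdb = align(patient_reads, donor_db, min_identity, backend)
    return profile_from_tables(dd, dp, pp, pdb)
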