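"""Final engraftment summary: engrafted / persistent / novel proportions.

The four classification bins plus the posterior split of the ambiguous bin
give the mapped mass attributable to each source.  Unmapped reads are then
corrected: some unmapped mass is *expected* (sequencing error and source
strains too rare to assemble, quantified by the self-unmapped rates of the
self-alignment profile), and only the excess over expectation is called
novel — strains acquired from diet or environment rather than either source.

The expected-unmapped mass is redistributed back to donor and patient in
proportion to their mapped-mass split; the redistribution is capped at the
observed unmapped count so the three output proportions always sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .bayes import (
    PosteriorAllocation,
    allocate_ambiguous,
    estimate_priors,
    posterior_donor,
)
from .classify import ClassificationResult, SelfAlignmentProfile
from .io_formats import write_fasta


@dataclass
class EngraftmentEstimate:
    """Engrafted/persistent/novel proportions for one post-treatment sample."""

    sample_id: str
    engrafted: float
    persistent: float
    novel: float
    posterior_donor: float
    counts: ClassificationResult
    per_mag_engrafted: dict[str, float] = field(default_factory=dict)
    expected_unmapped_count: float = 0.0
    novel_clamped: bool = False

    def __post_init__(self) -> None:
        total = self.engrafted + self.persistent + self.novel
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")
        for name in ("engrafted", "persistent", "novel"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _mapped_mass_split(c: ClassificationResult, alloc: PosteriorAllocation) -> tuple[float, float]:
    e = c.n_unique_donor + alloc.ambiguous_to_donor
    p = c.n_unique_patient + alloc.ambiguous_to_patient
    return e, p


def correct_unmapped(
    c: ClassificationResult,
    profile: SelfAlignmentProfile,
    alloc: PosteriorAllocation,
) -> tuple[float, float]:
    """Split the unmapped bin into expected dropout vs genuinely novel mass.

    The expected unmapped fraction is the mapped-mass-weighted average of the
    two self-unmapped rates; whatever unmapped mass remains above that
    expectation is novel.  Returns ``(novel_count, expected_unmapped_count)``;
    novel is clamped at zero when fewer reads are unmapped than expected.
    """
    e, p = _mapped_mass_split(c, alloc)
    if e + p == 0:
        warnings.warn(
            f"sample {c.sample_id!r}: no mapped reads; expected-unmapped rate "
            "taken as the mean of the two self-unmapped rates",
            stacklevel=2,
        )
        u = 0.5 * (profile.donor_self_unmapped_rate + profile.patient_self_unmapped_rate)
    else:
        u = (
            e * profile.donor_self_unmapped_rate + p * profile.patient_self_unmapped_rate
        ) / (e + p)
    expected_unmapped = u * c.n_total
    novel = max(0.0, c.n_unmapped - expected_unmapped)
    return novel, expected_unmapped


def summarize(
    c: ClassificationResult,
    alloc: PosteriorAllocation,
    correction: tuple[float, float],
) -> EngraftmentEstimate:
    """Combine counts, posterior allocation and unmapped correction.

    Expected-unmapped mass (capped at the observed unmapped count) is
    redistributed to donor/patient in proportion to the mapped-mass split, so
    engrafted + persistent + novel = 1 exactly.
    """
    if c.n_total == 0:
        raise ValueError(f"empty sample {c.sample_id!r}")
    novel_count, expected_unmapped = correction
    e, p = _mapped_mass_split(c, alloc)
    redistributed = c.n_unmapped - novel_count  # = min(expected, n_unmapped) given clamp
    if e + p > 0:
        r_d = e / (e + p)
    else:
        r_d = 0.5
    engrafted = (c.n_unique_donor + alloc.ambiguous_to_donor + r_d * redistributed) / c.n_total
    persistent = (
        c.n_unique_patient + alloc.ambiguous_to_patient + (1.0 - r_d) * redistributed
    ) / c.n_total
    novel = novel_count / c.n_total
    return EngraftmentEstimate(
        sample_id=c.sample_id,
        engrafted=engrafted,
        persistent=persistent,
        novel=novel,
        posterior_donor=alloc.posterior_donor,
        counts=c,
        per_mag_engrafted=per_mag_report(c, alloc),
        expected_unmapped_count=expected_unmapped,
        novel_clamped=expected_unmapped > c.n_unmapped,
    )


def estimate_from_classification(
    c: ClassificationResult, profile: SelfAlignmentProfile
) -> EngraftmentEstimate:
    """The statistical tail of the pipeline in one call:
    priors -> posterior -> ambiguous allocation -> unmapped correction -> summary.

    With no ambiguous reads the posterior is moot; it is set to the prior
    without the zero-likelihood warning since nothing is being allocated.
    """
    priors = estimate_priors(c)
    if c.n_ambiguous == 0:
        post = priors.prior_donor
    else:
        post = posterior_donor(priors, profile)
    alloc = allocate_ambiguous(c.n_ambiguous, post)
    correction = correct_unmapped(c, profile, alloc)
    return summarize(c, alloc, correction)


def per_mag_report(c: ClassificationResult, alloc: PosteriorAllocation) -> dict[str, float]:
    """Engrafted read mass per donor scaffold (MAG).

    Each unique-donor read contributes 1 to its best donor scaffold; each
    ambiguous read contributes the posterior.  Normalising these counts gives
    the percentage of engrafted reads per MAG.
    """
    mass: dict[str, float] = {}
    for read_id, pr in c.per_read.items():
        if pr.donor_scaffold is None:
            continue
        b = pr.flags.bin
        if b == "unique_donor":
            mass[pr.donor_scaffold] = mass.get(pr.donor_scaffold, 0.0) + 1.0
        elif b == "ambiguous":
            mass[pr.donor_scaffold] = mass.get(pr.donor_scaffold, 0.0) + alloc.posterior_donor
    return mass


def engrafted_read_rows(c: ClassificationResult, alloc: PosteriorAllocation) -> list[dict]:
    """Rows for the engrafted-reads table: unique-donor reads plus ambiguous
    reads whose posterior favours the donor (> 0.5; ties go to the patient)."""
    rows = []
    for read_id, pr in c.per_read.items():
        b = pr.flags.bin
        if b == "unique_donor":
            rows.append(
                {"read_id": read_id, "scaffold_id": pr.donor_scaffold,
                 "call": "unique_donor", "posterior_donor": 1.0}
            )
        elif b == "ambiguous" and alloc.posterior_donor > 0.5:
            rows.append(
                {"read_id": read_id, "scaffold_id": pr.donor_scaffold,
                 "call": "ambiguous_donor", "posterior_donor": alloc.posterior_donor}
            )
    return rows


def per_mag_table(per_mag: dict[str, float]) -> pd.DataFrame:
    """Per-MAG engrafted counts with percentages of total engrafted mass."""
    total = sum(per_mag.values())
    rows = [
        {
            "scaffold_id": sid,
            "engrafted_count": count,
            "engrafted_percent": 100.0 * count / total if total > 0 else 0.0,
        }
        for sid, count in sorted(per_mag.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["scaffold_id", "engrafted_count", "engrafted_percent"])


def export_engrafted_scaffolds(db, per_mag: dict[str, float], path) -> int:
    """Write donor scaffolds carrying engrafted mass to FASTA for downstream
    binning/taxonomy; returns the number of scaffolds written."""
    wanted = {sid for sid, count in per_mag.items() if count > 0}
    entries = [
        (s.scaffold_id, s.sequence) for s in db.scaffolds if s.scaffold_id in wanted
    ]
    write_fasta(entries, path)
    return len(entries)
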