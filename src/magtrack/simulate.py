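"""Simulation-based validation machinery.

Real engraftment truth is unknowable, so the method is validated on
constructed mixtures: donor and pre-treatment (patient) read pools are
combined at known fractions f = 0, 0.1, ..., 1.0, optionally spiked with a
20% "contaminate" source, and the pipeline's engraftment estimate is
compared against the known composition.  Read provenance labels ride along
on every simulated read, so type I error (contaminant mass called engrafted)
and type II error (donor mass missed) can be measured directly.

The synthetic cohort generator stands in for real stool metagenomes at desk
scale: a handful of random genomes per source with a controllable fraction
of genome content shared verbatim between donor and patient, reads sampled
uniformly from both strands with a substitution-only error model.  Replication
of the full-scale design uses 8.75 million reads per sample; desk-scale
defaults use 20 thousand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .backends import CoverageAssembler, MagDatabase, Scaffold, align
from .classify import (
    ClassificationResult,
    PerRead,
    ReadFlags,
    classify_reads,
    profile_from_tables,
)
from .engraftment import EngraftmentEstimate, estimate_from_classification
from .io_formats import ReadRecord, ReadSet

#: full-scale replication depth (reads per simulated sample)
REPLICATION_DEPTH = 8_750_000
#: desk-scale default depth for tests and examples
DESK_DEPTH = 20_000

FRACTION_GRID = tuple(round(0.1 * i, 1) for i in range(11))
IDENTITY_GRID = (0.98, 0.99, 1.00)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _child_seeds(seed: int, *context: int, n: int = 1) -> list[int]:
    """Deterministic sub-seeds (< 2**31) derived from a base seed and context."""
    state = np.random.SeedSequence([int(seed), *map(int, context)]).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


# ---------------------------------------------------------------------------
# synthetic cohort


@dataclass
class SyntheticCohortParams:
    """Knobs of the synthetic cohort generator.

    Two (optionally three) source communities of ``n_genomes`` random genomes
    of ``genome_length`` bp each; the patient shares ``shared_fraction`` of
    each genome with the donor (copied verbatim).  The contaminant can share
    ``contaminant_shared_fraction`` of donor content, mutated at
    ``contaminant_divergence`` per base, emulating related-but-distinct
    strains in an unrelated healthy donor.
    """

    n_genomes: int = 2
    genome_length: int = 25_000
    shared_fraction: float = 0.0
    contaminant_shared_fraction: float = 0.0
    contaminant_divergence: float = 0.01
    read_length: int = 150
    error_rate: float = 0.0
    n_reads: int = DESK_DEPTH
    abundances: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction outside [0, 1]")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")


@dataclass
class SyntheticCohort:
    """Truth genomes of the three source communities plus generator settings."""

    donor_genomes: dict[str, str]
    patient_genomes: dict[str, str]
    contaminant_genomes: dict[str, str]
    shared_fraction: float
    read_length: int
    error_rate: float
    seed: int
    #: per patient genome, length of the prefix copied verbatim from the donor
    shared_prefix: dict[str, int] = field(default_factory=dict)

    def all_genomes(self) -> dict[str, str]:
        return {**self.donor_genomes, **self.patient_genomes, **self.contaminant_genomes}


class CohortReads(NamedTuple):
    donor: ReadSet
    patient: ReadSet
    contaminant: ReadSet
    cohort: SyntheticCohort


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _kmer_set(seq: str, k: int) -> set[bytes]:
    b = seq.encode()
    return {b[i : i + k] for i in range(len(b) - k + 1)}


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.flatnonzero(rng.random(arr.size) < rate)
    if idx.size:
        code = np.searchsorted(_BASES, arr[idx])
        arr[idx] = _BASES[(code + rng.integers(1, 4, size=idx.size)) % 4]
    return arr.tobytes().decode()


def make_cohort(params: SyntheticCohortParams) -> SyntheticCohort:
    """Build the truth genomes.

    When a region is meant to be disjoint between communities it is screened
    for chance shared 21-mers against the donor genomes (both strands) and
    regenerated if any are found, so "no shared content" holds exactly at
    read scale, not just in expectation.
    """
    from .backends import revcomp

    rng = np.random.default_rng(_child_seeds(params.seed, 0xC0)[0])
    k = 21
    donor: dict[str, str] = {}
    donor_kmers: set[bytes] = set()
    for i in range(params.n_genomes):
        g = _random_genome(rng, params.genome_length)
        donor[f"donorG{i}"] = g
        donor_kmers |= _kmer_set(g, k) | _kmer_set(revcomp(g), k)

    def disjoint_random(length: int) -> str:
        for _ in range(20):
            g = _random_genome(rng, length)
            if not (_kmer_set(g, k) | _kmer_set(revcomp(g), k)) & donor_kmers:
                return g
        raise RuntimeError("could not generate a genome disjoint from the donor")

    patient: dict[str, str] = {}
    shared_prefix: dict[str, int] = {}
    s_len = int(round(params.shared_fraction * params.genome_length))
    for i in range(params.n_genomes):
        rest = disjoint_random(params.genome_length - s_len) if s_len < params.genome_length else ""
        name = f"patientG{i}"
        patient[name] = donor[f"donorG{i}"][:s_len] + rest
        shared_prefix[name] = s_len

    contaminant: dict[str, str] = {}
    c_len = int(round(params.contaminant_shared_fraction * params.genome_length))
    for i in range(params.n_genomes):
        shared = _mutate(rng, donor[f"donorG{i}"][:c_len], params.contaminant_divergence)
        rest = disjoint_random(params.genome_length - c_len) if c_len < params.genome_length else ""
        contaminant[f"contamG{i}"] = shared + rest

    return SyntheticCohort(
        donor_genomes=donor,
        patient_genomes=patient,
        contaminant_genomes=contaminant,
        shared_fraction=params.shared_fraction,
        read_length=params.read_length,
        error_rate=params.error_rate,
        seed=params.seed,
        shared_prefix=shared_prefix,
    )


def sample_reads(
    genomes: dict[str, str],
    n: int,
    read_length: int,
    error_rate: float,
    seed: int,
    label: str,
    id_prefix: str,
    abundances: Sequence[float] | None = None,
) -> ReadSet:
    """Sample ``n`` reads uniformly from both strands of the given genomes.

    ``abundances`` weights whole genomes (default: proportional to length,
    i.e. uniform over positions).  Substitution errors at ``error_rate`` per
    base; no indels, so the naive ungapped aligner remains an exact oracle.
    Provenance (true source, genome, position, strand) is recorded per read.
    """
    rng = np.random.default_rng(seed)
    names = list(genomes)
    arrays = [np.searchsorted(_BASES, np.frombuffer(genomes[g].encode(), dtype=np.uint8)) for g in names]
    n_positions = np.array([max(1, a.size - read_length + 1) for a in arrays], dtype=float)
    if abundances is None:
        weights = n_positions
    else:
        weights = np.asarray(abundances, dtype=float)
        if weights.size != len(names):
            raise ValueError("one abundance per genome required")
    weights = weights / weights.sum()
    genome_idx = rng.choice(len(names), size=n, p=weights)
    strands = rng.integers(0, 2, size=n)
    records: list[ReadRecord] = []
    for i in range(n):
        gi = int(genome_idx[i])
        arr = arrays[gi]
        pos = int(rng.integers(0, arr.size - read_length + 1))
        window = arr[pos : pos + read_length]
        if strands[i] == 1:
            window = 3 - window[::-1]
        if error_rate > 0:
            window = window.copy()
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            if errs.size:
                window[errs] = (window[errs] + rng.integers(1, 4, size=errs.size)) % 4
        records.append(
            ReadRecord(
                read_id=f"{id_prefix}{i:08d}",
                sequence=_BASES[window].tobytes().decode(),
                mate="unpaired",
                true_source=label,
                genome_id=names[gi],
                position=pos,
                strand="-" if strands[i] == 1 else "+",
            )
        )
    return ReadSet(sample_id=f"{label}_pool", records=records)


def generate_synthetic_cohort(params: SyntheticCohortParams) -> CohortReads:
    """Genomes plus one read pool per source community, deterministic per seed."""
    cohort = make_cohort(params)
    s_d, s_p, s_c = _child_seeds(params.seed, 0x5E, n=3)
    donor = sample_reads(
        cohort.donor_genomes, params.n_reads, params.read_length, params.error_rate,
        s_d, "donor", "D", params.abundances,
    )
    patient = sample_reads(
        cohort.patient_genomes, params.n_reads, params.read_length, params.error_rate,
        s_p, "patient", "P", params.abundances,
    )
    contaminant = sample_reads(
        cohort.contaminant_genomes, params.n_reads, params.read_length, params.error_rate,
        s_c, "contaminant", "C", params.abundances,
    )
    return CohortReads(donor, patient, contaminant, cohort)


# ---------------------------------------------------------------------------
# subsampling and mixtures


def _subsample_indices(depth: int, n: int, seed: int) -> np.ndarray:
    if not (0 <= n <= depth):
        raise ValueError(f"cannot draw {n} reads from a pool of {depth}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(depth, size=n, replace=False))


def subsample_reads(reads: ReadSet, n: int, seed: int) -> ReadSet:
    """Uniform sample of ``n`` reads without replacement, order-preserving."""
    idx = _subsample_indices(reads.depth, n, seed)
    return reads.subset(idx.tolist())


def mixture_counts(depth: int, f: float) -> tuple[int, int]:
    """(donor, patient) read counts for a mixture: f*depth rounded to nearest
    integer goes to the donor, the remainder to the patient."""
    n_donor = int(np.floor(f * depth + 0.5))
    return n_donor, depth - n_donor


def contaminated_counts(depth: int, f: float, c: float) -> tuple[int, int, int]:
    """(contaminant, donor, patient) counts: c*depth contaminant reads, the
    remaining (1-c)*depth split at ratio f : (1-f)."""
    if not (0.0 <= c < 1.0):
        raise ValueError(f"contaminant fraction must be in [0, 1), got {c}")
    n_contam = int(np.floor(c * depth + 0.5))
    n_donor, n_patient = mixture_counts(depth - n_contam, f)
    return n_contam, n_donor, n_patient


@dataclass
class SimulatedMixture:
    """A simulated post-treatment sample with exact known composition."""

    reads: ReadSet
    true_donor_fraction: float
    contaminant_fraction: float
    depth: int
    donor_indices: np.ndarray
    patient_indices: np.ndarray
    contaminant_indices: np.ndarray

    @property
    def n_donor(self) -> int:
        return len(self.donor_indices)


def _relabel(reads: ReadSet, indices: np.ndarray, label: str) -> list[ReadRecord]:
    return [replace(reads.records[i], true_source=label) for i in indices.tolist()]


def make_mixture(
    donor: ReadSet, patient: ReadSet, depth: int, f: float, seed: int,
    sample_id: str | None = None,
) -> SimulatedMixture:
    """Mix donor and patient reads at donor fraction ``f`` (exact counts)."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"donor fraction must be in [0, 1], got {f}")
    n_donor, n_patient = mixture_counts(depth, f)
    s_d, s_p = _child_seeds(seed, 0x31, n=2)
    d_idx = _subsample_indices(donor.depth, n_donor, s_d)
    p_idx = _subsample_indices(patient.depth, n_patient, s_p)
    records = _relabel(donor, d_idx, "donor") + _relabel(patient, p_idx, "patient")
    reads = ReadSet(sample_id or f"mix_f{f:g}", records)
    return SimulatedMixture(
        reads=reads,
        true_donor_fraction=n_donor / depth if depth else 0.0,
        contaminant_fraction=0.0,
        depth=depth,
        donor_indices=d_idx,
        patient_indices=p_idx,
        contaminant_indices=np.empty(0, dtype=int),
    )


def make_contaminated_mixture(
    donor: ReadSet, patient: ReadSet, contaminant: ReadSet,
    depth: int, f: float, c: float, seed: int, sample_id: str | None = None,
) -> SimulatedMixture:
    """Mixture with ``c`` of the depth from the contaminant source and the
    donor:patient ratio f : (1-f) preserved in the remainder."""
    if c == 0.0:
        return make_mixture(donor, patient, depth, f, seed, sample_id)
    n_contam, n_donor, n_patient = contaminated_counts(depth, f, c)
    s_c, s_d, s_p = _child_seeds(seed, 0x32, n=3)
    c_idx = _subsample_indices(contaminant.depth, n_contam, s_c)
    d_idx = _subsample_indices(donor.depth, n_donor, s_d)
    p_idx = _subsample_indices(patient.depth, n_patient, s_p)
    records = (
        _relabel(contaminant, c_idx, "contaminant")
        + _relabel(donor, d_idx, "donor")
        + _relabel(patient, p_idx, "patient")
    )
    reads = ReadSet(sample_id or f"mix_f{f:g}_c{c:g}", records)
    return SimulatedMixture(
        reads=reads,
        true_donor_fraction=n_donor / depth if depth else 0.0,
        contaminant_fraction=n_contam / depth if depth else 0.0,
        depth=depth,
        donor_indices=d_idx,
        patient_indices=p_idx,
        contaminant_indices=c_idx,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class EvaluationMetrics:
    """Accuracy metrics against the known mixture composition.

    ``absolute_error``: |estimated engraftment - true donor share of the sample|.
    ``type2_rate``: donor-origin read mass not recovered as engrafted (false
    negatives).  ``type1_rate``: contaminant-origin read mass wrongly called
    engrafted (false positives); 0 when there is no contaminant.
    Per-read mass = 1 for unique-donor calls, the posterior for ambiguous.
    """

    absolute_error: float
    type2_rate: float
    type1_rate: float


def evaluate(estimate: EngraftmentEstimate, truth: SimulatedMixture) -> EvaluationMetrics:
    posterior = estimate.posterior_donor
    mass_by_origin = {"donor": 0.0, "patient": 0.0, "contaminant": 0.0, "unknown": 0.0}
    count_by_origin = {"donor": 0, "patient": 0, "contaminant": 0, "unknown": 0}
    for rec in truth.reads:
        count_by_origin[rec.true_source] += 1
        pr = estimate.counts.per_read[rec.read_id]
        b = pr.flags.bin
        if b == "unique_donor":
            mass_by_origin[rec.true_source] += 1.0
        elif b == "ambiguous":
            mass_by_origin[rec.true_source] += posterior
    type2 = (
        1.0 - mass_by_origin["donor"] / count_by_origin["donor"]
        if count_by_origin["donor"] > 0
        else 0.0
    )
    type1 = (
        mass_by_origin["contaminant"] / count_by_origin["contaminant"]
        if count_by_origin["contaminant"] > 0
        else 0.0
    )
    return EvaluationMetrics(
        absolute_error=abs(estimate.engrafted - truth.true_donor_fraction),
        type2_rate=min(1.0, max(0.0, type2)),
        type1_rate=min(1.0, max(0.0, type1)),
    )


# ---------------------------------------------------------------------------
# experiment harness


def fragment_genomes(
    genomes: dict[str, str], fragment_length: int | None = None
) -> list[Scaffold]:
    """Truth genomes as scaffolds (a perfect 'assembly').

    With ``fragment_length`` set, genomes are split into fragments of that
    size; reads straddling fragment boundaries then fail to map end-to-end,
    emulating scaffold-level incompleteness.  The default keeps each genome
    whole so that error-free reads always have a full-length placement.
    """
    scaffolds = []
    for name in sorted(genomes):
        seq = genomes[name]
        if fragment_length is None:
            scaffolds.append(Scaffold(name, seq))
            continue
        for n, start in enumerate(range(0, len(seq), fragment_length)):
            chunk = seq[start : start + fragment_length]
            if chunk:
                scaffolds.append(Scaffold(f"{name}_f{n}", chunk))
    return scaffolds


@dataclass
class CohortBundle:
    """Everything one simulated donor/patient pair needs: read pools, truth
    genomes, and databases built from fragmented truth genomes."""

    reads: CohortReads
    donor_db: MagDatabase
    patient_db: MagDatabase

    @property
    def cohort(self) -> SyntheticCohort:
        return self.reads.cohort


def make_bundle(
    params: SyntheticCohortParams, fragment_length: int | None = None
) -> CohortBundle:
    reads = generate_synthetic_cohort(params)
    donor_db = MagDatabase(
        "donor", fragment_genomes(reads.cohort.donor_genomes, fragment_length)
    )
    patient_db = MagDatabase(
        "patient", fragment_genomes(reads.cohort.patient_genomes, fragment_length)
    )
    return CohortBundle(reads=reads, donor_db=donor_db, patient_db=patient_db)


def _classification_from_pools(
    mixture: SimulatedMixture,
    pool_tables: dict[str, tuple],
    sample_id: str,
) -> ClassificationResult:
    """Assemble a mixture's classification from cached pool-vs-database tables.

    Alignment is strictly per read and a mixture is a subset of the pools, so
    looking up each selected read's cached hits is exactly equivalent to
    aligning the mixture afresh (asserted by a test against the direct path).
    """
    per_read: dict[str, PerRead] = {}
    counts = {"unique_donor": 0, "unique_patient": 0, "ambiguous": 0, "unmapped": 0}
    for rec in mixture.reads:
        vs_donor, vs_patient = pool_tables[rec.true_source]
        dhit = vs_donor.hits[rec.read_id]
        phit = vs_patient.hits[rec.read_id]
        flags = ReadFlags(p=phit.aligned, d=dhit.aligned)
        per_read[rec.read_id] = PerRead(flags, dhit.scaffold_id, phit.scaffold_id)
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


def run_mixture_experiment(
    bundles: Sequence[CohortBundle],
    depth: int = DESK_DEPTH,
    fractions: Sequence[float] = FRACTION_GRID,
    identities: Sequence[float] = (1.0,),
    seed: int = 0,
    contaminant_fraction: float = 0.0,
) -> pd.DataFrame:
    """Run the full pipeline over every (pair, donor fraction, identity) cell.

    Each source read pool is aligned against both databases once per identity
    and every mixture's classification is derived from those cached per-read
    results; the same mixtures are reused across identities, mirroring the
    evaluate-one-sample-at-three-identities design.

    Returns one row per combination with the engraftment estimate and the
    provenance-based accuracy metrics.
    """
    rows = []
    for pair_idx, bundle in enumerate(bundles):
        donor_pool, patient_pool, contam_pool, _ = bundle.reads
        mixtures = []
        for f_idx, f in enumerate(fractions):
            mix_seed = _child_seeds(seed, pair_idx, f_idx)[0]
            if contaminant_fraction > 0:
                mix = make_contaminated_mixture(
                    donor_pool, patient_pool, contam_pool,
                    depth, f, contaminant_fraction, mix_seed,
                )
            else:
                mix = make_mixture(donor_pool, patient_pool, depth, f, mix_seed)
            mixtures.append((f, mix))
        for identity in identities:
            dd = align(donor_pool, bundle.donor_db, identity)
            dp = align(donor_pool, bundle.patient_db, identity)
            pp = align(patient_pool, bundle.patient_db, identity)
            pdt = align(patient_pool, bundle.donor_db, identity)
            profile = profile_from_tables(dd, dp, pp, pdt)
            pool_tables = {"donor": (dd, dp), "patient": (pdt, pp)}
            if contaminant_fraction > 0:
                cd = align(contam_pool, bundle.donor_db, identity)
                cp = align(contam_pool, bundle.patient_db, identity)
                pool_tables["contaminant"] = (cd, cp)
            for f, mix in mixtures:
                c = _classification_from_pools(
                    mix, pool_tables, f"pair{pair_idx}_f{f:g}_id{identity:g}"
                )
                est = estimate_from_classification(c, profile)
                metrics = evaluate(est, mix)
                rows.append(
                    {
                        "pair": pair_idx,
                        "f": f,
                        "identity": identity,
                        "estimate": est.engrafted,
                        "true_donor_fraction": mix.true_donor_fraction,
                        "contaminant_fraction": mix.contaminant_fraction,
                        "posterior_donor": est.posterior_donor,
                        "absolute_error": metrics.absolute_error,
                        "type1_rate": metrics.type1_rate,
                        "type2_rate": metrics.type2_rate,
                    }
                )
    return pd.DataFrame(rows)


def run_downsampling_experiment(
    bundle: CohortBundle,
    depths: Sequence[int],
    side: str = "post_only",
    f: float = 0.5,
    identity: float = 1.0,
    seed: int = 0,
    post_depth: int | None = None,
) -> pd.DataFrame:
    """Depth-robustness experiment.

    ``side="post_only"``: the post-treatment mixture is downsampled to each
    depth and classified against full-depth databases — the estimate should
    stay unbiased.  ``side="sources_only"``: the donor and patient read pools
    are downsampled *before* database construction (re-assembled with the
    coverage-based fixture assembler), so shallow sources leave genome regions
    out of the databases and the error grows at the smallest depths.
    """
    if side not in ("post_only", "sources_only"):
        raise ValueError(f"side must be post_only or sources_only, got {side!r}")
    donor_pool, patient_pool, _, cohort = bundle.reads
    post_depth = post_depth or min(donor_pool.depth, patient_pool.depth)
    mix_seed, sub_seed = _child_seeds(seed, 0xD5, n=2)
    mixture = make_mixture(donor_pool, patient_pool, post_depth, f, mix_seed)
    rows = []
    if side == "post_only":
        profile = profile_from_tables(
            align(donor_pool, bundle.donor_db, identity),
            align(donor_pool, bundle.patient_db, identity),
            align(patient_pool, bundle.patient_db, identity),
            align(patient_pool, bundle.donor_db, identity),
        )
        for depth_i, depth in enumerate(depths):
            post = subsample_reads(
                mixture.reads, depth, _child_seeds(sub_seed, depth_i)[0]
            )
            c = classify_reads(
                align(post, bundle.donor_db, identity),
                align(post, bundle.patient_db, identity),
                sample_id=f"post{depth}",
            )
            est = estimate_from_classification(c, profile)
            n_donor = sum(1 for r in post if r.true_source == "donor")
            rows.append(
                {
                    "side": side, "depth": depth, "estimate": est.engrafted,
                    "true_donor_fraction": n_donor / depth if depth else 0.0,
                    "absolute_error": abs(est.engrafted - (n_donor / depth if depth else 0.0)),
                }
            )
    else:
        genomes = cohort.all_genomes()
        for depth_i, depth in enumerate(depths):
            s_d, s_p = _child_seeds(sub_seed, depth_i, n=2)
            donor_sub = subsample_reads(donor_pool, depth, s_d)
            patient_sub = subsample_reads(patient_pool, depth, s_p)
            assembler = CoverageAssembler(genomes)
            donor_db = MagDatabase("donor", assembler.assemble(donor_sub))
            patient_db = MagDatabase("patient", assembler.assemble(patient_sub))
            profile = profile_from_tables(
                align(donor_sub, donor_db, identity),
                align(donor_sub, patient_db, identity),
                align(patient_sub, patient_db, identity),
                align(patient_sub, donor_db, identity),
            )
            c = classify_reads(
                align(mixture.reads, donor_db, identity),
                align(mixture.reads, patient_db, identity),
                sample_id=f"sources{depth}",
            )
            est = estimate_from_classification(c, profile)
            rows.append(
                {
                    "side": side, "depth": depth, "estimate": est.engrafted,
                    "true_donor_fraction": mixture.true_donor_fraction,
                    "absolute_error": abs(est.engrafted - mixture.true_donor_fraction),
                }
            )
    return pd.DataFrame(rows)
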