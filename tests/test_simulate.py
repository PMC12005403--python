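"""Mixture construction, the synthetic cohort generator, and the experiment
harnesses, checked against provenance-label oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from magtrack.backends import align_naive, revcomp
from magtrack.classify import classify_reads, estimate_self_profile
from magtrack.engraftment import estimate_from_classification
from magtrack.simulate import (
    EvaluationMetrics,
    _child_seeds,
    SyntheticCohortParams,
    contaminated_counts,
    evaluate,
    generate_synthetic_cohort,
    make_bundle,
    make_cohort,
    make_contaminated_mixture,
    make_mixture,
    mixture_counts,
    run_downsampling_experiment,
    run_mixture_experiment,
    subsample_reads,
)


class TestSubsample:
    def test_full_depth_is_identity(self, small_bundle):
        pool = small_bundle.reads.donor
        out = subsample_reads(pool, pool.depth, seed=1)
        assert out.read_ids() == pool.read_ids()

    def test_zero(self, small_bundle):
        assert subsample_reads(small_bundle.reads.donor, 0, seed=1).depth == 0

    def test_deterministic_and_order_preserving(self, small_bundle):
        pool = small_bundle.reads.donor
        a = subsample_reads(pool, 100, seed=42)
        b = subsample_reads(pool, 100, seed=42)
        assert a.read_ids() == b.read_ids()
        original_order = {rid: i for i, rid in enumerate(pool.read_ids())}
        positions = [original_order[rid] for rid in a.read_ids()]
        assert positions == sorted(positions)

    def test_overdraw_is_error(self, small_bundle):
        with pytest.raises(ValueError, match="cannot draw"):
            subsample_reads(small_bundle.reads.donor, 10**9, seed=1)


class TestMixtureArithmetic:
    def test_full_scale_bookkeeping(self):
        """At 8.75 M depth and 20% donor: 1.75 M donor + 7 M patient reads."""
        assert mixture_counts(8_750_000, 0.2) == (1_750_000, 7_000_000)

    @given(depth=st.integers(0, 10**7), f=st.floats(0, 1))
    def test_counts_partition_depth(self, depth, f):
        n_d, n_p = mixture_counts(depth, f)
        assert n_d + n_p == depth and n_d >= 0 and n_p >= 0

    def test_contamination_composition(self):
        """f=0.5, c=0.2 at depth 1000: 200 contaminant, 400 donor, 400 patient."""
        assert contaminated_counts(1000, 0.5, 0.2) == (200, 400, 400)

    @given(depth=st.integers(0, 10**6), f=st.floats(0, 1), c=st.floats(0, 0.99))
    def test_contaminated_counts_partition_depth(self, depth, f, c):
        n_c, n_d, n_p = contaminated_counts(depth, f, c)
        assert n_c + n_d + n_p == depth


class TestMakeMixture:
    def test_composition_is_exact_by_construction(self, small_bundle):
        r = small_bundle.reads
        mix = make_mixture(r.donor, r.patient, 1000, 0.3, seed=5)
        labels = [rec.true_source for rec in mix.reads]
        assert labels.count("donor") == 300
        assert labels.count("patient") == 700
        assert mix.true_donor_fraction == 0.3
        assert mix.reads.depth == 1000

    @pytest.mark.parametrize("f,label", [(0.0, "patient"), (1.0, "donor")])
    def test_pure_boundaries(self, small_bundle, f, label):
        r = small_bundle.reads
        mix = make_mixture(r.donor, r.patient, 500, f, seed=5)
        assert all(rec.true_source == label for rec in mix.reads)

    def test_contaminated_mixture_composition(self, small_bundle):
        r = small_bundle.reads
        mix = make_contaminated_mixture(r.donor, r.patient, r.contaminant,
                                        1000, 0.5, 0.2, seed=5)
        labels = [rec.true_source for rec in mix.reads]
        assert labels.count("contaminant") == 200
        assert labels.count("donor") == labels.count("patient") == 400
        assert mix.contaminant_fraction == 0.2

    def test_zero_contamination_reduces_to_plain_mixture(self, small_bundle):
        r = small_bundle.reads
        plain = make_mixture(r.donor, r.patient, 500, 0.4, seed=9)
        contam = make_contaminated_mixture(r.donor, r.patient, r.contaminant,
                                           500, 0.4, 0.0, seed=9)
        assert contam.reads.read_ids() == plain.reads.read_ids()

    def test_boundary_full_donor_with_contaminant(self, small_bundle):
        r = small_bundle.reads
        mix = make_contaminated_mixture(r.donor, r.patient, r.contaminant,
                                        1000, 1.0, 0.2, seed=5)
        labels = [rec.true_source for rec in mix.reads]
        assert labels.count("contaminant") == 200
        assert labels.count("donor") == 800
        assert labels.count("patient") == 0

    def test_insufficient_pool_depth_is_error(self, small_bundle):
        r = small_bundle.reads
        with pytest.raises(ValueError, match="cannot draw"):
            make_mixture(r.donor, r.patient, 10**7, 0.5, seed=1)


class TestSyntheticCohort:
    def test_fully_shared_sources_are_identical(self):
        cohort = make_cohort(SyntheticCohortParams(
            n_genomes=2, genome_length=2_000, shared_fraction=1.0, seed=3))
        for i in range(2):
            assert cohort.patient_genomes[f"patientG{i}"] == cohort.donor_genomes[f"donorG{i}"]

    def test_disjoint_sources_share_no_kmers(self):
        cohort = make_cohort(SyntheticCohortParams(
            n_genomes=2, genome_length=5_000, shared_fraction=0.0, seed=4))
        k = 21
        donor_kmers = set()
        for g in cohort.donor_genomes.values():
            for s in (g, revcomp(g)):
                donor_kmers |= {s[i:i + k] for i in range(len(s) - k + 1)}
        for g in cohort.patient_genomes.values():
            patient_kmers = {g[i:i + k] for i in range(len(g) - k + 1)}
            patient_kmers |= {revcomp(g)[i:i + k] for i in range(len(g) - k + 1)}
            assert not donor_kmers & patient_kmers

    def test_error_rate_gives_expected_read_identity(self):
        """error_rate 0.01 at 100 bp: mean per-read identity vs the truth
        window ~ 0.99 (binomial expectation over 10^4 reads)."""
        params = SyntheticCohortParams(
            n_genomes=1, genome_length=20_000, read_length=100,
            error_rate=0.01, n_reads=10_000, seed=6,
        )
        reads = generate_synthetic_cohort(params)
        genome = reads.cohort.donor_genomes["donorG0"]
        mismatches = 0
        for rec in reads.donor:
            window = genome[rec.position:rec.position + 100]
            if rec.strand == "-":
                window = revcomp(window)
            mismatches += sum(a != b for a, b in zip(rec.sequence, window))
        mean_identity = 1.0 - mismatches / (100 * reads.donor.depth)
        assert mean_identity == pytest.approx(0.99, abs=0.001)

    def test_deterministic_per_seed(self):
        params = SyntheticCohortParams(n_genomes=1, genome_length=2_000,
                                       n_reads=100, seed=8)
        a = generate_synthetic_cohort(params)
        b = generate_synthetic_cohort(params)
        assert a.cohort.donor_genomes == b.cohort.donor_genomes
        assert [r.sequence for r in a.donor] == [r.sequence for r in b.donor]
        assert [r.read_id for r in a.contaminant] == [r.read_id for r in b.contaminant]


class TestEvaluate:
    def test_perfect_estimate_scores_zero(self, small_bundle):
        b = small_bundle
        mix = make_mixture(b.reads.donor, b.reads.patient, 500, 0.5, seed=2)
        c = classify_reads(
            align_naive(mix.reads, b.donor_db, 1.0),
            align_naive(mix.reads, b.patient_db, 1.0),
        )
        profile = estimate_self_profile(
            b.reads.donor.subset(range(300)), b.reads.patient.subset(range(300)),
            b.donor_db, b.patient_db, 1.0,
        )
        est = estimate_from_classification(c, profile)
        m = evaluate(est, mix)
        assert m.absolute_error == 0.0
        assert m.type2_rate == 0.0
        assert m.type1_rate == 0.0

    def test_absolute_error_arithmetic(self):
        assert abs(0.45 - 0.50) == pytest.approx(0.05)  # definition sanity
        m = EvaluationMetrics(absolute_error=0.05, type2_rate=0.0, type1_rate=0.0)
        assert m.absolute_error == pytest.approx(0.05)


class TestMixtureExperiment:
    def test_cached_experiment_matches_direct_pipeline(self, shared_bundle):
        """One mixture run through the pool-cached harness must equal a direct
        align-classify-estimate run on the materialised mixture reads."""
        b = shared_bundle
        table = run_mixture_experiment([b], depth=800, fractions=[0.4],
                                       identities=[1.0], seed=31)
        mix = make_mixture(b.reads.donor, b.reads.patient, 800, 0.4,
                           seed=_child_seeds(31, 0, 0)[0])
        c = classify_reads(
            align_naive(mix.reads, b.donor_db, 1.0),
            align_naive(mix.reads, b.patient_db, 1.0),
        )
        profile = estimate_self_profile(
            b.reads.donor, b.reads.patient, b.donor_db, b.patient_db, 1.0
        )
        est = estimate_from_classification(c, profile)
        assert table.iloc[0].estimate == pytest.approx(est.engrafted, abs=1e-12)

    def test_monotone_response_in_donor_fraction(self, shared_bundle):
        table = run_mixture_experiment([shared_bundle], depth=1500,
                                       identities=[1.0], seed=13)
        estimates = table.sort_values("f").estimate.to_numpy()
        assert (np.diff(estimates) >= -1e-9).all()

    def test_placebo_analogue_near_zero(self, small_bundle):
        """Post reads drawn only from the patient: engraftment ~ 0."""
        table = run_mixture_experiment([small_bundle], depth=1000,
                                       fractions=[0.0], identities=[1.0], seed=17)
        assert table.iloc[0].estimate == pytest.approx(0.0, abs=1e-9)

    def test_experiment_determinism(self, small_bundle):
        kwargs = dict(depth=600, fractions=[0.3, 0.7], identities=[1.0], seed=23)
        a = run_mixture_experiment([small_bundle], **kwargs)
        b = run_mixture_experiment([small_bundle], **kwargs)
        assert a.equals(b)


class TestDownsampling:
    def test_full_depth_post_matches_baseline(self, small_bundle):
        pool_depth = small_bundle.reads.donor.depth
        table = run_downsampling_experiment(
            small_bundle, depths=[pool_depth, 500], side="post_only", seed=3
        )
        assert table.iloc[0].absolute_error == pytest.approx(0.0, abs=1e-9)

    def test_post_only_estimate_unbiased_across_depths(self, small_bundle):
        table = run_downsampling_experiment(
            small_bundle, depths=[2000, 1000, 500], side="post_only", seed=3
        )
        # error-free disjoint sources: the estimate equals the realised
        # subsample composition exactly at every depth
        assert (table.absolute_error < 1e-9).all()

    def test_shallow_sources_increase_error(self, small_bundle):
        table = run_downsampling_experiment(
            small_bundle, depths=[2000, 400, 100], side="sources_only", seed=3
        )
        errors = table.set_index("depth").absolute_error
        assert errors[100] > errors[2000]
        assert errors[100] >= errors[400] >= errors[2000] - 1e-9

    def test_invalid_side_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="side"):
            run_downsampling_experiment(small_bundle, [100], side="both")
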