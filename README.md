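# magtrack

Quantifies **donor microbiota engraftment** after fecal microbiota
transplantation (FMT) or encapsulated microbiota transplant therapy (MTT)
from shotgun metagenomic sequencing, for researchers running transplant
trials who need the pharmacokinetics of a live biotherapeutic: how much of
the post-treatment gut community is donor-derived, how much of the
patient's own baseline community persists, and how much is novel.

## Method

The donor sample and the patient's pre-treatment (baseline) sample are each
assembled into metagenome-assembled-genome (MAG) scaffold databases.  Every
read of a post-treatment sample is aligned against both databases at a
minimum identity (1 − edit distance / read length; default 1.00) and binned
four ways: uniquely donor-aligned, uniquely patient-aligned, ambiguous
(aligned to both), or unmapped.

Ambiguous reads are reallocated with Bayes' theorem.  For read *i*, let
*z<sub>i</sub>* be the hidden event "truly donor-derived" and (*p<sub>i</sub>*, *d<sub>i</sub>*) the
observed alignment flags against the patient and donor databases:

> P(z | p, d) = P(p, d | z) P(z) / [ P(p, d | z) P(z) + P(p, d | ¬z) P(¬z) ]

The priors P(z), P(¬z) are the proportions of the post sample's reads
uniquely assigned to each source.  The likelihoods are estimated
empirically by aligning each *source* sample's own reads against both
databases — the self-alignment profile — whose both-aligned rates say how
often a read truly from one source looks ambiguous.  The same profile's
self-unmapped rates give the unmapped read mass expected from sequencing
error and unassembled rare strains; only unmapped mass above that
expectation is called **novel** (diet/environment acquisition).  The final
output is engrafted / persistent / novel proportions plus per-MAG engrafted
read counts for downstream binning and taxonomy.

The package includes the full simulation machinery used to validate the
method: synthetic donor/patient/contaminant communities with controllable
genome overlap and read error, mixtures at known donor fractions (0–100% in
10% steps), 20% contaminant spiking, depth downsampling, and
provenance-label scoring of type I/II error — so the method is testable
end-to-end with no external data or binaries (a built-in exhaustive-
equivalent aligner replaces Bowtie 2 at desk scale; external
metaSPAdes/Bowtie 2/minimap2 adapters are provided for real data).

## Worked example

```python
from magtrack.backends import align
from magtrack.classify import classify_reads, estimate_self_profile
from magtrack.engraftment import estimate_from_classification
from magtrack.simulate import SyntheticCohortParams, make_bundle, make_mixture

bundle = make_bundle(SyntheticCohortParams(
    n_genomes=2, genome_length=10_000, read_length=100, n_reads=5_000, seed=1))
profile = estimate_self_profile(
    bundle.reads.donor, bundle.reads.patient,
    bundle.donor_db, bundle.patient_db, min_identity=1.0)
mix = make_mixture(bundle.reads.donor, bundle.reads.patient,
                   depth=5_000, f=0.6, seed=2)   # truly 60% donor
c = classify_reads(align(mix.reads, bundle.donor_db, 1.0),
                   align(mix.reads, bundle.patient_db, 1.0), sample_id="week8")
est = estimate_from_classification(c, profile)
print(est.engrafted, est.persistent, est.novel)
```

prints

```
bins: unique_donor=3000 unique_patient=2000 ambiguous=0 unmapped=0
engrafted=0.6000 persistent=0.4000 novel=0.0000
```

— with disjoint, error-free sources every read classifies uniquely and the
engrafted proportion recovers the simulated 60% donor fraction exactly.
`examples/` contains this and three more narrative scripts (dose-response
recovery with 30% shared genome content, contaminant type I error across
identity thresholds, and depth robustness); each prints the numbers it
computes and what they mean.

A thin CLI mirrors the library for file-based studies:

```bash
magtrack build-db --donor d1.fq.gz,d2.fq.gz --baseline b.fq.gz --out DB
magtrack track --db DB --post wk8.fq.gz --label wk8 --out results
magtrack simulate mixture --pairs 1 --depth 5000 --out mix.tsv
```

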