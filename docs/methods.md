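# Methods

## Model

A post-treatment stool metagenome is modelled as a mixture of three read
sources: the donor community, the patient's pre-treatment (baseline)
community, and everything else ("novel": diet, environment, contact).  The
two known sources are represented by per-sample MAG databases — unbinned
metaSPAdes-style scaffolds assembled from the donor and baseline reads
themselves — so no external reference database is involved and reads from
strains absent from public references are not discarded.  Scaffolds are
deliberately not length-filtered: short scaffolds carry rare-strain signal
and dropping them would bias engraftment against rare strains.

Each post-treatment read is aligned against both databases and binned by
its flag pair (d = donor hit, p = patient hit): unique-donor, unique-
patient, ambiguous (both), unmapped (neither).  Alignment identity is
1 − edit distance / read length, end-to-end over the whole read; a read is
"aligned" iff its best hit reaches the configured minimum identity.  Only
the best hit per read per database is retained (ties broken toward the
first scaffold in database order, then the leftmost placement, then the
forward strand — deterministic by construction).

### Ambiguous reads

The posterior that an ambiguous read is donor-derived is

    P(z|p,d) = L_d π_d / (L_d π_d + L_p π_p)

with priors π from the proportions of the sample's *uniquely* assigned
reads, and likelihoods L_d, L_p estimated by aligning each source sample's
own reads against both databases and taking the proportion aligning to
both (denominator: all reads of that source sample, read literally so the
estimate is auditable).  Because every ambiguous read carries the identical
observation (p = d = true), the posterior is one scalar per sample, and the
ambiguous bin is split fractionally — the deterministic expectation —
rather than sampled read by read.  Per-read labels in the engrafted-reads
report use posterior > 0.5, ties to the patient.  When both likelihoods are
zero there is no information and the posterior falls back to the prior
(with a warning); the case only matters when the ambiguous bin is empty
anyway, where the posterior is reported but allocates nothing.

### Unmapped correction

Some unmapped mass is expected even for reads truly from a source:
sequencing errors at strict identity, and strains too rare to assemble.
The self-alignment profile quantifies this as each source's self-unmapped
rate.  The expected unmapped fraction of a post sample is the mapped-mass-
weighted average of the two rates (expected dropout comes from whichever
source is actually present, in proportion to its presence); unmapped mass
above expectation is novel.  Expected-unmapped mass is redistributed to
donor/patient proportionally to the mapped-mass split.  Two guards keep the
output a proper composition: novel mass is clamped at zero (a negative
novel fraction is uninterpretable; clamping is flagged on the estimate),
and the redistributed mass is capped at the observed unmapped count, so
engrafted + persistent + novel = 1 holds exactly for every input.  The raw
expected-unmapped count is reported so the correction can be audited.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_identity` | 1.00 | alignment identity threshold; 1.00 minimises type I error (false engraftment from related strains), 0.98 trades it for lower type II error under sequencing noise |
| posterior tie rule | > 0.5 | ambiguous read listed as engrafted only if the donor is strictly more likely |
| mixture rounding | nearest, remainder→patient | f·depth donor reads rounded to nearest integer, patient takes the remainder |

Paired-end mates are classified independently: the prior/likelihood
arithmetic is per-read, and pair-aware rescue would change denominators
silently.  Mates sharing an identifier are disambiguated with a mate
suffix at FASTQ parsing.

## Alignment backends

The built-in aligner is ungapped and exhaustive-equivalent: it seeds each
read with m+1 disjoint k-mers (m = allowed mismatches at the threshold) and
verifies candidates by vectorised Hamming comparison on both strands.  By
the pigeonhole principle any placement with ≤ m mismatches contains an
exact seed, so the thresholded decision is identical to a literal scan of
every offset; an `exhaustive=True` mode performs that literal scan and the
test suite asserts equivalence on randomised cases.  Reads shorter than
8 seed bases fall back to the exhaustive path.  Adapters for minimap2
(short-read preset) and Bowtie 2 (end-to-end, default sensitivity, best
alignment) shell out to the binaries and parse SAM; soft/hard-clipped bases
count as edits so identity semantics stay end-to-end across backends.  The
naive and minimap2 backends are cross-checked for identical partitions on
exact-match reads.

Assembly adapters: metaSPAdes via subprocess for real data; a fixture
adapter (caller-supplied scaffolds) for tests; and a coverage-based
synthetic assembler that, given simulation truth genomes and per-read
provenance, emits exactly the genome segments covered by reads.  The last
reproduces the one assembly property the pipeline's depth behaviour depends
on — uncovered regions cannot enter the database — without reimplementing
de Bruijn assembly, and is only meaningful on simulated data.

## What the simulator emulates — and what it does not

Synthetic cohorts are random genomes (default two 25 kb genomes per source,
150 bp reads) with a controllable fraction of content shared verbatim
between donor and patient, and an optional contaminant carrying diverged
(default 1% per-base) copies of donor content.  Disjoint regions are
screened for chance shared 21-mers and regenerated if any are found, so
"no shared content" holds exactly at read length.  Reads are sampled
uniformly from both strands with substitution-only errors — no indels, so
the ungapped aligner remains an exact oracle; indel robustness is the
external aligners' job.  Quality strings are a constant placeholder.

Real stool metagenomes differ in ways the simulator does not attempt:
hundreds of species at uneven abundance, strain-level SNP structure between
related donors and patients, instrument-specific error profiles, and
imperfect real assemblies.  Passing the simulation suite therefore
demonstrates the correctness of the classification, posterior and
correction arithmetic under known truth — not field accuracy on clinical
samples, which depends on assembly quality and community overlap.

Replication-scale defaults follow the published simulation design
(8.75 million reads per sample, 15 donor/patient pairs × 11 fractions =
165 samples, 20% contamination of the 50/50 mixture; one report of the
design also states 10 million reads and 16 pairs — the depth is a
parameter and the harness follows the 15-pair/165-sample figure).  Tests
and the acceptance script run a desk-scale analogue: two 50 kb sources and
20,000-read samples, sizes chosen so binomial noise on a 20k-read sample
(SE ≈ 0.35%) is far below the 2% recovery tolerance being checked.

## Experiment harnesses

`run_mixture_experiment` aligns each source read pool against both
databases once per identity and derives every mixture's classification by
subsetting the cached per-read results; since alignment is per-read and
mixtures are subsamples of the pools this is exact, and a test asserts
equality with a direct uncached run.  Mixtures are generated once and
reused across identity thresholds, mirroring the evaluate-one-sample-at-
three-identities design.  All randomness flows through seeded NumPy
generators with deterministic child seeds, so identical seeds reproduce
identical cohorts, mixtures and estimates byte-for-byte.

Evaluation metrics use the simulation provenance labels directly:
type II = donor-origin read mass not recovered as engrafted,
type I = contaminant-origin mass called engrafted, with per-read mass 1
for unique-donor calls and the posterior for ambiguous calls.

## Known limitations

- High donor/patient overlap (related or autologous donors) inflates the
  ambiguous bin and can bias engraftment low; 100% identity is recommended
  there.
- The posterior conditions only on the two boolean flags, so all ambiguous
  reads in a sample share one posterior; per-MAG conditioning is not
  modelled.
- Shallow *source* sequencing degrades the databases and the estimate;
  shallow post-treatment sequencing does not (the downsampling harness
  quantifies both).
- The built-in aligner is ungapped and desk-scale; real studies should use
  the external adapters.
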