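"""Bayesian allocation of ambiguous reads between donor and patient sources.

For an ambiguous read i, let z_i be the hidden event "the read truly comes
from the donor" and let (p_i, d_i) be the observed alignment flags against
the patient and donor databases (both true, by definition of ambiguous).
Bayes' theorem gives

    P(z | p, d) = P(p, d | z) P(z) / [ P(p, d | z) P(z) + P(p, d | not z) P(not z) ]

The likelihoods P(p, d | z) and P(p, d | not z) are the empirical rates at
which reads from the donor and patient samples respectively align to *both*
databases (the self-alignment profile); the priors are the proportions of
the post-treatment sample's reads uniquely assigned to each source.

Because every ambiguous read carries the identical observation (p=T, d=T),
the posterior is a single scalar per sample, and the ambiguous bin is split
fractionally — the deterministic expected allocation — rather than sampled
read by read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .classify import ClassificationResult, SelfAlignmentProfile


@dataclass(frozen=True)
class SourcePriors:
    """P(z) and P(not z): the prior source probabilities for an ambiguous read."""

    prior_donor: float
    prior_patient: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.prior_donor <= 1.0):
            raise ValueError(f"prior_donor={self.prior_donor} outside [0, 1]")
        if abs(self.prior_donor + self.prior_patient - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")


@dataclass(frozen=True)
class PosteriorAllocation:
    """Fractional split of the ambiguous bin into donor/patient expected counts."""

    posterior_donor: float
    ambiguous_to_donor: float
    ambiguous_to_patient: float


def estimate_priors(c: ClassificationResult) -> SourcePriors:
    """Priors from the proportions of reads uniquely assigned to each source.

    With no uniquely assigned reads at all there is no information; fall back
    to the uninformative (0.5, 0.5) with a warning.
    """
    n_unique = c.n_unique_donor + c.n_unique_patient
    if n_unique == 0:
        warnings.warn(
            f"sample {c.sample_id!r}: no uniquely assigned reads; "
            "falling back to uniform priors",
            stacklevel=2,
        )
        return SourcePriors(0.5, 0.5)
    prior_donor = c.n_unique_donor / n_unique
    return SourcePriors(prior_donor, 1.0 - prior_donor)


def posterior_donor(priors: SourcePriors, profile: SelfAlignmentProfile) -> float:
    """Posterior probability that an ambiguous read's true source is the donor.

    L_d * pi_d / (L_d * pi_d + L_p * pi_p), with L_d/L_p the both-aligned
    rates from the self-alignment profile.  A zero denominator carries no
    likelihood information, so the prior is returned with a warning.
    """
    num = profile.donor_both_rate * priors.prior_donor
    den = num + profile.patient_both_rate * priors.prior_patient
    if den == 0.0:
        warnings.warn(
            "both both-aligned likelihoods are zero; posterior falls back to the prior",
            stacklevel=2,
        )
        return priors.prior_donor
    return num / den


def allocate_ambiguous(n_ambiguous: int, posterior: float) -> PosteriorAllocation:
    """Split the ambiguous count by the posterior (expected counts, exact mass)."""
    if n_ambiguous < 0:
        raise ValueError(f"n_ambiguous must be >= 0, got {n_ambiguous}")
    if not (0.0 <= posterior <= 1.0):
        raise ValueError(f"posterior={posterior} outside [0, 1]")
    to_donor = n_ambiguous * posterior
    return PosteriorAllocation(
        posterior_donor=posterior,
        ambiguous_to_donor=to_donor,
        ambiguous_to_patient=n_ambiguous - to_donor,
    )
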