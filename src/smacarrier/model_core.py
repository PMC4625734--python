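"""Conjugate beta-binomial model for the SMN1 read proportion.

The quantity of interest is ``pi``, the probability that a read aligning to
the SMN1/SMN2 locus pair originates from SMN1.  With ``r`` total SMN reads
and a (possibly coverage-scaled, hence non-integer) SMN1 count ``d``, a
Beta(alpha, beta) prior yields the posterior

    pi | d, r  ~  Beta(alpha + d, r - d + beta).

The carrier probability is the posterior CDF at a threshold just above 1/3
(default 0.38, allowing a 5 % type-I margin over the exact 1-SMN1:2-SMN2
ratio).  Samples are categorised by where their equal-tailed credible
interval falls relative to that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "PriorSpec",
    "PosteriorSummary",
    "posterior_params",
    "carrier_probability",
    "credible_interval",
    "classify_ternary",
    "classify_binary",
    "summarize_sample",
    "JEFFREYS",
    "UNIFORM",
]

CATEGORIES = ("likely", "possible", "unlikely")


@dataclass(frozen=True)
class PriorSpec:
    """Beta prior plus the decision parameters of the carrier model.

    Parameters
    ----------
    alpha, beta:
        Beta prior shape parameters.  Jeffreys (1/2, 1/2) is the default
        noninformative choice; the uniform prior (1, 1) behaves almost
        identically for realistic read counts.
    carrier_threshold:
        Upper bound on ``pi`` defining a carrier-compatible read proportion.
    credible_level:
        Mass of the equal-tailed posterior credible interval.
    """

    alpha: float = 0.5
    beta: float = 0.5
    carrier_threshold: float = 0.38
    credible_level: float = 0.95

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("prior shapes alpha and beta must be positive")
        if not 0 < self.carrier_threshold < 1:
            raise ValueError("carrier_threshold must be in (0, 1)")
        if not 0 < self.credible_level < 1:
            raise ValueError("credible_level must be in (0, 1)")


JEFFREYS = PriorSpec(alpha=0.5, beta=0.5)
UNIFORM = PriorSpec(alpha=1.0, beta=1.0)


@dataclass
class PosteriorSummary:
    """Per-sample posterior report for the SMN1 read proportion."""

    sample_id: str
    d_scaled: float
    r_total: int
    pi_hat: float | None
    pi_hat_scaled: float | None
    alpha_post: float
    beta_post: float
    carrier_prob: float
    ci_low: float
    ci_high: float
    category: str
    binary_carrier: bool
    epsilon_met: bool = True
    scaling_factor: float = 1.0
    d_total: int = 0
    loci_used: tuple[str, ...] = field(default_factory=tuple)
    low_coverage: bool = False


def _check_counts(d_scaled: float, r_total: int) -> None:
    if d_scaled < 0:
        raise ValueError(f"d_scaled must be nonnegative, got {d_scaled}")
    if r_total < 0:
        raise ValueError(f"r_total must be nonnegative, got {r_total}")
    if d_scaled > r_total:
        raise ValueError(
            f"d_scaled ({d_scaled}) cannot exceed r_total ({r_total})"
        )


def posterior_params(
    d_scaled: float, r_total: int, prior: PriorSpec = JEFFREYS
) -> tuple[float, float]:
    """Posterior Beta shapes ``(alpha + d, r - d + beta)``.

    ``d_scaled`` may be non-integer: coverage scaling multiplies the raw
    SMN1 count by a factor in [0, 1] and the conjugate update accepts the
    resulting pseudo-count directly.
    """
    _check_counts(d_scaled, r_total)
    return prior.alpha + d_scaled, r_total - d_scaled + prior.beta


def carrier_probability(
    d_scaled: float, r_total: int, prior: PriorSpec = JEFFREYS
) -> float:
    """P(pi <= carrier_threshold | d, r): posterior CDF at the threshold.

    With r = 0 this is the prior CDF — a sample with no informative reads
    gets the prior carrier probability, not an error.
    """
    a, b = posterior_params(d_scaled, r_total, prior)
    return float(stats.beta.cdf(prior.carrier_threshold, a, b))


def credible_interval(
    d_scaled: float, r_total: int, prior: PriorSpec = JEFFREYS
) -> tuple[float, float]:
    """Equal-tailed credible interval for ``pi`` at ``prior.credible_level``."""
    a, b = posterior_params(d_scaled, r_total, prior)
    tail = (1.0 - prior.credible_level) / 2.0
    lo = float(stats.beta.ppf(tail, a, b))
    hi = float(stats.beta.ppf(1.0 - tail, a, b))
    return lo, hi


def classify_ternary(
    ci_low: float, ci_high: float, carrier_threshold: float = 0.38
) -> str:
    """likely / possible / unlikely from the interval's position vs the cutoff.

    Entirely below the threshold → "likely" carrier; spanning it →
    "possible"; entirely above → "unlikely".
    """
    if ci_low > ci_high:
        raise ValueError(f"ci_low ({ci_low}) exceeds ci_high ({ci_high})")
    if ci_high < carrier_threshold:
        return "likely"
    if ci_low > carrier_threshold:
        return "unlikely"
    return "possible"


def classify_binary(carrier_prob: float) -> bool:
    """Binary carrier call: more likely than not (strictly > 1/2)."""
    return carrier_prob > 0.5


def summarize_sample(
    sample_id: str,
    d_scaled: float,
    r_total: int,
    prior: PriorSpec = JEFFREYS,
    *,
    d_total: int | None = None,
    epsilon_met: bool = True,
    scaling_factor: float = 1.0,
    loci_used: tuple[str, ...] = ("a", "b", "c"),
) -> PosteriorSummary:
    """Full posterior report for one sample from its (scaled) pooled counts."""
    a, b = posterior_params(d_scaled, r_total, prior)
    prob = carrier_probability(d_scaled, r_total, prior)
    lo, hi = credible_interval(d_scaled, r_total, prior)
    if d_total is None:
        d_total = int(round(d_scaled / scaling_factor)) if scaling_factor else 0
    pi_hat = d_total / r_total if r_total > 0 else None
    pi_hat_scaled = d_scaled / r_total if r_total > 0 else None
    return PosteriorSummary(
        sample_id=sample_id,
        d_scaled=d_scaled,
        r_total=r_total,
        pi_hat=pi_hat,
        pi_hat_scaled=pi_hat_scaled,
        alpha_post=a,
        beta_post=b,
        carrier_prob=prob,
        ci_low=lo,
        ci_high=hi,
        category=classify_ternary(lo, hi, prior.carrier_threshold),
        binary_carrier=classify_binary(prob),
        epsilon_met=epsilon_met,
        scaling_factor=scaling_factor,
        d_total=d_total,
        loci_used=tuple(loci_used),
    )
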