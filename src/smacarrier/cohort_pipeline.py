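"""End-to-end cohort analysis: depths → pooling → scaling → posterior.

One call applies the full protocol to a cohort: per-sample epsilon-rule
pooling of the six-locus depths, cohort-wide control-gene selection and
coverage scaling, then the conjugate posterior, carrier probability,
credible interval and categorisation per sample.  The calling path is
deterministic — identical inputs and configuration reproduce the result
bit for bit.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import coverage_scaling, locus_pooling, model_core, population_stats
from .coverage_scaling import GeneCoverageMatrix, HousekeepingSelection
from .locus_pooling import SampleLocusDepths
from .model_core import PosteriorSummary, PriorSpec

__all__ = ["CohortResult", "CohortSummary", "run_cohort", "summarize_cohort"]

#: SMN reads per sample below which results are flagged as under the
#: recommended coverage for 90 % carrier sensitivity (they are still scored;
#: low coverage widens the credible interval rather than invalidating it).
RECOMMENDED_MIN_READS = 350


@dataclass
class CohortResult:
    summaries: list[PosteriorSummary]
    selection: HousekeepingSelection
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample report table (one row per sample)."""
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "epsilon_met": s.epsilon_met,
                    "loci_used": "".join(s.loci_used),
                    "theta_hat": s.scaling_factor,
                    "d_total": s.d_total,
                    "d_scaled": s.d_scaled,
                    "r_total": s.r_total,
                    "pi_hat": s.pi_hat,
                    "pi_hat_scaled": s.pi_hat_scaled,
                    "carrier_prob": s.carrier_prob,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "category": s.category,
                    "binary_carrier": s.binary_carrier,
                    "coverage_flag": "below_recommended" if s.low_coverage else "ok",
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CohortSummary:
    n_samples: int
    n_likely: int
    n_possible: int
    n_unlikely: int
    n_binary_carriers: int
    carrier_frequency: float
    ci_low: float
    ci_high: float


def _digest(parts: Sequence[str]) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def run_cohort(
    depths: Sequence[SampleLocusDepths],
    coverage: GeneCoverageMatrix,
    prior: PriorSpec = model_core.JEFFREYS,
    epsilon: float = 0.10,
    percentile: float = 5.0,
    fail_fraction: float = 0.10,
    top_n: int = 10,
    z_bar_reference: pd.Series | None = None,
    min_reads: int = RECOMMENDED_MIN_READS,
) -> CohortResult:
    """Score every sample present in both the depth and coverage tables.

    Samples found in only one of the two inputs are dropped with a warning
    (inner join); an empty intersection is an error.  Scaling is applied to
    the pooled SMN1 count (D′ = θ̂·D) for every sample, including those that
    failed the epsilon condition.
    """
    depth_ids = [d.sample_id for d in depths]
    if len(set(depth_ids)) != len(depth_ids):
        raise ValueError("duplicate sample ids in depth input")
    common = [sid for sid in depth_ids if sid in set(coverage.sample_ids)]
    dropped = sorted(
        set(depth_ids).symmetric_difference(coverage.sample_ids)
    )
    if dropped:
        warnings.warn(
            f"{len(dropped)} sample(s) present in only one input were "
            f"dropped: {dropped[:10]}{'...' if len(dropped) > 10 else ''}",
            stacklevel=2,
        )
    if not common:
        raise ValueError("no samples shared between depth and coverage inputs")

    cov = GeneCoverageMatrix(coverage.data.loc[common])
    if z_bar_reference is not None:
        # reference mode: the control-gene set is fixed by the reference
        # panel, so each sample's result is independent of the rest of the
        # cohort
        genes = [g for g in z_bar_reference.index if g in cov.data.columns]
        if not genes:
            raise ValueError("no reference z̄ gene is present in the coverage table")
        selection = HousekeepingSelection(
            selected_genes=genes,
            cv_coverage=pd.Series(dtype=float),
            cv_z=pd.Series(dtype=float),
            percentile=percentile,
            fail_fraction=fail_fraction,
            top_n=top_n,
        )
    else:
        selection = coverage_scaling.select_housekeeping(
            cov, percentile=percentile, fail_fraction=fail_fraction, top_n=top_n
        )
    factors = coverage_scaling.scaling_factor(cov, selection, z_bar_reference)

    by_id = {d.sample_id: d for d in depths}
    summaries = []
    for sid in common:
        pooled = locus_pooling.pool_counts(by_id[sid], epsilon)
        theta = float(factors.theta_hat[sid])
        d_scaled = coverage_scaling.scale_counts(theta, pooled)
        s = model_core.summarize_sample(
            sid,
            d_scaled,
            pooled.r_total,
            prior,
            d_total=pooled.d_total,
            epsilon_met=pooled.epsilon_met,
            scaling_factor=theta,
            loci_used=pooled.loci_used,
        )
        s.low_coverage = pooled.r_total < min_reads
        summaries.append(s)

    metadata = {
        "prior_alpha": prior.alpha,
        "prior_beta": prior.beta,
        "carrier_threshold": prior.carrier_threshold,
        "credible_level": prior.credible_level,
        "epsilon": epsilon,
        "percentile": percentile,
        "fail_fraction": fail_fraction,
        "top_n": top_n,
        "mode": "reference" if z_bar_reference is not None else "cohort",
        "min_reads": min_reads,
        "n_samples": len(common),
        "selected_genes": ",".join(selection.selected_genes),
        "depth_digest": _digest(
            [
                f"{d.sample_id}:{[d.smn1[l] for l in 'abc']}:{[d.smn2[l] for l in 'abc']}"
                for d in depths
            ]
        ),
        "coverage_digest": _digest([coverage.data.to_csv()]),
    }
    return CohortResult(summaries=summaries, selection=selection, metadata=metadata)


def summarize_cohort(result: CohortResult, level: float = 0.95) -> CohortSummary:
    """Ternary category counts plus binary carrier frequency with exact CI."""
    if not result.summaries:
        raise ValueError("empty cohort result")
    cats = [s.category for s in result.summaries]
    n = len(cats)
    n_carriers = sum(s.binary_carrier for s in result.summaries)
    lo, hi = population_stats.exact_proportion_ci(n_carriers, n, level)
    return CohortSummary(
        n_samples=n,
        n_likely=cats.count("likely"),
        n_possible=cats.count("possible"),
        n_unlikely=cats.count("unlikely"),
        n_binary_carriers=n_carriers,
        carrier_frequency=n_carriers / n,
        ci_low=lo,
        ci_high=hi,
    )
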