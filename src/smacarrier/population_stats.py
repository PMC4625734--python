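"""Population carrier-frequency statistics and MLPA concordance.

Observed cohort carrier frequencies are compared with published population
frequencies using the two-sided exact binomial test (minimum-likelihood
convention, as in R's ``binom.test``) and exact Clopper-Pearson confidence
intervals.  MLPA (multiplex ligation-dependent probe amplification) SMN1
exon-7 ratios are categorised with the standard 0.7 / 1.3 copy-loss and
copy-gain thresholds and cross-tabulated against sequencing-based calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .model_core import PosteriorSummary

__all__ = [
    "FrequencyComparison",
    "MlpaRecord",
    "exact_binomial_test",
    "exact_proportion_ci",
    "compare_frequencies",
    "mlpa_category",
    "concordance_table",
]


@dataclass
class FrequencyComparison:
    population: str
    n_samples: int
    n_carriers: int
    p_obs: float
    ci_low: float
    ci_high: float
    p_published: float
    p_value: float


@dataclass
class MlpaRecord:
    """SMN1 exon-7 to reference ratio with its copy-number category."""

    sample_id: str
    smn1_ratio: float
    category: str = ""

    def __post_init__(self) -> None:
        if self.smn1_ratio < 0:
            raise ValueError("MLPA ratio must be nonnegative")
        self.category = mlpa_category(self.smn1_ratio)


def _check(n_carriers: int, n_samples: int) -> None:
    if not 0 <= n_carriers <= n_samples:
        raise ValueError(
            f"need 0 <= n_carriers ({n_carriers}) <= n_samples ({n_samples})"
        )


def exact_binomial_test(n_carriers: int, n_samples: int, p0: float) -> float:
    """Two-sided exact binomial p-value, minimum-likelihood convention.

    Sums P(X = x) over all outcomes no more likely than the observed one
    (the convention of R's ``binom.test`` and ``scipy.stats.binomtest``),
    capped at 1.
    """
    _check(n_carriers, n_samples)
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(
        stats.binomtest(n_carriers, n_samples, p0, alternative="two-sided").pvalue
    )


def exact_proportion_ci(
    n_carriers: int, n_samples: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided confidence interval for a proportion."""
    _check(n_carriers, n_samples)
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    ci = stats.binomtest(n_carriers, n_samples, 0.5).proportion_ci(
        confidence_level=level, method="exact"
    )
    return float(ci.low), float(ci.high)


def compare_frequencies(
    populations: pd.DataFrame, level: float = 0.95
) -> list[FrequencyComparison]:
    """Carrier-frequency comparison for each row of a population table.

    ``populations`` needs columns population, n_samples, n_carriers,
    p_published.
    """
    required = {"population", "n_samples", "n_carriers", "p_published"}
    missing = required - set(populations.columns)
    if missing:
        raise ValueError(f"population table lacks columns: {sorted(missing)}")
    out = []
    for row in populations.itertuples(index=False):
        n, x = int(row.n_samples), int(row.n_carriers)
        lo, hi = exact_proportion_ci(x, n, level)
        out.append(
            FrequencyComparison(
                population=str(row.population),
                n_samples=n,
                n_carriers=x,
                p_obs=x / n,
                ci_low=lo,
                ci_high=hi,
                p_published=float(row.p_published),
                p_value=exact_binomial_test(x, n, float(row.p_published)),
            )
        )
    return out


def mlpa_category(smn1_ratio: float) -> str:
    """Copy-number category from the SMN1:reference ratio.

    Below 0.7 → "loss" (carrier or affected); above 1.3 → "gain"; otherwise
    "normal".
    """
    if smn1_ratio < 0:
        raise ValueError("MLPA ratio must be nonnegative")
    if smn1_ratio < 0.7:
        return "loss"
    if smn1_ratio > 1.3:
        return "gain"
    return "normal"


def concordance_table(
    posteriors: list[PosteriorSummary], mlpa: list[MlpaRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate sequencing carrier calls against MLPA categories.

    Joins on sample_id; unmatched ids on either side are reported in the
    discordance frame (reason "unmatched") rather than raised.  Returns
    (crosstab, details) where details lists every joined sample with both
    calls plus the unmatched ids, flagging discordant samples (MLPA loss
    without a sequencing carrier call, or the reverse).
    """
    post_by_id = {p.sample_id: p for p in posteriors}
    mlpa_by_id = {m.sample_id: m for m in mlpa}
    rows = []
    for sid in sorted(set(post_by_id) | set(mlpa_by_id)):
        p = post_by_id.get(sid)
        m = mlpa_by_id.get(sid)
        if p is None or m is None:
            rows.append(
                {
                    "sample_id": sid,
                    "mlpa_category": m.category if m else None,
                    "seq_binary_carrier": p.binary_carrier if p else None,
                    "seq_category": p.category if p else None,
                    "carrier_prob": p.carrier_prob if p else None,
                    "status": "unmatched",
                }
            )
            continue
        discordant = (m.category == "loss") != p.binary_carrier
        rows.append(
            {
                "sample_id": sid,
                "mlpa_category": m.category,
                "seq_binary_carrier": p.binary_carrier,
                "seq_category": p.category,
                "carrier_prob": p.carrier_prob,
                "status": "discordant" if discordant else "concordant",
            }
        )
    details = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "mlpa_category",
            "seq_binary_carrier",
            "seq_category",
            "carrier_prob",
            "status",
        ],
    )
    joined = details[details["status"] != "unmatched"]
    if joined.empty:
        xtab = pd.DataFrame()
    else:
        xtab = pd.crosstab(joined["mlpa_category"], joined["seq_binary_carrier"])
    return xtab, details
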