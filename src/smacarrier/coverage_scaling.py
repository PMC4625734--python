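"""Coverage-based scaling of SMN1 read counts.

Read-ratio methods alone cannot tell a 1-SMN1:1-SMN2 genotype (4 total SMN
copies, non-carrier) from a 2-total-copy genotype whose reads also split
~1:1 (a carrier).  Total SMN coverage relative to stably covered control
("housekeeping") genes resolves this: for each sample the ratio

    z_ki = (cov_SMN1 + cov_SMN2) / cov_gene_k

is compared against its cohort mean z̄_k, and the scaling factor

    θ̂_i = mean_k( z_ki / z̄_k ),  capped at 1,

down-weights the observed SMN1 count (D′ = θ̂·D) for samples whose total
SMN coverage is below the cohort norm.  Control genes are chosen for low
coefficient of variation in coverage and in z_ki after a minimum-coverage
filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locus_pooling import PooledCounts

__all__ = [
    "GeneCoverageMatrix",
    "HousekeepingSelection",
    "ScalingFactors",
    "coverage_filter",
    "select_housekeeping",
    "scaling_factor",
    "scale_counts",
]

SMN_GENES = ("SMN1", "SMN2")


@dataclass
class GeneCoverageMatrix:
    """Per-sample mean coverage for SMN1, SMN2 and candidate control genes.

    Wraps a samples × genes DataFrame of nonnegative mean coverages that
    must contain SMN1 and SMN2 columns; every other column is a candidate
    control gene.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [g for g in SMN_GENES if g not in self.data.columns]
        if missing:
            raise ValueError(f"coverage matrix lacks required columns: {missing}")
        if len(self.data) < 1:
            raise ValueError("coverage matrix must contain at least one sample")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("coverages must be nonnegative")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def candidate_genes(self) -> list[str]:
        return [g for g in self.data.columns if g not in SMN_GENES]

    def smn_total(self) -> pd.Series:
        """Per-sample SMN1 + SMN2 mean coverage."""
        return self.data["SMN1"] + self.data["SMN2"]

    def z_ratios(self, genes: list[str]) -> pd.DataFrame:
        """z_ki = (cov_SMN1 + cov_SMN2) / cov_gene_k for the given genes."""
        h = self.data[genes]
        if (h.to_numpy() == 0).any():
            bad = [
                (s, g)
                for s in self.data.index
                for g in genes
                if self.data.at[s, g] == 0
            ]
            sample, gene = bad[0]
            raise ValueError(
                f"control gene {gene!r} has zero coverage in sample {sample!r}; "
                "it cannot serve as a coverage reference"
            )
        return self.smn_total().to_numpy()[:, None] / h


@dataclass
class HousekeepingSelection:
    selected_genes: list[str]
    cv_coverage: pd.Series  # CV of mean coverage per surviving gene
    cv_z: pd.Series  # CV of z_ki per surviving gene
    percentile: float = 5.0
    fail_fraction: float = 0.10
    top_n: int = 10


@dataclass
class ScalingFactors:
    z: pd.DataFrame  # samples × selected genes
    z_bar: pd.Series  # cohort column means
    theta_hat: pd.Series  # per-sample, capped at 1


def coverage_filter(
    cov: GeneCoverageMatrix,
    percentile: float = 5.0,
    fail_fraction: float = 0.10,
) -> list[str]:
    """Drop candidate genes with recurrently low within-sample coverage.

    For each sample the ``percentile``-th percentile of that sample's
    candidate-gene coverages is the bar; a gene "fails" in a sample when its
    coverage is strictly below it.  Genes failing in at least
    ``fail_fraction`` of samples are removed.
    """
    genes = cov.candidate_genes
    if not genes:
        raise ValueError("no candidate control genes in the coverage matrix")
    mat = cov.data[genes].to_numpy(dtype=float)
    bar = np.percentile(mat, percentile, axis=1, keepdims=True)
    fail_rate = (mat < bar).mean(axis=0)
    return [g for g, f in zip(genes, fail_rate) if f < fail_fraction]


def _cv(frame: pd.DataFrame) -> pd.Series:
    """Coefficient of variation per column: sample std (ddof=1) over mean."""
    if len(frame) < 2:
        return pd.Series(0.0, index=frame.columns)
    return frame.std(ddof=1) / frame.mean()


def select_housekeeping(
    cov: GeneCoverageMatrix,
    percentile: float = 5.0,
    fail_fraction: float = 0.10,
    top_n: int = 10,
) -> HousekeepingSelection:
    """Pick ``2*top_n`` control genes by two stability criteria.

    Survivors of the coverage filter are ranked (ascending) by CV of mean
    coverage and, separately, by CV of z_ki, and the top ``top_n`` of each
    list are merged.  When more than 2*top_n genes survive, overlap between
    the two lists is backfilled from the next-ranked genes, taking
    alternately from the two rankings, until 2*top_n distinct genes are
    chosen; with fewer survivors the selection is just the (deduplicated)
    union of the two top-n lists.  Ties in CV break by gene id.
    """
    survivors = coverage_filter(cov, percentile, fail_fraction)
    if len(survivors) < top_n:
        raise ValueError(
            f"only {len(survivors)} genes survive the coverage filter but "
            f"top_n={top_n}; relax percentile/fail_fraction or supply more "
            "candidate genes"
        )
    cv_cov = _cv(cov.data[survivors])
    cv_z = _cv(cov.z_ratios(survivors))
    rank_cov = sorted(survivors, key=lambda g: (cv_cov[g], g))
    rank_z = sorted(survivors, key=lambda g: (cv_z[g], g))

    if len(survivors) >= 2 * top_n:
        target = 2 * top_n
        lists = [rank_cov, rank_z]
    else:
        target = len(survivors)
        lists = [rank_cov[:top_n], rank_z[:top_n]]
    chosen: list[str] = []
    iters = [iter(lists[0]), iter(lists[1])]
    exhausted = [False, False]
    # round-robin through both rankings; duplicates skip, which backfills
    # overlap with the next-best gene from either criterion
    i = 0
    while len(chosen) < target and not all(exhausted):
        try:
            g = next(iters[i % 2])
        except StopIteration:
            exhausted[i % 2] = True
            i += 1
            continue
        if g not in chosen:
            chosen.append(g)
        i += 1
    return HousekeepingSelection(
        selected_genes=chosen,
        cv_coverage=cv_cov,
        cv_z=cv_z,
        percentile=percentile,
        fail_fraction=fail_fraction,
        top_n=top_n,
    )


def scaling_factor(
    cov: GeneCoverageMatrix,
    selection: HousekeepingSelection,
    z_bar_reference: pd.Series | None = None,
) -> ScalingFactors:
    """Per-sample scaling factor θ̂ from SMN-to-control coverage ratios.

    By default z̄_k is the mean over the analysed cohort itself (the
    procedure is cohort-based).  ``z_bar_reference`` substitutes precomputed
    cohort means for single-sample or reference-panel use; a warning notes
    the departure from the cohort design.
    """
    z = cov.z_ratios(selection.selected_genes)
    if z_bar_reference is not None:
        missing = [g for g in selection.selected_genes if g not in z_bar_reference]
        if missing:
            raise ValueError(f"reference z̄ lacks selected genes: {missing}")
        z_bar = z_bar_reference[selection.selected_genes].astype(float)
        warnings.warn(
            "using reference z̄ values; the scaling procedure is designed "
            "to be cohort-based",
            stacklevel=2,
        )
    else:
        if len(z) == 1:
            warnings.warn(
                "single-sample cohort: z̄ equals the sample's own z, forcing "
                "θ̂ = 1; scaling is uninformative",
                stacklevel=2,
            )
        z_bar = z.mean(axis=0)
    theta = (z / z_bar).mean(axis=1).clip(upper=1.0)
    return ScalingFactors(z=z, z_bar=z_bar, theta_hat=theta)


def scale_counts(theta_hat_i: float, pooled: PooledCounts) -> float:
    """Scaled SMN1 pseudo-count D′ = θ̂ · D (r is unchanged)."""
    if not 0.0 <= theta_hat_i <= 1.0:
        raise ValueError(f"theta_hat must be in [0, 1], got {theta_hat_i}")
    return theta_hat_i * pooled.d_total
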