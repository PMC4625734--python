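"""Synthetic cohorts with known SMN1/SMN2 diplotypes.

Generates the depth tables, gene-coverage matrices and (optionally) mini
BAM files consumed by the rest of the package, with a truth table recording
each sample's copy numbers, true SMN1 read proportion and carrier status —
so pooling, scaling, posterior inference and frequency estimation are all
testable end to end without external data.

Generative model: each locus's total SMN read count is Poisson with mean
proportional to total SMN copy number, and the SMN1 share is binomial with
the genotype's read proportion — the same binomial read model the posterior
assumes.  Gene-level mean coverages are gamma-distributed around their
expectations (CV set by ``noise``), with SMN gene coverage proportional to
copy number.  It does not emulate alignment artifacts, reference bias or
GC effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage_scaling import GeneCoverageMatrix
from .locus_pooling import GRCH37_LOCI, LOCUS_LABELS, LocusSet, SampleLocusDepths

__all__ = [
    "SyntheticSampleSpec",
    "generate_cohort",
    "generate_discordant_sample",
    "write_depth_bam",
]


@dataclass(frozen=True)
class SyntheticSampleSpec:
    """One sample's genotype and sequencing parameters.

    ``pi_override`` forces the SMN1 read proportion away from the
    copy-number ratio, representing recombinant/hybrid SMN alleles whose
    exonic and intronic bases disagree with the canonical genes (the reads
    of such a sample can split ~1:1 while it carries ≤1 functional SMN1).
    """

    sample_id: str
    smn1_copies: int = 2
    smn2_copies: int = 2
    mean_locus_depth_per_copy: float = 125.0
    housekeeping_mean: float = 100.0
    noise: float = 0.05  # coverage CV; 0 switches to the deterministic limit
    pi_override: float | None = None

    def __post_init__(self) -> None:
        if self.smn1_copies < 0 or self.smn2_copies < 0:
            raise ValueError("copy numbers must be nonnegative integers")
        if self.mean_locus_depth_per_copy <= 0 or self.housekeeping_mean <= 0:
            raise ValueError("depth and coverage means must be positive")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")
        if self.pi_override is not None and not 0 <= self.pi_override <= 1:
            raise ValueError("pi_override must be in [0, 1]")

    @property
    def total_copies(self) -> int:
        return self.smn1_copies + self.smn2_copies

    @property
    def pi_true(self) -> float:
        if self.pi_override is not None:
            return self.pi_override
        if self.total_copies == 0:
            return 0.0
        return self.smn1_copies / self.total_copies

    @property
    def is_carrier(self) -> bool:
        return self.smn1_copies <= 1


def _gamma_around(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    if cv == 0 or mean == 0:
        return np.full(size, float(mean))
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size)


def generate_cohort(
    specs: Sequence[SyntheticSampleSpec],
    n_housekeeping_genes: int = 30,
    seed: int = 0,
) -> tuple[list[SampleLocusDepths], GeneCoverageMatrix, pd.DataFrame]:
    """Simulate depth table, coverage matrix and truth table for a cohort.

    With ``noise = 0`` a sample's depths are the rounded expectations
    (deterministic limit); otherwise locus totals are Poisson and SMN1
    shares binomial.  SMN1/SMN2 gene mean coverage is
    ``housekeeping_mean * copies / 2`` (a canonical 2-copy gene matches the
    control genes), so total SMN coverage tracks total copy number and the
    downstream scaling factor should recover ≈ total_copies / 4.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in specs")
    rng = np.random.default_rng(seed)
    gene_names = [f"HK{j:03d}" for j in range(n_housekeeping_genes)]

    depths: list[SampleLocusDepths] = []
    cov_rows = []
    truth_rows = []
    for spec in specs:
        lam = spec.total_copies * spec.mean_locus_depth_per_copy
        smn1: dict[str, int] = {}
        smn2: dict[str, int] = {}
        for label in LOCUS_LABELS:
            if spec.noise == 0:
                r_l = int(round(lam))
                d_l = int(round(r_l * spec.pi_true))
            else:
                r_l = int(rng.poisson(lam))
                d_l = int(rng.binomial(r_l, spec.pi_true)) if r_l else 0
            smn1[label] = d_l
            smn2[label] = r_l - d_l
        depths.append(SampleLocusDepths(spec.sample_id, smn1, smn2))

        c1_mean = spec.housekeeping_mean * spec.smn1_copies / 2.0
        c2_mean = spec.housekeeping_mean * spec.smn2_copies / 2.0
        row = {
            "SMN1": float(_gamma_around(rng, c1_mean, spec.noise, ())),
            "SMN2": float(_gamma_around(rng, c2_mean, spec.noise, ())),
        }
        hk = _gamma_around(rng, spec.housekeeping_mean, spec.noise, len(gene_names))
        row.update(dict(zip(gene_names, hk)))
        cov_rows.append(row)

        truth_rows.append(
            {
                "sample_id": spec.sample_id,
                "smn1_copies": spec.smn1_copies,
                "smn2_copies": spec.smn2_copies,
                "total_copies": spec.total_copies,
                "pi_true": spec.pi_true,
                "theta_expected": min(1.0, spec.total_copies / 4.0),
                "is_carrier": spec.is_carrier,
            }
        )

    coverage = GeneCoverageMatrix(pd.DataFrame(cov_rows, index=pd.Index(ids, name="sample_id")))
    truth = pd.DataFrame(truth_rows)
    return depths, coverage, truth


def generate_discordant_sample(
    spec: SyntheticSampleSpec,
    locus_bias: dict[str, float],
) -> SampleLocusDepths:
    """Deterministic sample whose flanking-locus proportions are shifted.

    ``locus_bias`` maps locus labels ("a" and/or "c") to an additive shift
    of the SMN1 read proportion at that locus relative to the exon-7 locus,
    for constructing samples that pass or fail the epsilon consistency rule
    by a known margin.  Depths are rounded expectations; the realised
    proportion shift is exact whenever bias × locus depth is integral.
    """
    bad = set(locus_bias) - {"a", "c"}
    if bad:
        raise ValueError(f"locus_bias applies to flanking loci a/c only, got {bad}")
    n = int(round(spec.total_copies * spec.mean_locus_depth_per_copy))
    smn1: dict[str, int] = {}
    smn2: dict[str, int] = {}
    for label in LOCUS_LABELS:
        pi_l = min(1.0, max(0.0, spec.pi_true + locus_bias.get(label, 0.0)))
        d_l = int(round(n * pi_l))
        smn1[label] = d_l
        smn2[label] = n - d_l
    return SampleLocusDepths(spec.sample_id, smn1, smn2)


def write_depth_bam(
    depths: SampleLocusDepths,
    path: str,
    locus_set: LocusSet = GRCH37_LOCI,
    read_length: int = 40,
    extra_duplicates: int = 0,
    extra_secondary: int = 0,
) -> None:
    """Emit a sorted, indexed mini-BAM realising the given per-locus depths.

    Reads carry placeholder sequence — only positions and flags matter to
    the depth-extraction adapter.  ``extra_duplicates`` / ``extra_secondary``
    add flagged reads at every locus that a correct adapter must not count.
    The default read length (40) is below the 49-bp spacing of the two
    closest paralog-defining positions, so reads planted for one locus never
    bleed depth into another.
    """
    if read_length > 49:
        raise ValueError("read_length must be <= 49 to keep planted loci independent")
    import pysam

    chrom = locus_set.loci[0].chromosome
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": 181_538_259}],
    }
    records = []
    serial = 0
    for locus in locus_set.loci:
        depth = (
            depths.smn1[locus.label] if locus.gene == "SMN1" else depths.smn2[locus.label]
        )
        pos0 = locus.position - 1
        for j in range(depth + extra_duplicates + extra_secondary):
            a = pysam.AlignedSegment()
            a.query_name = f"read{serial}"
            serial += 1
            a.query_sequence = "A" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            a.reference_id = 0
            # stagger starts while keeping the locus inside the read
            a.reference_start = max(0, pos0 - (j % read_length))
            a.cigarstring = f"{read_length}M"
            a.mapping_quality = 60
            flag = 0
            if j >= depth:
                flag |= 0x400 if j < depth + extra_duplicates else 0x100
            a.flag = flag
            records.append(a)
    records.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for a in records:
            bam.write(a)
    pysam.index(path)
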