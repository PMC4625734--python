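"""Pooling per-locus SMN1/SMN2 read depths into a single (D, r) pair.

Three base positions distinguish canonical SMN1 from SMN2 on GRCh37 chr5:
the exon-7 gene-defining c.840C>T site (locus ``b``) flanked by two intronic
paralogous sequence variants (``a`` and ``c``).  When the SMN1 read
proportion at the flanking loci agrees with the exon-7 proportion to within
``epsilon`` (default 0.10), depths are summed across all three loci;
otherwise only the gene-defining exon-7 locus is trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LOCUS_LABELS",
    "Locus",
    "LocusSet",
    "GRCH37_LOCI",
    "SampleLocusDepths",
    "PooledCounts",
    "locus_proportions",
    "pool_counts",
]

LOCUS_LABELS = ("a", "b", "c")


@dataclass(frozen=True)
class Locus:
    gene: str  # "SMN1" or "SMN2"
    label: str  # "a", "b" (exon-7 gene-defining) or "c"
    chromosome: str
    position: int  # 1-based


@dataclass(frozen=True)
class LocusSet:
    """The six paralog-defining positions, one per (gene, label) pair."""

    build: str
    loci: tuple[Locus, ...]

    def __post_init__(self) -> None:
        pairs = {(l.gene, l.label) for l in self.loci}
        if len(self.loci) != 6 or len(pairs) != 6:
            raise ValueError("LocusSet requires exactly one locus per (gene, label)")

    def position(self, gene: str, label: str) -> Locus:
        for l in self.loci:
            if l.gene == gene and l.label == label:
                return l
        raise KeyError((gene, label))


#: Default GRCh37/hg19 coordinates of the three SMN1 paralog-defining
#: positions and their SMN2 counterparts.
GRCH37_LOCI = LocusSet(
    build="GRCh37",
    loci=(
        Locus("SMN1", "a", "chr5", 70_247_724),
        Locus("SMN1", "b", "chr5", 70_247_773),
        Locus("SMN1", "c", "chr5", 70_247_921),
        Locus("SMN2", "a", "chr5", 69_372_304),
        Locus("SMN2", "b", "chr5", 69_372_353),
        Locus("SMN2", "c", "chr5", 69_372_501),
    ),
)


@dataclass
class SampleLocusDepths:
    """Read depths for one sample at the six paralog-defining positions."""

    sample_id: str
    smn1: dict[str, int]  # label -> depth
    smn2: dict[str, int]

    def __post_init__(self) -> None:
        for d in (self.smn1, self.smn2):
            if set(d) != set(LOCUS_LABELS):
                raise ValueError(f"depths must cover loci {LOCUS_LABELS}, got {set(d)}")
            for label, v in d.items():
                if v < 0 or int(v) != v:
                    raise ValueError(
                        f"sample {self.sample_id}: depth at locus {label} "
                        f"must be a nonnegative integer, got {v}"
                    )

    def r_at(self, label: str) -> int:
        return self.smn1[label] + self.smn2[label]


@dataclass
class PooledCounts:
    sample_id: str
    d_total: int  # SMN1 reads over the loci used
    r_total: int  # total SMN reads over the loci used
    epsilon_met: bool
    loci_used: tuple[str, ...]


def locus_proportions(
    depths: SampleLocusDepths,
) -> tuple[float | None, float | None, float | None]:
    """Observed SMN1 read proportion at each locus; None where depth is zero."""
    out = []
    for label in LOCUS_LABELS:
        r = depths.r_at(label)
        out.append(depths.smn1[label] / r if r > 0 else None)
    return tuple(out)


def pool_counts(depths: SampleLocusDepths, epsilon: float = 0.10) -> PooledCounts:
    """Apply the epsilon consistency rule and pool depths.

    The condition is met when both flanking proportions are defined and lie
    within ``epsilon`` of the exon-7 proportion (inclusive: a deviation of
    exactly ``epsilon`` passes).  On failure — including any undefined
    proportion — only the exon-7 locus ``b`` is used; if locus b itself has
    no reads the result is (0, 0), handled downstream as a no-data sample.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pi_a, pi_b, pi_c = locus_proportions(depths)
    met = (
        pi_a is not None
        and pi_b is not None
        and pi_c is not None
        and abs(pi_b - pi_a) <= epsilon
        and abs(pi_b - pi_c) <= epsilon
    )
    if met:
        d = sum(depths.smn1[l] for l in LOCUS_LABELS)
        r = sum(depths.r_at(l) for l in LOCUS_LABELS)
        return PooledCounts(depths.sample_id, d, r, True, LOCUS_LABELS)
    return PooledCounts(
        depths.sample_id, depths.smn1["b"], depths.r_at("b"), False, ("b",)
    )
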