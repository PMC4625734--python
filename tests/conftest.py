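import pytest

from smacarrier import SyntheticSampleSpec, generate_cohort


@pytest.fixture(scope="session")
def canonical_cohort():
    """100 canonical [2:2] samples at ~500x per-locus SMN depth."""
    specs = [SyntheticSampleSpec(sample_id=f"C{i:03d}") for i in range(100)]
    return generate_cohort(specs, seed=42)


@pytest.fixture(scope="session")
def mixed_cohort():
    """Canonical background plus planted carriers and copy-variant samples.

    Planted genotypes: [0:1] and [0:2] (SMA-affected read patterns),
    [1:2] (classic carrier, pi=1/3), a 2-total-copy sample whose reads
    split 1:1 (recombinant-allele carrier, the MLPA-confirmed rescue case),
    and a 3-total-copy pi=1/2 carrier.
    """
    specs = [SyntheticSampleSpec(sample_id=f"B{i:03d}") for i in range(95)]
    specs += [
        SyntheticSampleSpec(sample_id="AFF01", smn1_copies=0, smn2_copies=1),
        SyntheticSampleSpec(sample_id="AFF02", smn1_copies=0, smn2_copies=2),
        SyntheticSampleSpec(sample_id="CAR12", smn1_copies=1, smn2_copies=2),
        SyntheticSampleSpec(
            sample_id="REC2C", smn1_copies=1, smn2_copies=1, pi_override=0.5
        ),
        SyntheticSampleSpec(
            sample_id="REC3C", smn1_copies=1, smn2_copies=2, pi_override=0.5
        ),
    ]
    return generate_cohort(specs, seed=7)
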