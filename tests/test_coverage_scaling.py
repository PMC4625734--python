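"""Control-gene selection and the SMN coverage scaling factor."""

import numpy as np
import pandas as pd
import pytest

from smacarrier import (
    GeneCoverageMatrix,
    PooledCounts,
    coverage_filter,
    scale_counts,
    scaling_factor,
    select_housekeeping,
)


def matrix(df):
    return GeneCoverageMatrix(df)


def make_cov(n_samples=10, n_genes=40, value=100.0, smn=200.0):
    genes = {f"G{j:02d}": [value] * n_samples for j in range(n_genes)}
    df = pd.DataFrame({"SMN1": [smn / 2] * n_samples, "SMN2": [smn / 2] * n_samples, **genes})
    df.index = pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id")
    return matrix(df)


def test_requires_smn_columns():
    df = pd.DataFrame({"SMN1": [1.0], "G1": [1.0]})
    with pytest.raises(ValueError, match="SMN2"):
        matrix(df)


def test_identical_coverage_all_genes_survive():
    cov = make_cov()
    assert coverage_filter(cov) == cov.candidate_genes


def test_zero_coverage_gene_removed():
    cov = make_cov()
    cov.data["G00"] = 0.0
    assert "G00" not in coverage_filter(cov)


def test_filter_counts_failures_across_samples():
    # one gene below the within-sample 5th percentile in exactly 2/10 samples
    cov = make_cov()
    cov.data.loc[["s0", "s1"], "G05"] = 1.0
    assert "G05" not in coverage_filter(cov, fail_fraction=0.10)
    # failing in 0 samples keeps it
    cov2 = make_cov()
    assert "G05" in coverage_filter(cov2, fail_fraction=0.10)


def test_filter_requires_candidates():
    df = pd.DataFrame({"SMN1": [1.0], "SMN2": [1.0]})
    with pytest.raises(ValueError):
        coverage_filter(matrix(df))


def test_select_prefers_low_cv():
    rng = np.random.default_rng(0)
    n = 20
    df = pd.DataFrame(
        {
            "SMN1": 100.0,
            "SMN2": 100.0,
            "g1": 100 + rng.normal(0, 1, n),
            "g2": 100 + rng.normal(0, 2, n),
            "g3": 100 + rng.normal(0, 50, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    sel = select_housekeeping(matrix(df), top_n=2, percentile=0.0)
    assert set(sel.selected_genes) == {"g1", "g2"}


def test_tie_break_by_gene_id():
    cov = make_cov(n_genes=30)  # all CVs are zero
    sel = select_housekeeping(cov, top_n=10)
    assert sel.selected_genes == sorted(cov.candidate_genes)[:20]


def test_backfill_when_criteria_overlap_or_disagree():
    # construct genes where coverage-CV and z-CV rankings differ: SMN total
    # varies across samples, so genes correlated with it have low z-CV but
    # high coverage-CV
    rng = np.random.default_rng(1)
    n = 50
    smn = 200 * (1 + 0.2 * rng.normal(size=n))
    cols = {"SMN1": smn / 2, "SMN2": smn / 2}
    for j in range(12):  # stable coverage, poor z stability
        cols[f"flat{j:02d}"] = 100 + 0.1 * rng.normal(size=n)
    for j in range(12):  # coverage tracks SMN, so z is stable
        cols[f"trak{j:02d}"] = smn / 2 * (1 + 0.001 * rng.normal(size=n))
    df = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    sel = select_housekeeping(matrix(df), top_n=10, percentile=0.0)
    assert len(sel.selected_genes) == 20
    assert len(set(sel.selected_genes)) == 20
    # both families are represented
    assert any(g.startswith("flat") for g in sel.selected_genes)
    assert any(g.startswith("trak") for g in sel.selected_genes)


def test_select_errors_when_too_few_survivors():
    cov = make_cov(n_genes=5)
    with pytest.raises(ValueError, match="relax"):
        select_housekeeping(cov, top_n=10)


def test_canonical_cohort_scales_to_one():
    cov = make_cov()
    sel = select_housekeeping(cov, top_n=10)
    fac = scaling_factor(cov, sel)
    assert np.allclose(fac.z.to_numpy(), 2.0)
    assert np.allclose(fac.theta_hat.to_numpy(), 1.0)


def test_single_sample_theta_is_one_with_warning():
    cov = make_cov(n_samples=1)
    sel_basis = make_cov()  # selection computed on a proper cohort
    sel = select_housekeeping(sel_basis, top_n=10)
    with pytest.warns(UserWarning, match="single-sample"):
        fac = scaling_factor(cov, sel)
    assert fac.theta_hat.iloc[0] == 1.0


def test_high_coverage_sample_capped_at_one():
    cov = make_cov(n_samples=101)
    # one sample with 1.25x the canonical SMN total coverage
    cov.data.loc["s100", ["SMN1", "SMN2"]] = 125.0
    sel = select_housekeeping(cov, top_n=10)
    fac = scaling_factor(cov, sel)
    # raw value 1.25 / (mean z over cohort / 2) > 1, capped
    assert fac.theta_hat["s100"] == 1.0
    assert (fac.theta_hat <= 1.0).all()


def test_three_copy_sample_scaled_to_about_three_quarters():
    cov = make_cov(n_samples=101)
    cov.data.loc["s100", ["SMN1", "SMN2"]] = [75.0, 75.0]  # 3 of 4 copies
    sel = select_housekeeping(cov, top_n=10)
    fac = scaling_factor(cov, sel)
    # z = 1.5 against a cohort mean pulled slightly below 2 by this sample
    expected = 1.5 / ((100 * 2.0 + 1.5) / 101)
    assert fac.theta_hat["s100"] == pytest.approx(expected, abs=1e-12)
    assert fac.theta_hat["s100"] == pytest.approx(0.75, abs=0.01)


def test_zero_control_coverage_is_an_error_naming_the_gene():
    cov = make_cov()
    sel = select_housekeeping(cov, top_n=10)
    cov.data.loc["s3", "G00"] = 0.0
    with pytest.raises(ValueError, match="G00.*s3"):
        scaling_factor(cov, sel)


def test_reference_mode_overrides_cohort_means():
    cov = make_cov(n_samples=3)
    sel = select_housekeeping(make_cov(), top_n=10)
    z_ref = pd.Series(4.0, index=sel.selected_genes)  # cohort mean z of 4
    with pytest.warns(UserWarning, match="reference"):
        fac = scaling_factor(cov, sel, z_bar_reference=z_ref)
    # sample z = 2 against reference 4 halves theta
    assert np.allclose(fac.theta_hat.to_numpy(), 0.5)


def test_scale_counts_identity_and_halving():
    pooled = PooledCounts("s", 300, 600, True, ("a", "b", "c"))
    assert scale_counts(1.0, pooled) == 300
    assert scale_counts(0.5, pooled) == 150
    with pytest.raises(ValueError):
        scale_counts(1.2, pooled)


def test_scaling_never_increases_pi_hat(mixed_cohort):
    from smacarrier import pool_counts

    depths, coverage, _ = mixed_cohort
    sel = select_housekeeping(coverage, top_n=10)
    fac = scaling_factor(coverage, sel)
    for d in depths:
        pooled = pool_counts(d)
        if pooled.r_total == 0:
            continue
        theta = float(fac.theta_hat[d.sample_id])
        assert scale_counts(theta, pooled) <= pooled.d_total


def test_scaled_and_raw_proportions_rank_correlate():
    """Ranks of pi-hat survive scaling on a mostly-canonical cohort.

    The premise of tight rank agreement is that the scaling factor is a
    small, stable per-sample correction: control genes are selected for
    minimal z-variability, so their residual coverage CV sits well below
    the read-sampling noise of pi-hat.  The cohort here is mostly canonical
    with a minority of carriers and SMN2-duplication genotypes whose scaled
    proportions stay distinct from the canonical cloud.
    """
    from scipy import stats as sps

    from smacarrier import SyntheticSampleSpec, generate_cohort, pool_counts

    rng = np.random.default_rng(17)
    genotypes = [(2, 2), (1, 2), (2, 3), (3, 2)]
    weights = [0.85, 0.05, 0.05, 0.05]
    specs = []
    for i in range(150):
        s1, s2 = genotypes[rng.choice(len(genotypes), p=weights)]
        specs.append(
            SyntheticSampleSpec(
                sample_id=f"s{i:03d}", smn1_copies=s1, smn2_copies=s2, noise=0.01
            )
        )
    depths, coverage, _ = generate_cohort(specs, seed=18)
    sel = select_housekeeping(coverage, top_n=10)
    fac = scaling_factor(coverage, sel)
    raw, scaled = [], []
    for d in depths:
        pooled = pool_counts(d)
        theta = float(fac.theta_hat[d.sample_id])
        raw.append(pooled.d_total / pooled.r_total)
        scaled.append(scale_counts(theta, pooled) / pooled.r_total)
    rho = sps.spearmanr(raw, scaled).statistic
    assert rho >= 0.96
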