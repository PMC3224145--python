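"""Animal-model association scan: REML recovery, GLS-vs-OLS oracle,
null calibration, P3D-vs-exact agreement and the trend test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dupgwas.mixed_gwas import (
    EigenA,
    FixedDesign,
    GwasResult,
    RankError,
    VarianceComponents,
    build_fixed_design,
    fit_null_model,
    run_gwas,
    snp_association,
    trend_test,
)
from dupgwas.pedigree import RelationshipMatrix
from dupgwas.synthetic_data import SimulationConfig, simulate_population


def identity_A(n):
    return RelationshipMatrix([f"a{i}" for i in range(n)], np.eye(n))


def ols_oracle(y, X, g):
    """Plain OLS of y on [X g] with the classical t-test on the g column."""
    M = np.column_stack([X, g])
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    n, k = M.shape
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(M.T @ M)
    b = beta[-1]
    se = np.sqrt(cov[-1, -1])
    t = b / se
    p = 2 * stats.t.sf(abs(t), n - k)
    return b, se, t, p


# ------------------------------------------------------------ fixed design

def test_fixed_design_expands_factors_full_rank():
    factors = pd.DataFrame(
        {
            "breed": ["B1", "B1", "B2", "B2", "B1", "B2"],
            "herd": ["h1", "h2", "h1", "h2", "h1", "h2"],
            "ssg": ["M1", "M1", "F1", "F1", "M2", "M2"],
        },
        index=[f"a{i}" for i in range(6)],
    )
    d = build_fixed_design(factors)
    assert d.columns[0] == "intercept"
    # 4 composed breed:herd levels -> 3 dummies; 3 ssg levels -> 2 dummies
    assert d.matrix.shape == (6, 6)
    assert np.linalg.matrix_rank(d.matrix) == 6


def test_duplicated_column_raises_rank_error_naming_alias():
    X = np.ones((10, 2))
    X[:, 1] = np.arange(10)
    Xdup = np.column_stack([X, X[:, 1]])
    y = pd.Series(np.arange(10, dtype=float), index=[f"a{i}" for i in range(10)])
    with pytest.raises(RankError, match="aliased"):
        fit_null_model(y, Xdup, identity_A(10))


# ------------------------------------------------------------ null model

def test_reml_recovers_variance_components_with_identity_A():
    rng = np.random.default_rng(123)
    n = 2000
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    beta = np.array([10.0, 1.0])
    a = rng.standard_normal(n) * 2.0  # sigma2_a = 4, A = I
    e = rng.standard_normal(n) * 2.0  # sigma2_e = 4
    y = pd.Series(X @ beta + a + e, index=[f"a{i}" for i in range(n)])
    fit = fit_null_model(y, X, identity_A(n))
    total = fit.vc.sigma2_a + fit.vc.sigma2_e
    # with A = I only the total is identifiable; check it tightly
    se_total = total * np.sqrt(2.0 / (n - 2))
    assert abs(total - 8.0) < 3 * se_total


def test_reml_recovers_components_with_pedigree_structure():
    from dupgwas.pedigree import build_nrm

    # half-sib design separates sigma2_a from sigma2_e, but each single fit
    # has a wide sampling spread; average over seeds
    est_a, est_e = [], []
    for seed in (77, 78, 79):
        cfg = SimulationConfig(
            seed=seed, n_sires=100, sibship_range=(10, 10), n_snps=2,
            sigma2_a=8.0, sigma2_e=4.0, herd_sd=0.0, ssg_sd=0.0, qtl_specs=[],
        )
        study = simulate_population(cfg)
        ids = study.cohort
        A = build_nrm(study.pedigree, order=ids)
        fit = fit_null_model(study.y_true.loc[ids], np.ones((len(ids), 1)), A)
        est_a.append(fit.vc.sigma2_a)
        est_e.append(fit.vc.sigma2_e)
    assert np.mean(est_a) == pytest.approx(8.0, abs=2.5)
    assert np.mean(est_e) == pytest.approx(4.0, abs=2.5)


def test_reml_shrinks_sigma2_a_to_zero_without_genetic_signal():
    from dupgwas.pedigree import build_nrm

    cfg = SimulationConfig(
        seed=5, n_sires=100, sibship_range=(10, 10), n_snps=2,
        sigma2_a=0.0, sigma2_e=9.0, herd_sd=0.0, ssg_sd=0.0, qtl_specs=[],
    )
    study = simulate_population(cfg)
    ids = study.cohort
    A = build_nrm(study.pedigree, order=ids)
    fit = fit_null_model(study.y_true.loc[ids], np.ones((len(ids), 1)), A)
    assert fit.vc.sigma2_a <= 0.1 * fit.vc.sigma2_e


def test_adjusted_phenotype_removes_fixed_effects_only():
    rng = np.random.default_rng(9)
    n = 300
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    y = pd.Series(X @ np.array([5.0, 2.0]) + rng.standard_normal(n),
                  index=[f"a{i}" for i in range(n)])
    fit = fit_null_model(y, X, identity_A(n))
    np.testing.assert_allclose(fit.adjusted.values, y.values - X @ fit.beta)
    # BLUP-subtracted variant differs when sigma2_a > 0 is estimated
    assert fit.adjusted_phenotype(subtract_blup=True).shape == (n,)


# ------------------------------------------------------------ single SNP

def test_gls_reduces_to_ols_when_sigma2_a_zero():
    rng = np.random.default_rng(31)
    n = 400
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    g = rng.integers(0, 3, n).astype(float)
    y = X @ np.array([10.0, 0.5]) + 0.4 * g + rng.standard_normal(n) * 2.0
    vc = VarianceComponents(0.0, 1.0)  # any scale c > 0
    res = snp_association(y, X, identity_A(n), g, vc)
    b, se, t, p = ols_oracle(y, X, g)
    assert res.b == pytest.approx(b, rel=1e-8)
    assert res.se == pytest.approx(se, rel=1e-8)
    assert res.t == pytest.approx(t, rel=1e-8)
    assert res.p == pytest.approx(p, rel=1e-8)


def test_gls_with_scaled_identity_matches_ols_for_any_scale():
    rng = np.random.default_rng(32)
    n = 200
    X = np.ones((n, 1))
    g = rng.integers(0, 3, n).astype(float)
    y = 3.0 + 0.2 * g + rng.standard_normal(n)
    b0, se0, *_ = ols_oracle(y, X, g)
    for c in (0.1, 1.0, 17.0):
        res = snp_association(y, X, identity_A(n), g, VarianceComponents(0.0, c))
        assert res.b == pytest.approx(b0, rel=1e-10)
        assert res.se == pytest.approx(se0, rel=1e-8)


def test_monomorphic_snp_flagged_untested():
    n = 50
    res = snp_association(
        np.random.default_rng(0).standard_normal(n), np.ones((n, 1)),
        identity_A(n), np.ones(n), VarianceComponents(0.0, 1.0),
    )
    assert not res.tested
    assert np.isnan(res.p)


def test_allele_relabelling_flips_b_and_preserves_significance():
    rng = np.random.default_rng(44)
    n = 300
    X = np.ones((n, 1))
    g = rng.integers(0, 3, n).astype(float)
    y = 5.0 + 0.5 * g + rng.standard_normal(n)
    vc = VarianceComponents(0.5, 1.0)
    res_a = snp_association(y, X, identity_A(n), g, vc)
    res_b = snp_association(y, X, identity_A(n), 2.0 - g, vc)
    assert res_b.b == pytest.approx(-res_a.b, rel=1e-10)
    assert abs(res_b.t) == pytest.approx(abs(res_a.t), rel=1e-10)
    assert res_b.p == pytest.approx(res_a.p, rel=1e-10)


def test_null_permutations_give_uniform_p_values():
    rng = np.random.default_rng(2024)
    n = 200
    X = np.ones((n, 1))
    y = rng.standard_normal(n) * 2.0 + 12.0
    g0 = rng.integers(0, 3, n).astype(float)
    vc = VarianceComponents(0.0, 4.0)
    A = identity_A(n)
    pvals = []
    for _ in range(200):
        g = rng.permutation(g0)
        pvals.append(snp_association(y, X, A, g, vc).p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# ------------------------------------------------------------ full scan

@pytest.fixture(scope="module")
def small_study():
    cfg = SimulationConfig(
        seed=2025, n_sires=30, sibship_range=(10, 10), n_snps=200,
        sigma2_a=6.0, sigma2_e=6.0,
        qtl_specs=[{"chromosome": "14", "position_bp": 24_000_000,
                    "effect_mm": 1.0, "freq": 0.5}],
        blunder_prob=0.0, heaping_prob=0.0, offset_delta=0.0, sigma_small=1.0,
    )
    return simulate_population(cfg)


def scan_inputs(study, phenotype):
    ids = study.cohort
    y = phenotype.loc[ids]
    return (
        y,
        study.factors.loc[ids],
        study.pedigree,
        study.cohort_dosages(),
        study.snp_map,
    )


def test_p3d_and_exact_modes_agree(small_study):
    y, fac, ped, dos, smap = scan_inputs(small_study, small_study.measurement_1)
    r_p3d = run_gwas(y, fac, ped, dos, smap, mode="p3d")
    r_exact = run_gwas(y, fac, ped, dos, smap, mode="exact")
    t1, t2 = r_p3d.table.set_index("snp"), r_exact.table.set_index("snp")
    both = t1.index[t1["tested"] & t2.loc[t1.index, "tested"]]
    lp1 = -np.log10(t1.loc[both, "p"].astype(float))
    lp2 = -np.log10(t2.loc[both, "p"].astype(float))
    assert np.corrcoef(lp1, lp2)[0, 1] >= 0.99


def test_scan_is_map_sorted_and_complete(small_study):
    y, fac, ped, dos, smap = scan_inputs(small_study, small_study.measurement_1)
    res = run_gwas(y, fac, ped, dos, smap)
    assert len(res.table) == len(dos.columns)
    for _, grp in res.table.groupby("chrom", sort=False):
        assert grp["pos"].is_monotonic_increasing
    assert res.metadata["n_animals"] == len(y)


def test_qtl_effect_recovered_within_three_se():
    cfg = SimulationConfig(
        seed=99, n_sires=94, sibship_range=(10, 10), n_snps=10,
        sigma2_a=0.0, sigma2_e=4.0, herd_sd=0.0, ssg_sd=0.0,
        qtl_specs=[{"chromosome": "1", "position_bp": 30_000_000,
                    "effect_mm": 1.0, "freq": 0.5}],
        sigma_small=0.0, blunder_prob=0.0, heaping_prob=0.0, offset_delta=0.0,
    )
    study = simulate_population(cfg)
    ids = study.cohort
    assert len(ids) == 940
    qtl_dos = pd.DataFrame(
        {"qtl": study.qtl_dosage[[study.animals.index(a) for a in ids], 0]}, index=ids
    )
    res = run_gwas(study.y_true.loc[ids], study.factors.loc[ids], study.pedigree, qtl_dos)
    row = res.table.iloc[0]
    assert abs(row["b"] - 1.0) < 3 * row["se"]


def test_shuffled_phenotypes_calibrate_type_one_error(small_study):
    rng = np.random.default_rng(7)
    y, fac, ped, dos, smap = scan_inputs(small_study, small_study.measurement_1)
    y_shuf = pd.Series(rng.permutation(y.values), index=y.index)
    res = run_gwas(y_shuf, fac, ped, dos, smap)
    frac = (res.significant(0.05).shape[0]) / res.n_tested
    # 99% binomial CI around 0.05 with 200 SNPs
    se = np.sqrt(0.05 * 0.95 / res.n_tested)
    assert abs(frac - 0.05) < 2.58 * se + 1e-9


def test_se_decreases_with_sample_size(small_study):
    y, fac, ped, dos, smap = scan_inputs(small_study, small_study.measurement_1)
    res_full = run_gwas(y, fac, ped, dos, smap)
    half_ids = y.index[: len(y) // 2]
    res_half = run_gwas(y.loc[half_ids], fac.loc[half_ids], ped, dos.loc[half_ids], smap)
    t_full = res_full.table.set_index("snp")
    t_half = res_half.table.set_index("snp")
    both = t_full.index[t_full["tested"] & t_half["tested"].reindex(t_full.index, fill_value=False)]
    assert (t_full.loc[both, "se"] < t_half.loc[both, "se"]).mean() > 0.95


def test_empty_scan_on_monomorphic_panel():
    n = 40
    ids = [f"a{i}" for i in range(n)]
    y = pd.Series(np.random.default_rng(1).standard_normal(n) + 10, index=ids)
    fac = pd.DataFrame({"breed": "B1", "herd": "h1", "ssg": "M1"}, index=ids)
    dos = pd.DataFrame({"s1": np.ones(n), "s2": np.zeros(n)}, index=ids)
    res = run_gwas(y, fac, RelationshipMatrix(ids, np.eye(n)), dos)
    assert res.n_tested == 0
    assert (~res.table["tested"]).all()


def test_missing_genotypes_dropped_casewise(small_study):
    y, fac, ped, dos, smap = scan_inputs(small_study, small_study.measurement_1)
    dos = dos.astype(float)
    target = dos.columns[3]
    missing_ids = dos.index[:25]
    dos.loc[missing_ids, target] = np.nan
    res = run_gwas(y, fac, ped, dos, smap)
    row = res.table.set_index("snp").loc[target]
    assert row["n"] == len(y) - 25
    # equals a from-scratch scan on the complete cases with the same vc
    keep = dos.index.difference(missing_ids)
    vc = VarianceComponents(res.metadata["sigma2_a"], res.metadata["sigma2_e"])
    sub = run_gwas(y.loc[keep], fac.loc[keep], ped, dos.loc[keep, [target]], vc=vc)
    np.testing.assert_allclose(row["b"], sub.table.iloc[0]["b"], rtol=1e-6)
    np.testing.assert_allclose(row["se"], sub.table.iloc[0]["se"], rtol=1e-6)


# ------------------------------------------------------------ trend test

def ca_trend_oracle(affected, unaffected):
    """Textbook Cochran-Armitage chi-square for a 2x3 dosage table."""
    r = np.asarray(affected, float)
    n = r + np.asarray(unaffected, float)
    w = np.array([0.0, 1.0, 2.0])
    N = n.sum()
    R = r.sum()
    pbar = R / N
    num = np.sum(w * (r - n * pbar))
    den = pbar * (1 - pbar) * (np.sum(w**2 * n) - np.sum(w * n) ** 2 / N)
    return num**2 / den


def counts_to_vectors(affected, unaffected):
    status, g = [], []
    for j, (a, u) in enumerate(zip(affected, unaffected)):
        status += [1] * a + [0] * u
        g += [j] * (a + u)
    return np.array(status), np.array(g)


def test_trend_statistic_matches_textbook_oracle():
    affected, unaffected = (10, 20, 30), (30, 20, 10)
    status, g = counts_to_vectors(affected, unaffected)
    z, p = trend_test(status, g)
    assert z**2 == pytest.approx(ca_trend_oracle(affected, unaffected), abs=1e-10)
    assert z > 0  # dosage enriched in affected


def test_trend_zero_when_distributions_identical():
    status, g = counts_to_vectors((10, 20, 30), (10, 20, 30))
    z, p = trend_test(status, g)
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_trend_requires_both_classes_and_polymorphism():
    with pytest.raises(ValueError):
        trend_test(np.ones(10, dtype=int), np.array([0, 1] * 5))
    with pytest.raises(ValueError):
        trend_test(np.array([0, 1] * 5), np.zeros(10, dtype=int))


def test_trend_type_one_error_calibrated():
    rng = np.random.default_rng(17)
    n, reps, alpha = 120, 2000, 0.05
    hits = 0
    for _ in range(reps):
        g = rng.binomial(2, 0.4, size=n)
        status = rng.integers(0, 2, size=n)
        if status.min() == status.max() or np.ptp(g) == 0:
            continue
        _, p = trend_test(status, g)
        hits += p < alpha
    frac = hits / reps
    se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(frac - alpha) < 2.58 * se
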