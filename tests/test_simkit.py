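"""Generator-level checks: frequencies, founders, mating, meiosis, adoption,
weight noise and the phenotype model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

stats_norm_q = stats.norm.ppf(1 - 0.001)  # one-sided alpha = 0.001

import famfx as fx
from famfx.errors import (DegenerateInputError, ParameterError,
                          StructuralError)
from famfx.simkit import draw_true_weights, make_snp_table, plan_offspring


# ---------------------------------------------------------------------------
# scenario validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("kwargs", [
    {"n_families": 1},
    {"m_snps": 0},
    {"maf_low": 0.0},
    {"maf_low": 0.3, "maf_high": 0.2},
    {"maf_high": 0.7},
    {"am_rho": 1.0},
    {"am_rho": -0.1},
    {"pgs_precision": 0.0},
    {"pgs_precision": 1.2},
    {"offspring_per_family": 4},
    {"mz_fraction": 0.6, "dz_fraction": 0.6},
    {"adoption_fraction": 1.0},
    {"mating_trait": "height"},
    {"resid_sd": -1},
    {"fst": -0.1},
])
def test_scenario_rejects_invalid_parameters(kwargs):
    with pytest.raises(ParameterError):
        fx.SimulationScenario(**kwargs)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def test_zero_fst_gives_identical_subpopulation_frequencies():
    anc, sub = fx.draw_allele_freqs(100, 2, 0.0, 0.05, 0.5, seed=1)
    assert np.array_equal(sub[0], sub[1])
    assert np.array_equal(sub[0], anc)
    assert ((anc >= 0.05) & (anc <= 0.5)).all()


def test_single_snp_single_population_within_bounds():
    anc, sub = fx.draw_allele_freqs(1, 1, 0.5, 0.1, 0.4, seed=2)
    assert sub.shape == (1, 1)
    assert 0.1 <= anc[0] <= 0.4


def test_balding_nichols_divergence_moment():
    # E[(p1 - p2)^2 | p] = 2 F p (1 - p) under independent Beta draws with
    # variance F p (1 - p); the p(1-p)-standardized squared difference
    # averaged over many SNPs must approach 2F.
    fst = 0.1
    anc, sub = fx.draw_allele_freqs(5000, 2, fst, 0.05, 0.5, seed=3)
    standardized = (sub[0] - sub[1]) ** 2 / (anc * (1 - anc))
    # per-SNP the statistic is ~ 2F * chi2_1, so SE of the mean is
    # 2F * sqrt(2 / m)
    se = 2 * fst * np.sqrt(2 / 5000)
    assert abs(standardized.mean() - 2 * fst) < 4 * se


def test_freq_parameter_errors():
    with pytest.raises(ParameterError):
        fx.draw_allele_freqs(10, 2, 0.1, 0.4, 0.2, seed=0)
    with pytest.raises(ParameterError):
        fx.draw_allele_freqs(10, 2, -0.5, 0.1, 0.4, seed=0)


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------


def test_founder_dosage_means_match_binomial_expectation():
    scen = fx.SimulationScenario(n_families=20_000, m_snps=300, seed=5)
    founders = fx.simulate_founders(scen)
    d = founders.dosages()
    p = founders.subpop_freqs[0]
    se = np.sqrt(2 * p * (1 - p) / d.shape[0])
    dev = np.abs(d.mean(axis=0) - 2 * p) / se
    # per-SNP deviations are ~N(0,1); none should stray absurdly far
    assert dev.mean() < 1.3
    assert dev.max() < 6


def test_founder_sexes_and_scores_standardized():
    scen = fx.SimulationScenario(n_families=500, m_snps=100, seed=6)
    founders = fx.simulate_founders(scen)
    assert (founders.sex == 0).sum() == (founders.sex == 1).sum() == 500
    assert np.allclose(founders.z.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(founders.z.std(axis=0), 1, atol=1e-12)


def test_null_weights_flagged_degenerate():
    scen = fx.SimulationScenario(n_families=200, m_snps=50, seed=7)
    with pytest.raises(DegenerateInputError):
        fx.simulate_founders(scen, weights_true=np.zeros((50, 2)))


def test_stratified_scores_separate_when_frequencies_diverge():
    scen = fx.SimulationScenario(n_families=4000, m_snps=300, n_subpops=2,
                                 fst=0.2, seed=8)
    founders = fx.simulate_founders(scen)
    # brute-force per-subpopulation means of the raw scores
    expected_gap = np.empty(2)
    for c in range(2):
        w = founders.weights_true[:, c]
        gap = 2 * w @ (founders.subpop_freqs[0] - founders.subpop_freqs[1])
        expected_gap[c] = gap / founders.score_raw[:, c].std()
    got = np.empty(2)
    for c in range(2):
        m0 = founders.z[founders.subpop == 0, c].mean()
        m1 = founders.z[founders.subpop == 1, c].mean()
        got[c] = m0 - m1
    assert np.allclose(got, expected_gap, atol=0.1)


# ---------------------------------------------------------------------------
# spouse pairing
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def big_founders():
    scen = fx.SimulationScenario(n_families=20_000, m_snps=80, seed=9)
    return fx.simulate_founders(scen)


def test_random_mating_spousal_correlation_null(big_founders):
    couples = fx.pair_spouses(big_founders, 0.0, "pgs", seed=1)
    t = big_founders.mating_trait_values("pgs")
    r = np.corrcoef(t[couples.father_row], t[couples.mother_row])[0, 1]
    assert abs(r) < 3 / np.sqrt(len(couples))


def test_assortative_mating_hits_target_correlation(big_founders):
    couples = fx.pair_spouses(big_founders, 0.2, "pgs", seed=2)
    t = big_founders.mating_trait_values("pgs")
    r = np.corrcoef(t[couples.father_row], t[couples.mother_row])[0, 1]
    assert abs(r - 0.2) < 0.02


def test_extreme_assortment_near_monotone(big_founders):
    couples = fx.pair_spouses(big_founders, 0.95, "pgs", seed=3)
    t = big_founders.mating_trait_values("pgs")
    rho = pd.Series(t[couples.father_row]).corr(
        pd.Series(t[couples.mother_row]), method="spearman")
    assert rho > 0.9


def test_unbalanced_sexes_rejected(big_founders):
    founders = fx.simulate_founders(
        fx.SimulationScenario(n_families=100, m_snps=50, seed=10))
    founders.sex = founders.sex.copy()
    founders.sex[0] = 1  # one father too few
    with pytest.raises(StructuralError):
        fx.pair_spouses(founders, 0.0, "pgs", seed=0)


def test_phenotype_mating_trait_supported():
    scen = fx.SimulationScenario(n_families=2000, m_snps=80, seed=12,
                                 am_rho=0.5, mating_trait="phenotype")
    founders = fx.simulate_founders(scen)
    couples = fx.pair_spouses(founders, 0.5, "phenotype", seed=4)
    t = founders.mating_trait_values("phenotype")
    r = np.corrcoef(t[couples.father_row], t[couples.mother_row])[0, 1]
    assert abs(r - 0.5) < 0.06


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def test_mendelian_identities_exact(tiny_cohort):
    cohort, _ = tiny_cohort
    off = cohort.off_rows
    cols = np.arange(cohort.haps.shape[1])
    child = cohort.dosages(off)
    pat = cohort.haps[off][:, :, 0]
    mat = cohort.haps[off][:, :, 1]
    assert np.array_equal(child, pat + mat)
    F, M = cohort.father_row_of_off, cohort.mother_row_of_off
    t_pat = cohort.haps[F[:, None], cols[None, :], cohort.trans_pat]
    nt_pat = cohort.haps[F[:, None], cols[None, :], 1 - cohort.trans_pat]
    t_mat = cohort.haps[M[:, None], cols[None, :], cohort.trans_mat]
    nt_mat = cohort.haps[M[:, None], cols[None, :], 1 - cohort.trans_mat]
    assert np.array_equal(t_pat, pat)
    assert np.array_equal(t_mat, mat)
    # transmitted + non-transmitted = parent dosage, per parent and locus
    assert np.array_equal(t_pat + nt_pat, cohort.dosages(F))
    assert np.array_equal(t_mat + nt_mat, cohort.dosages(M))


def test_homozygous_parent_forces_transmission(tiny_cohort):
    cohort, _ = tiny_cohort
    F = cohort.father_row_of_off
    father_d = cohort.dosages(F)
    pat = cohort.haps[cohort.off_rows][:, :, 0]
    assert (pat[father_d == 2] == 1).all()
    assert (pat[father_d == 0] == 0).all()


def test_mz_twins_identical_dz_twins_distinct(tiny_cohort):
    cohort, _ = tiny_cohort
    p = cohort.persons
    off = p[p.role == "offspring"]
    for zyg, identical in (("MZ", True), ("DZ", False)):
        fams = off[off.zygosity == zyg].groupby("family_id").groups
        same = []
        for f, rows in fams.items():
            rows = list(rows)
            same.append(np.array_equal(cohort.haps[rows[0]],
                                       cohort.haps[rows[1]]))
        if identical:
            assert all(same)
        else:
            assert not any(same)


def test_sibling_genotype_correlation_half():
    scen = fx.SimulationScenario(n_families=20_000, m_snps=100, seed=13,
                                 dz_fraction=1.0)
    cohort, _ = fx.simulate_cohort(scen)
    d = cohort.dosages(cohort.off_rows)
    sib1, sib2 = d[::2], d[1::2]
    rs = [np.corrcoef(sib1[:, j], sib2[:, j])[0, 1] for j in range(100)]
    assert abs(np.mean(rs) - 0.5) < 0.01


# ---------------------------------------------------------------------------
# adoption
# ---------------------------------------------------------------------------


def test_adoption_zero_fraction_is_identity(tiny_cohort):
    cohort, _ = tiny_cohort
    out = fx.assign_adoption(cohort, 0.0, seed=1)
    pd.testing.assert_frame_equal(out.persons, cohort.persons)


def test_adoption_structure(tiny_cohort):
    cohort, _ = tiny_cohort
    p = cohort.persons
    ad = p[(p.role == "offspring") & p.adopted]
    assert len(ad) > 0
    assert (ad.rearing_family_id != ad.family_id).all()
    # one adoptee per rearing family
    assert ad.rearing_family_id.is_unique


@pytest.mark.parametrize("am_rho", [0.0, 0.4])
def test_adoptee_uncorrelated_with_adoptive_midparent(am_rho):
    scen = fx.SimulationScenario(n_families=10_000, m_snps=150, seed=14,
                                 adoption_fraction=0.1, am_rho=am_rho)
    cohort, weights = fx.simulate_cohort(scen)
    table = fx.cohort_score_table(cohort, weights)
    p = table
    ad = p[(p.role == "offspring") & p.adopted]
    fathers = p[p.role == "father"].set_index("family_id")
    mothers = p[p.role == "mother"].set_index("family_id")
    mid = 0.5 * (fathers.loc[ad.rearing_family_id, "pgs_cog"].to_numpy()
                 + mothers.loc[ad.rearing_family_id, "pgs_cog"].to_numpy())
    r = np.corrcoef(ad["pgs_cog"], mid)[0, 1]
    assert abs(r) < 3 / np.sqrt(len(ad))


# ---------------------------------------------------------------------------
# weight noise
# ---------------------------------------------------------------------------


def test_noisy_weights_precision_one_identity():
    w = draw_true_weights(40, seed=1)
    out = fx.make_noisy_weights(w, 1.0, np.full(40, 0.3), seed=2)
    assert np.array_equal(out, w)


def test_noisy_weights_zero_weights_error():
    with pytest.raises(DegenerateInputError):
        fx.make_noisy_weights(np.zeros((40, 2)), 0.5, np.full(40, 0.3))


def test_noisy_weights_realized_precision():
    scen = fx.SimulationScenario(n_families=10_000, m_snps=2_000, seed=15)
    founders = fx.simulate_founders(scen)
    noisy = fx.make_noisy_weights(founders.weights_true, 0.25,
                                  founders.ancestral_freqs, seed=3)
    s = founders.dosages() @ noisy
    for c in range(2):
        r2 = np.corrcoef(s[:, c], founders.score_raw[:, c])[0, 1] ** 2
        assert abs(r2 - 0.25) < 0.03


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------


def _null_scenario(**kw):
    base = dict(n_families=4000, m_snps=150, seed=16,
                beta_direct_cog=0, beta_direct_noncog=0,
                beta_postnatal_cog=0, beta_postnatal_noncog=0)
    base.update(kw)
    return fx.SimulationScenario(**base)


def test_null_model_phenotype_is_noise():
    scen = _null_scenario()
    cohort, _ = fx.simulate_cohort(scen)
    y = cohort.persons.loc[cohort.off_rows, "y"].to_numpy()
    z = cohort.z_true[cohort.off_rows]
    assert abs(y.std() - 1.0) < 0.05
    for c in range(2):
        assert abs(np.corrcoef(y, z[:, c])[0, 1]) < 3 / np.sqrt(len(y))


def test_direct_only_regression_recovers_effect():
    scen = _null_scenario(n_families=20_000, beta_direct_cog=0.15, seed=17)
    cohort, _ = fx.simulate_cohort(scen)
    y = cohort.persons.loc[cohort.off_rows, "y"].to_numpy()
    z = cohort.z_true[cohort.off_rows, 0]
    slope = np.cov(y, z)[0, 1] / np.var(z)
    assert abs(slope - 0.15) < 0.015


def test_prenatal_effect_follows_biological_parents():
    scen = _null_scenario(n_families=10_000, seed=18,
                          beta_prenatal_cog=0.2, beta_prenatal_noncog=0.2,
                          adoption_fraction=0.2)
    cohort, _ = fx.simulate_cohort(scen)
    p = cohort.persons
    off_idx = cohort.off_rows
    is_ad = p.loc[off_idx, "adopted"].to_numpy()
    y = p.loc[off_idx, "y"].to_numpy()
    z = cohort.z_true
    mid_bio = 0.5 * (z[cohort.father_row_of_off, 0]
                     + z[cohort.mother_row_of_off, 0])
    rear = p.loc[off_idx, "rearing_family_id"].to_numpy()
    n = cohort.n_families
    mid_rear = 0.5 * (z[rear, 0] + z[rear + n, 0])
    slope_bio = np.cov(y[is_ad], mid_bio[is_ad])[0, 1] / np.var(mid_bio[is_ad])
    slope_rear = np.cov(y[is_ad], mid_rear[is_ad])[0, 1] / \
        np.var(mid_rear[is_ad])
    assert abs(slope_bio - 0.2) < 0.06
    assert abs(slope_rear) < 0.06


def test_singletons_receive_no_sibling_term():
    scen = fx.SimulationScenario(
        n_families=3000, m_snps=100, seed=19, offspring_per_family=1,
        beta_sibling_cog=0.5, beta_sibling_noncog=0.5,
        beta_direct_cog=0, beta_direct_noncog=0,
        beta_postnatal_cog=0, beta_postnatal_noncog=0)
    cohort, _ = fx.simulate_cohort(scen)
    y = cohort.persons.loc[cohort.off_rows, "y"].to_numpy()
    assert abs(y.std() - 1.0) < 0.05


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------


def test_seeded_runs_bit_reproducible():
    scen = fx.SimulationScenario(n_families=300, m_snps=60, seed=20,
                                 adoption_fraction=0.2, dz_fraction=0.3,
                                 pgs_precision=0.5)
    c1, w1 = fx.simulate_cohort(scen)
    c2, w2 = fx.simulate_cohort(scen)
    assert np.array_equal(c1.haps, c2.haps)
    pd.testing.assert_frame_equal(c1.persons, c2.persons)
    pd.testing.assert_frame_equal(w1, w2)


def test_sibling_icc_and_spousal_null_with_assortment_contrast():
    # with random mating the sibling true-score ICC is 1/2 and spouses are
    # uncorrelated; with assortment both are elevated
    scen = fx.SimulationScenario(n_families=8000, m_snps=150, seed=21,
                                 dz_fraction=1.0)
    cohort, weights = fx.simulate_cohort(scen)
    table = fx.cohort_score_table(cohort, weights)
    diag = fx.pgs_correlation_diagnostics(table)
    icc = diag[(diag.statistic == "sibling_icc")
               & (diag.construct == "cog")]["value"].iloc[0]
    sp = diag[(diag.statistic == "spousal_r")
              & (diag.construct == "cog")]["value"].iloc[0]
    assert abs(icc - 0.5) < 3 * (1 - 0.25) / np.sqrt(8000)
    assert abs(sp) < 3 / np.sqrt(8000)

    scen_am = scen.replace(am_rho=0.6, seed=22)
    cohort, weights = fx.simulate_cohort(scen_am)
    table = fx.cohort_score_table(cohort, weights)
    diag = fx.pgs_correlation_diagnostics(table)
    icc_am = diag[(diag.statistic == "sibling_icc")
                  & (diag.construct == "cog")]["value"].iloc[0]
    sp_am = diag[(diag.statistic == "spousal_r")
                 & (diag.construct == "cog")]["value"].iloc[0]
    # one-sided detection of elevated correlations
    assert icc_am > 0.5 + stats_norm_q * (1 - 0.25) / np.sqrt(8000)
    assert sp_am > stats_norm_q / np.sqrt(8000)
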