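"""Genotype tables, trend test and Cox proportional-hazards machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from daehap.errors import DataError, ModelError
from daehap.risk import (
    CarrierRecord,
    cox_fit,
    cox_per_allele,
    cox_score_test_at_zero,
    genotype_status_table,
    haplotype_cohort_assoc,
    heterogeneity_test,
    trend_test,
)
from daehap.simulate import (
    SimConfig,
    gen_carrier_cohort,
    gen_haplotype_carrier_cohort,
)

#: Genotype counts (GG, AG, AA) x (unaffected, affected) from the carrier cohort.
COHORT_COUNTS = np.array([[648, 817], [246, 271], [27, 24]])


def _records(counts: np.ndarray, rng=None) -> list[CarrierRecord]:
    rng = rng or np.random.default_rng(0)
    out = []
    i = 0
    for g in range(3):
        for status in (False, True):
            for _ in range(int(counts[g, int(status)])):
                i += 1
                out.append(
                    CarrierRecord(
                        f"c{i}", "s1", g, status, float(rng.exponential(30) + 0.01)
                    )
                )
    return out


def test_genotype_table_reproduces_printed_percentages():
    tab = genotype_status_table(_records(COHORT_COUNTS))
    assert tab.percent[0, 0] == 70.36  # unaffected GG
    assert tab.percent[0, 1] == 73.47  # affected GG
    assert tab.percent[2, 1] == 2.16  # affected AA
    assert tab.n_affected == 1112 or tab.n_affected == int(COHORT_COUNTS[:, 1].sum())
    assert tab.total == int(COHORT_COUNTS.sum())


def test_genotype_table_single_record_and_missing():
    tab = genotype_status_table(
        [CarrierRecord("c1", "s", 1, True, 5.0), CarrierRecord("c2", "s", None, True, 5.0)]
    )
    assert tab.percent[1, 1] == 100.0
    with pytest.raises(DataError):
        genotype_status_table([CarrierRecord("c1", "s", None, True, 5.0)])


def test_hwe_genotype_frequencies_in_simulation():
    cfg = SimConfig(seed=29)
    cfg.carrier.n = 2000
    cfg.carrier.maf = 0.16
    carriers = gen_carrier_cohort(cfg)
    g = np.array([c.genotype for c in carriers])
    p = cfg.carrier.maf
    for k, expected in enumerate([(1 - p) ** 2, 2 * p * (1 - p), p**2]):
        se = math.sqrt(expected * (1 - expected) / len(g))
        assert abs((g == k).mean() - expected) < 3 * se


def test_trend_identical_distributions_is_null():
    z, p = trend_test(np.array([[50, 50], [30, 30], [5, 5]]))
    assert z == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)


def test_trend_matches_hand_computed_oracle():
    counts = COHORT_COUNTS
    t = np.array([0.0, 1.0, 2.0])
    n_g = counts.sum(axis=1)
    A = counts[:, 1]
    N, R = counts.sum(), counts[:, 1].sum()
    u = t @ A - R / N * (t @ n_g)
    var = R * (N - R) / (N * (N - 1)) * (t @ (t * n_g) - (t @ n_g) ** 2 / N)
    z_hand = u / math.sqrt(var)
    z, p = trend_test(counts)
    assert z == pytest.approx(z_hand)
    assert z < 0  # fewer minor alleles among affected carriers
    assert 0 < p < 1


def test_trend_rejects_empty_column():
    with pytest.raises(ValueError):
        trend_test(np.array([[5, 0], [3, 0], [1, 0]]))


# ---------------------------------------------------------------------------
# Cox model


def _sim_cox_data(n=400, beta=0.4, seed=1):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 3, n).astype(float)
    t = rng.exponential(1.0 / (0.05 * np.exp(beta * g)))
    c = rng.exponential(30, n)
    return g, np.minimum(t, c), t <= c


def test_cox_matches_lifelines_oracle():
    from lifelines import CoxPHFitter

    g, t, e = _sim_cox_data()
    fit = cox_fit(g[:, None], t, e)
    df = pd.DataFrame({"g": g, "t": t, "e": e.astype(int)})
    cph = CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron ties
    fit_efron = cox_fit(g[:, None], t, e, ties="efron")
    assert fit_efron.beta[0] == pytest.approx(cph.params_["g"], abs=1e-6)
    assert fit_efron.se[0] == pytest.approx(cph.standard_errors_["g"], rel=1e-5)
    assert fit_efron.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)
    # continuous times: Breslow and Efron agree to numerical noise
    assert fit.beta[0] == pytest.approx(fit_efron.beta[0], abs=1e-6)


def test_cox_gradient_contract_and_convergence():
    g, t, e = _sim_cox_data(seed=5)
    fit = cox_fit(g[:, None], t, e)
    assert fit.converged
    assert fit.score_norm < 1e-6


def test_score_test_at_zero_equals_logrank():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(8)
    n = 200
    grp = rng.integers(0, 2, n)
    t = rng.exponential(np.where(grp == 1, 8.0, 12.0))
    c = rng.exponential(15, n)
    time, event = np.minimum(t, c), t <= c
    chi2, p = cox_score_test_at_zero(grp.astype(float)[:, None], time, event)
    lr = logrank_test(
        time[grp == 0], time[grp == 1], event[grp == 0], event[grp == 1]
    )
    assert chi2 == pytest.approx(lr.test_statistic, rel=1e-6)
    assert p == pytest.approx(lr.p_value, rel=1e-6)


def test_allele_recoding_flips_beta_sign():
    g, t, e = _sim_cox_data(seed=3)
    fit = cox_fit(g[:, None], t, e)
    flipped = cox_fit((2 - g)[:, None], t, e)
    assert flipped.beta[0] == pytest.approx(-fit.beta[0], abs=1e-7)
    assert flipped.se[0] == pytest.approx(fit.se[0], rel=1e-7)


def test_uncensored_two_group_matches_rate_ratio():
    """Without censoring the Cox estimate tracks the closed-form rate ratio."""
    rng = np.random.default_rng(12)
    n = 2000
    grp = rng.integers(0, 2, n).astype(float)
    beta_true = 0.5
    t = rng.exponential(1.0 / (0.1 * np.exp(beta_true * grp)))
    fit = cox_fit(grp[:, None], t, np.ones(n, bool))
    # rate-ratio estimator: log(mean time ratio) with SE sqrt(1/n1 + 1/n2)
    log_rr = math.log(t[grp == 0].mean() / t[grp == 1].mean())
    se = math.sqrt(1 / (grp == 0).sum() + 1 / (grp == 1).sum())
    assert abs(fit.beta[0] - log_rr) < 3 * se


def test_null_genotype_gives_unit_hr_and_ci_coverage():
    rng = np.random.default_rng(100)
    covered = 0
    n_sim = 200
    for i in range(n_sim):
        g = rng.integers(0, 3, 250).astype(float)
        t = rng.exponential(10, 250)
        e = rng.random(250) < 0.7
        if np.ptp(g) == 0 or not e.any():
            covered += 1
            continue
        fit = cox_fit(g[:, None], t, e)
        lo = fit.beta[0] - 1.96 * fit.se[0]
        hi = fit.beta[0] + 1.96 * fit.se[0]
        covered += lo <= 0.0 <= hi
    assert 0.90 <= covered / n_sim <= 0.99


def test_cox_per_allele_wrapper_and_2df():
    cfg = SimConfig(seed=31)
    cfg.carrier.n = 3000
    carriers = gen_carrier_cohort(cfg)
    add = cox_per_allele(carriers)
    assert add.terms[0].ci_low < add.terms[0].hr < add.terms[0].ci_high
    two = cox_per_allele(carriers, coding="2df")
    assert {t.name for t in two.terms} == {"het", "hom"}
    assert two.lrt_p is not None and 0 <= two.lrt_p <= 1
    strat = cox_per_allele(carriers, stratify_by_study=True)
    assert abs(math.log(strat.terms[0].hr) - math.log(add.terms[0].hr)) < 0.2


def test_cox_error_paths():
    recs = [CarrierRecord(f"c{i}", "s", 1, False, 5.0) for i in range(5)]
    with pytest.raises(ModelError):
        cox_per_allele(recs)  # no events
    recs2 = [CarrierRecord(f"c{i}", "s", 1, i % 2 == 0, 5.0 + i) for i in range(6)]
    with pytest.raises(ModelError):
        cox_per_allele(recs2)  # no genotype variation


def test_heterogeneity_error_with_single_study():
    cfg = SimConfig(seed=2)
    cfg.carrier.n = 200
    cfg.carrier.n_studies = 1
    with pytest.raises(ModelError):
        heterogeneity_test(gen_carrier_cohort(cfg))


def test_heterogeneity_detects_opposite_effects():
    rng = np.random.default_rng(77)
    carriers = []
    for study, beta in (("s1", -0.8), ("s2", 0.8)):
        g = rng.integers(0, 3, 800)
        t = rng.exponential(1.0 / (0.05 * np.exp(beta * g)))
        c = rng.exponential(30, 800)
        for i in range(800):
            carriers.append(
                CarrierRecord(
                    f"{study}_{i}", study, int(g[i]),
                    bool(t[i] <= c[i]), float(min(t[i], c[i])),
                )
            )
    lr, df, p = heterogeneity_test(carriers)
    assert df == 1
    assert p < 1e-3


def test_haplotype_model_integer_dosages_equal_plain_cox():
    """Phase-known dosages reduce to an ordinary Cox fit on counted haplotypes."""
    cfg = SimConfig(seed=41)
    cfg.carrier.n = 1500
    carriers = gen_haplotype_carrier_cohort(cfg, {"hap4": math.log(0.84)})
    est = haplotype_cohort_assoc(carriers, "hap2")
    dosage_cols = sorted({h for c in carriers for h in c.dosages} - {"hap2"})
    X = np.array([[c.dosages.get(h, 0.0) for h in dosage_cols] for c in carriers])
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    fit = cox_fit(
        X[:, keep],
        np.array([c.time for c in carriers]),
        np.array([c.status for c in carriers]),
    )
    assert np.allclose(
        [math.log(t.hr) for t in est.terms], fit.beta, atol=1e-8
    )
    assert all(float(d).is_integer() for c in carriers for d in c.dosages.values())


def test_haplotype_model_error_paths():
    carriers = [
        CarrierRecord("c1", "s", None, True, 3.0, dosages={"hap2": 2.0}),
        CarrierRecord("c2", "s", None, False, 5.0, dosages={"hap2": 2.0}),
    ]
    with pytest.raises(ValueError):
        haplotype_cohort_assoc(carriers, "hap9")
    with pytest.raises(ModelError):
        haplotype_cohort_assoc(carriers, "hap2")  # everyone reference-homozygous


def test_carrier_record_validation():
    with pytest.raises(DataError):
        CarrierRecord("c", "s", 3, True, 5.0)
    with pytest.raises(DataError):
        CarrierRecord("c", "s", 1, True, 0.0)
    with pytest.raises(DataError):
        CarrierRecord("c", "s", 1, True, 5.0, entry_time=6.0)
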