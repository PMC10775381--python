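import numpy as np
import pytest

from surfhet.association import (
    fit_random_intercept_logit,
    genomic_logistic,
    site_mixed_model,
    transcript_logistic,
)
from surfhet.errors import DegenerateOutcomeError
from surfhet.synthetic import simulate_genomic_cohort, simulate_site_cohort

from conftest import build_cohort


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------


def test_zero_patient_variance_reduces_to_raw_site_means():
    cohort = simulate_site_cohort(
        n_patients=30, patient_sd=0.0, residual_sd=15.0, seed=4
    )
    contrasts = {c.site: c for c in site_mixed_model(cohort, "TROP2")}
    df = cohort.samples
    means = df.groupby("anatomic_site")["TROP2_h"].mean()
    raw_diff = means["liver"] - means["vertebral_bone"]
    assert contrasts["liver"].mean_difference == pytest.approx(raw_diff, abs=1e-4)
    assert contrasts["vertebral_bone"].mean_difference == 0.0
    assert contrasts["vertebral_bone"].reference_mean == pytest.approx(
        means["vertebral_bone"], abs=1e-4
    )


def test_reference_site_change_relabels_but_preserves_cell_means():
    cohort = simulate_site_cohort(n_patients=25, seed=8)
    a = {c.site: c for c in site_mixed_model(cohort, "TROP2", "vertebral_bone")}
    b = {c.site: c for c in site_mixed_model(cohort, "TROP2", "liver")}
    cell_a = {s: a[s].reference_mean + a[s].mean_difference for s in a}
    cell_b = {s: b[s].reference_mean + b[s].mean_difference for s in b}
    for s in cell_a:
        assert cell_a[s] == pytest.approx(cell_b[s], abs=1e-3)


def test_single_site_cohort_not_estimable():
    rows = [
        ("P1", "S1", "B1", "C1", "liver", {"TROP2": 100}),
        ("P2", "S1", "B1", "C1", "liver", {"TROP2": 50}),
    ]
    with pytest.raises(DegenerateOutcomeError):
        site_mixed_model(build_cohort(rows), "TROP2", reference_site="liver")


def test_singleton_site_flagged_wide_ci():
    rows = [
        ("P1", "S1", "B1", "C1", "liver", {"TROP2": 100}),
        ("P1", "S2", "B1", "C1", "liver", {"TROP2": 90}),
        ("P2", "S1", "B1", "C1", "liver", {"TROP2": 50}),
        ("P2", "S2", "B1", "C1", "lung", {"TROP2": 70}),
    ]
    contrasts = {c.site: c for c in site_mixed_model(build_cohort(rows), "TROP2", "liver")}
    assert contrasts["lung"].wide_ci


def test_contrast_ci_brackets_estimate():
    cohort = simulate_site_cohort(n_patients=20, seed=2)
    for c in site_mixed_model(cohort, "TROP2"):
        assert c.ci_low <= c.mean_difference <= c.ci_high


# ---------------------------------------------------------------------------
# random-intercept logistic regression
# ---------------------------------------------------------------------------


def test_one_sample_per_patient_matches_classical_2x2_odds_ratio():
    # 2x2 table: altered 30 pos / 10 neg; wildtype 20 pos / 40 neg
    y = np.array([1] * 30 + [0] * 10 + [1] * 20 + [0] * 40)
    x = np.array([1] * 40 + [0] * 60)
    cluster = np.arange(100)
    fit = fit_random_intercept_logit(y, x, cluster)
    assert fit.sigma == 0.0
    classical = (30 * 40) / (10 * 20)
    assert np.exp(fit.coef) == pytest.approx(classical, abs=1e-6)


def test_boundary_loglik_equals_plain_logistic():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 2, 60)
    y = (rng.random(60) < 0.3 + 0.3 * x).astype(float)
    fit = fit_random_intercept_logit(y, x, np.arange(60))
    import statsmodels.api as sm

    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)


def test_recovers_cluster_variance_when_present():
    cohort = simulate_genomic_cohort(
        n_patients=150, samples_per_patient=5, patient_sd=1.2, seed=6
    )
    a = genomic_logistic(cohort, "PSMA", "AR", collapse="none")
    assert 0.6 < a.sigma < 2.0
    assert a.ci_low <= a.odds_ratio <= a.ci_high


def test_patient_collapse_any_counts_patients_once():
    cohort = simulate_genomic_cohort(n_patients=60, samples_per_patient=3, seed=1)
    a = genomic_logistic(cohort, "PSMA", "AR", collapse="any")
    assert a.n_altered + a.n_wildtype == 60


def test_complete_separation_flagged():
    rows = []
    genomics = []
    for i in range(20):
        pid = f"P{i}"
        altered = i < 10
        genomics.append({"patient_id": pid, "RB1": int(altered)})
        rows.append((pid, "S1", "B1", "C1", "liver", {"TROP2": 0 if altered else 150}))
    cohort = build_cohort(rows, genomics=genomics)
    a = genomic_logistic(cohort, "TROP2", "RB1")
    assert a.separated
    assert a.odds_ratio == 0.0  # altered patients never express


def test_single_class_outcome_rejected():
    y = np.ones(20)
    x = np.array([0, 1] * 10)
    with pytest.raises(DegenerateOutcomeError):
        fit_random_intercept_logit(y, x, np.arange(20))


def test_transcript_mode_dichotomizes_fpkm():
    import pandas as pd

    rng = np.random.default_rng(3)
    n = 120
    x = rng.integers(0, 2, n)
    fpkm = np.where(
        rng.random(n) < 0.25 + 0.45 * x, rng.uniform(2, 50, n), rng.uniform(0, 0.9, n)
    )
    table = pd.DataFrame(
        {"patient_id": [f"P{i}" for i in range(n)], "CEACAM5": fpkm, "gene_PTEN": x}
    )
    a = transcript_logistic(table, "CEACAM5", "PTEN")
    assert a.odds_ratio > 1
    assert a.expression_dichotomization == "FPKM >= 1"
    assert 0 <= a.p_value <= 1
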