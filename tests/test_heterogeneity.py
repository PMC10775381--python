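import math

import numpy as np
import pytest

from surfhet.errors import ConfigurationError, NoPairsError
from surfhet.heterogeneity import (
    bca_interval,
    enumerate_pairs,
    heterogeneity_bootstrap,
    heterogeneity_exact,
)
from surfhet.synthetic import generate_cohort, truth_heterogeneity

from conftest import status_cohort


def pool_from_statuses(statuses_by_block, scope="intra_tumoral"):
    return enumerate_pairs(status_cohort(statuses_by_block), "TROP2", scope)


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------


def test_three_cores_give_three_intra_pairs():
    pool = pool_from_statuses({("P1", "S1", "B1"): [True, True, False]})
    assert pool.n_pairs == 3


def test_inter_pairs_cross_blocks_only():
    pool = pool_from_statuses(
        {("P1", "S1", "B1"): [True, False], ("P1", "S2", "B1"): [True]},
        scope="inter_tumoral",
    )
    # blocks of sizes {2,1}: 2*1 cross-block pairs; the within-block pair is excluded
    assert pool.n_pairs == 2


def test_singleton_blocks_yield_no_intra_pool():
    with pytest.raises(NoPairsError):
        pool_from_statuses(
            {("P1", "S1", "B1"): [True], ("P1", "S2", "B1"): [False]}
        )


def test_unscored_samples_excluded_from_pool():
    cohort = status_cohort({("P1", "S1", "B1"): [True, False, True]})
    cohort.samples.loc[2, "TROP2_h"] = np.nan
    cohort.samples.loc[2, "PSMA_h"] = 0.0  # keep the row schema-valid
    pool = enumerate_pairs(cohort, "TROP2", "intra_tumoral")
    assert pool.n_pairs == 1


# ---------------------------------------------------------------------------
# exact index
# ---------------------------------------------------------------------------


def test_exact_discordance_single_block():
    # n=4, k=2: 6 pairs, 4 discordant -> 2/3
    pool = pool_from_statuses({("P1", "S1", "B1"): [True, True, False, False]})
    assert heterogeneity_exact(pool) == pytest.approx(2 / 3)


@pytest.mark.parametrize("statuses", [[True] * 5, [False] * 4])
def test_uniform_blocks_have_zero_discordance(statuses):
    pool = pool_from_statuses({("P1", "S1", "B1"): statuses})
    assert heterogeneity_exact(pool) == 0.0


@pytest.mark.parametrize("n,k", [(4, 2), (5, 1), (6, 3), (7, 5), (10, 0)])
def test_exact_matches_hypergeometric_identity(n, k):
    """Pair enumeration equals 1 - [C(k,2)+C(n-k,2)]/C(n,2)."""
    pool = pool_from_statuses({("P1", "S1", "B1"): [True] * k + [False] * (n - k)})
    expected = 1 - (math.comb(k, 2) + math.comb(n - k, 2)) / math.comb(n, 2)
    assert heterogeneity_exact(pool) == pytest.approx(expected)


def test_group_weighting_averages_blocks_equally():
    pool = pool_from_statuses(
        {
            ("P1", "S1", "B1"): [True, True, False, False],  # discordance 2/3
            ("P1", "S2", "B1"): [True, True],  # discordance 0
        }
    )
    assert heterogeneity_exact(pool, weighting="group") == pytest.approx(1 / 3)
    # pair weighting pools the 7 pairs: 4 discordant of 7
    assert heterogeneity_exact(pool, weighting="pair") == pytest.approx(4 / 7)


def test_label_swap_symmetry():
    statuses = {("P1", "S1", "B1"): [True, False, True, True, False]}
    flipped = {k: [not s for s in v] for k, v in statuses.items()}
    a = heterogeneity_exact(pool_from_statuses(statuses))
    b = heterogeneity_exact(pool_from_statuses(flipped))
    assert a == pytest.approx(b)


def test_wider_between_block_spread_raises_inter_index():
    uniform = {
        ("P1", "S1", "B1"): [True, True],
        ("P1", "S2", "B1"): [True, True],
        ("P2", "S1", "B1"): [True, True],
        ("P2", "S2", "B1"): [True, True],
    }
    spread = {
        ("P1", "S1", "B1"): [True, True],
        ("P1", "S2", "B1"): [False, False],
        ("P2", "S1", "B1"): [True, True],
        ("P2", "S2", "B1"): [False, False],
    }
    lo = heterogeneity_exact(pool_from_statuses(uniform, "inter_tumoral"))
    hi = heterogeneity_exact(pool_from_statuses(spread, "inter_tumoral"))
    assert hi > lo


def test_truth_oracle_agrees_with_pair_enumeration():
    cohort, truth = generate_cohort(seed=5)
    for marker in ("TROP2", "PSMA"):
        for scope in ("intra_tumoral", "inter_tumoral"):
            pool = enumerate_pairs(cohort, marker, scope)
            assert heterogeneity_exact(pool) == pytest.approx(
                truth_heterogeneity(truth, marker, scope), abs=1e-12
            )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_is_deterministic_given_seed():
    pool = pool_from_statuses({("P1", "S1", "B1"): [True, True, False, False, True]})
    a = heterogeneity_bootstrap(pool, seed=42)
    b = heterogeneity_bootstrap(pool, seed=42)
    assert a == b
    c = heterogeneity_bootstrap(pool, seed=43)
    assert c.point_estimate != a.point_estimate


def test_bootstrap_point_estimate_near_exact():
    pool = pool_from_statuses({("P1", "S1", "B1"): [True, True, False, False]})
    exact = heterogeneity_exact(pool)
    est = heterogeneity_bootstrap(pool, n_pairs=1000, n_boot=2000, seed=1)
    se = math.sqrt(exact * (1 - exact) / (1000 * 2000))
    assert abs(est.point_estimate - exact) <= 3 * se


def test_all_concordant_pool_degenerates_to_zero():
    pool = pool_from_statuses({("P1", "S1", "B1"): [True, True, True]})
    est = heterogeneity_bootstrap(pool, seed=0)
    assert est.point_estimate == 0.0
    assert (est.ci_low, est.ci_high) == (0.0, 0.0)
    assert est.degenerate


def test_estimates_and_cis_stay_in_unit_interval():
    cohort, _ = generate_cohort(seed=2)
    pool = enumerate_pairs(cohort, "CEACAM5", "inter_tumoral")
    for unit in ("pair", "patient"):
        est = heterogeneity_bootstrap(pool, seed=9, resample_unit=unit)
        assert 0 <= est.ci_low <= est.point_estimate <= est.ci_high <= 1


def test_invalid_sizes_rejected():
    pool = pool_from_statuses({("P1", "S1", "B1"): [True, False]})
    with pytest.raises(ConfigurationError):
        heterogeneity_bootstrap(pool, n_boot=0)
    with pytest.raises(ConfigurationError):
        heterogeneity_bootstrap(pool, n_pairs=0)


# ---------------------------------------------------------------------------
# BCa interval
# ---------------------------------------------------------------------------


def test_symmetric_replicates_reduce_to_percentile_interval():
    rng = np.random.default_rng(0)
    reps = rng.normal(0.5, 0.05, size=20001)
    jack = np.full(50, 0.5)  # zero acceleration
    ci = bca_interval(reps, observed=float(np.median(reps)), jackknife=jack)
    lo, hi = np.quantile(reps, [0.025, 0.975])
    assert ci.z0 == pytest.approx(0.0, abs=0.02)
    assert ci.acceleration == 0.0
    assert ci.low == pytest.approx(lo, abs=5e-3)
    assert ci.high == pytest.approx(hi, abs=5e-3)


def test_two_point_replicate_distribution_hand_computed():
    # 500 replicates at 0.1 and 500 at 0.2, observed 0.15: half the mass lies
    # below the observed value so z0=0; flat jackknife gives a=0, and the
    # 2.5/97.5 percentiles of the two-point distribution are its support ends.
    reps = np.array([0.1] * 500 + [0.2] * 500)
    jack = np.full(30, 0.15)
    ci = bca_interval(reps, observed=0.15, jackknife=jack)
    assert ci.z0 == 0.0
    assert (ci.low, ci.high) == (0.1, 0.2)


def test_degenerate_replicates_flagged_not_raised():
    ci = bca_interval(np.full(100, 0.3), 0.3, np.full(10, 0.3))
    assert ci.degenerate
    assert (ci.low, ci.high) == (0.3, 0.3)


def test_bias_constant_sign_follows_replicate_shift():
    # most replicates above the observed value -> negative z0 pulls downward
    reps = np.concatenate([np.full(900, 0.4), np.full(100, 0.1)])
    ci = bca_interval(reps, observed=0.2, jackknife=np.linspace(0.1, 0.4, 20))
    assert ci.z0 < 0
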