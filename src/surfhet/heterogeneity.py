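"""Intra- and inter-tumoral expression heterogeneity.

The heterogeneity index for a marker is the probability that two samples
drawn at random without replacement from the same group are *discordant* in
binarized status (one H-score >= threshold, the other below).  Two scopes are
defined by the grouping:

* intra-tumoral — both samples from the same tumor block;
* inter-tumoral — both samples from the same patient but different blocks
  (i.e. across that patient's metastatic sites).

For a single group of n samples with k positives the concordance probability
is the finite-population (hypergeometric) identity
``[C(k,2) + C(n-k,2)] / C(n,2)`` and the index is its complement.  The exact
index is computed by exhaustive pair enumeration; the bootstrap estimator
resamples pairs (or whole patients) and attaches bias-corrected and
accelerated (BCa) confidence limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .cohort import CohortTable
from .errors import ConfigurationError, NoPairsError
from .scoring import DEFAULT_THRESHOLD

SCOPES = ("intra_tumoral", "inter_tumoral")


@dataclass
class PairPool:
    """All eligible unordered sample pairs for one marker and scope.

    ``statuses`` is an (n_pairs, 2) boolean array of the two members'
    binarized calls; ``groups`` holds the grouping key of each pair (block
    triple for intra-tumoral, patient for inter-tumoral).
    """

    scope: str
    marker: str
    threshold: float
    statuses: np.ndarray
    groups: list[tuple]

    @property
    def n_pairs(self) -> int:
        return len(self.statuses)

    @property
    def discordant(self) -> np.ndarray:
        return self.statuses[:, 0] != self.statuses[:, 1]


def enumerate_pairs(
    cohort: CohortTable,
    marker: str,
    scope: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> PairPool:
    """Exhaustively enumerate eligible pairs for one marker and scope.

    Samples with the marker not assessed are excluded; a group contributes
    pairs only if it retains at least two eligible samples.  Raises
    :class:`NoPairsError` on an empty pool.
    """
    if scope not in SCOPES:
        raise ConfigurationError(f"scope must be one of {SCOPES}, got {scope!r}")
    col = cohort.config.hscore_column(marker)
    df = cohort.samples.dropna(subset=[col])
    status = (df[col] >= threshold).to_numpy()

    pair_status: list[tuple[bool, bool]] = []
    groups: list[tuple] = []
    if scope == "intra_tumoral":
        for key, idx in df.groupby(["patient_id", "site_id", "block_id"]).indices.items():
            s = status[np.asarray(idx)]
            for i in range(len(s)):
                for j in range(i + 1, len(s)):
                    pair_status.append((s[i], s[j]))
                    groups.append(key)
    else:
        blocks = df[["patient_id", "site_id", "block_id"]].apply(tuple, axis=1).to_numpy()
        for key, idx in df.groupby("patient_id").indices.items():
            idx = np.asarray(idx)
            s, b = status[idx], blocks[idx]
            for i in range(len(s)):
                for j in range(i + 1, len(s)):
                    if b[i] != b[j]:
                        pair_status.append((s[i], s[j]))
                        groups.append((key,))
    if not pair_status:
        raise NoPairsError(f"no eligible {scope} pairs for marker {marker!r}")
    return PairPool(
        scope=scope,
        marker=marker,
        threshold=threshold,
        statuses=np.asarray(pair_status, dtype=bool),
        groups=groups,
    )


def heterogeneity_exact(pool: PairPool, weighting: str = "pair") -> float:
    """Exact discordance probability over the enumerated pair population.

    ``pair`` weighting treats every eligible pair as equally likely;
    ``group`` weighting averages each group's discordant fraction with equal
    group weights.
    """
    disc = pool.discordant
    if weighting == "pair":
        return float(disc.mean())
    if weighting == "group":
        inverse, g = _group_indices(pool.groups)
        sums = np.bincount(inverse, weights=disc.astype(float), minlength=g)
        counts = np.bincount(inverse, minlength=g)
        return float(np.mean(sums / counts))
    raise ConfigurationError(f"weighting must be 'pair' or 'group', got {weighting!r}")


def _group_indices(groups: list[tuple]) -> tuple[np.ndarray, int]:
    """Map group keys to dense indices in first-appearance order (stable
    across processes, unlike hash-based grouping)."""
    index: dict[tuple, int] = {}
    inverse = np.empty(len(groups), dtype=np.intp)
    for i, g in enumerate(groups):
        inverse[i] = index.setdefault(g, len(index))
    return inverse, len(index)


@dataclass
class BcaInterval:
    """BCa confidence limits with the bias and acceleration constants."""

    low: float
    high: float
    z0: float
    acceleration: float
    level: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.low, self.high))


def bca_interval(
    replicates: np.ndarray,
    observed: float,
    jackknife: np.ndarray,
    level: float = 0.95,
) -> BcaInterval:
    """Bias-corrected and accelerated bootstrap confidence limits.

    The bias constant z0 is the normal quantile of the fraction of replicate
    statistics below the observed value; the acceleration is the jackknife
    third-moment skewness ``sum(d^3) / (6 * sum(d^2)^1.5)`` with
    ``d = mean(jackknife) - jackknife``.  An all-identical replicate
    distribution is returned as a flagged point-mass interval rather than an
    error.
    """
    replicates = np.asarray(replicates, dtype=float)
    jackknife = np.asarray(jackknife, dtype=float)
    if replicates.size < 2:
        raise ConfigurationError("need at least 2 bootstrap replicates")
    if not 0 < level < 1:
        raise ConfigurationError(f"confidence level must be in (0,1), got {level}")

    if np.allclose(replicates, replicates[0]):
        v = float(replicates[0])
        return BcaInterval(v, v, 0.0, 0.0, level, degenerate=True)

    n = replicates.size
    below = np.sum(replicates < observed) + 0.5 * np.sum(replicates == observed)
    prop = min(max(below / n, 0.5 / n), 1 - 0.5 / n)  # keep z0 finite
    z0 = float(norm.ppf(prop))

    d = jackknife.mean() - jackknife
    denom = np.sum(d**2) ** 1.5
    accel = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - level
    lo_hi = []
    for a in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = norm.ppf(a)
        adj = norm.cdf(z0 + (z0 + z) / (1.0 - accel * (z0 + z)))
        lo_hi.append(float(np.quantile(replicates, adj)))
    return BcaInterval(lo_hi[0], lo_hi[1], z0, accel, level)


@dataclass
class HeterogeneityEstimate:
    """Bootstrap heterogeneity estimate with BCa 95% limits."""

    scope: str
    marker: str
    point_estimate: float
    ci_low: float
    ci_high: float
    n_pairs_population: int
    n_pairs_sampled: int
    n_boot: int
    seed: int
    resample_unit: str
    degenerate: bool = False
    threshold: float = DEFAULT_THRESHOLD

    def as_row(self) -> dict:
        return {
            "marker": self.marker,
            "scope": self.scope,
            "estimate_pct": round(100 * self.point_estimate),
            "estimate": self.point_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pairs_population": self.n_pairs_population,
            "n_pairs_sampled": self.n_pairs_sampled,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "resample_unit": self.resample_unit,
            "degenerate": self.degenerate,
        }


def _patient_replicates(
    pool: PairPool, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster bootstrap: resample whole groups (patients/blocks)."""
    disc = pool.discordant.astype(float)
    inverse, g = _group_indices(pool.groups)
    sums = np.bincount(inverse, weights=disc, minlength=g)
    counts = np.bincount(inverse, minlength=g)
    draws = rng.integers(0, g, size=(n_boot, g))
    reps = sums[draws].sum(axis=1) / counts[draws].sum(axis=1)
    # leave-one-group-out jackknife
    tot_s, tot_c = sums.sum(), counts.sum()
    jack = (tot_s - sums) / (tot_c - counts)
    return reps, jack


def heterogeneity_bootstrap(
    pool: PairPool,
    n_pairs: int | None = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    resample_unit: str = "pair",
) -> HeterogeneityEstimate:
    """Bootstrap estimate of the heterogeneity index with BCa 95% limits.

    Each replicate draws ``n_pairs`` pairs uniformly with replacement from
    the pooled pair population (``n_pairs=None`` uses the pool size, the
    classical bootstrap); the statistic is the discordant fraction, the point
    estimate its mean over replicates.  ``resample_unit="patient"`` instead
    resamples whole groups to respect within-patient clustering.  Fully
    reproducible for a given seed.
    """
    if n_boot < 1 or (n_pairs is not None and n_pairs < 1):
        raise ConfigurationError("n_pairs and n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    disc = pool.discordant.astype(float)
    n = pool.n_pairs

    if resample_unit == "pair":
        m = n if n_pairs is None else int(n_pairs)
        draws = rng.integers(0, n, size=(n_boot, m))
        reps = disc[draws].mean(axis=1)
        total = disc.sum()
        jack = (total - disc) / (n - 1) if n > 1 else np.array([total])
        sampled = m
    elif resample_unit == "patient":
        reps, jack = _patient_replicates(pool, n_boot, rng)
        sampled = n
    else:
        raise ConfigurationError(
            f"resample_unit must be 'pair' or 'patient', got {resample_unit!r}"
        )

    observed = heterogeneity_exact(
        pool, weighting="pair" if resample_unit == "pair" else "group"
    )
    ci = bca_interval(reps, observed, jack)
    return HeterogeneityEstimate(
        scope=pool.scope,
        marker=pool.marker,
        point_estimate=float(reps.mean()),
        ci_low=ci.low,
        ci_high=ci.high,
        n_pairs_population=n,
        n_pairs_sampled=sampled,
        n_boot=n_boot,
        seed=seed,
        resample_unit=resample_unit,
        degenerate=ci.degenerate,
        threshold=pool.threshold,
    )
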