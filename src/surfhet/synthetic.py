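"""Synthetic multi-site rapid-autopsy cohort generator.

Emulates the statistical structure the estimators assume: ~52 patients, each
with several metastatic sites (one tumor block per site, 1-4 TMA cores per
block, ~750 cores in total), a per-patient dominant molecular subtype with
occasional within-patient subtype switching, subtype-conditional marker
H-score distributions, within-block score correlation, additive anatomic-site
shifts and per-patient genomic alterations with known log-odds effects on
marker positivity.

H-scores are drawn from a three-part mixture per (subtype, marker) cell:
a point mass at 0 (no expression), a point mass at 200 (saturated staining)
and a scaled Beta interior, with the interior solved numerically so the
cell's marginal median lands on its configured anchor.  Every generated
cohort is paired with a :class:`CohortTruth` carrying the realized per-sample
statuses and generating parameters, so downstream estimators can be tested
against ground truth by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist
from scipy.optimize import brentq
from scipy.stats import norm

from .cohort import CohortTable
from .config import SUBTYPES, SchemaConfig
from .errors import ConfigurationError
from .scoring import DEFAULT_THRESHOLD, HSCORE_MAX


@dataclass(frozen=True)
class MarkerCell:
    """Mixture parameters for one (subtype, marker) H-score distribution.

    ``p_zero``/``p_max`` are the point masses at 0 and 200; ``median_anchor``
    is the target marginal median on the H-score scale; ``kappa`` the Beta
    concentration of the interior component.
    """

    p_zero: float
    p_max: float
    median_anchor: float
    kappa: float = 3.0

    def interior_beta(self) -> tuple[float, float]:
        """Solve interior Beta(a, b) so the cell median hits the anchor."""
        if self.p_zero + self.p_max > 1:
            raise ConfigurationError("p_zero + p_max must be <= 1")
        interior = 1.0 - self.p_zero - self.p_max
        if self.median_anchor <= 0 or self.p_zero >= 0.5 or interior <= 0:
            mu = 0.25  # median is pinned at 0 (or no interior); shape free
            return mu * self.kappa, (1 - mu) * self.kappa
        if self.p_max >= 0.5:
            mu = 0.6  # median pinned at 200
            return mu * self.kappa, (1 - mu) * self.kappa
        q = (0.5 - self.p_zero) / interior
        s = min(self.median_anchor / HSCORE_MAX, 0.995)
        if not 0 < q < 1:
            raise ConfigurationError(
                f"cell {self} has no interior median (q={q:.3f})"
            )

        def f(mu: float) -> float:
            return beta_dist.ppf(q, mu * self.kappa, (1 - mu) * self.kappa) - s

        mu = brentq(f, 1e-3, 1 - 1e-3, xtol=1e-10)
        return mu * self.kappa, (1 - mu) * self.kappa


def _default_marker_cells() -> dict[str, dict[str, MarkerCell]]:
    """Per-marker, per-subtype mixture defaults.

    Median anchors follow the subtype-conditional expression pattern of the
    markers: TROP2 high outside NEPC, DLL3/CEACAM5 largely NEPC-restricted,
    PSMA strongest in adenocarcinoma, and the axis markers (AR, NKX3.1, SYP,
    INSM1) tracking their own subtype axes.
    """
    c = MarkerCell
    ad, ne, amp, dn = SUBTYPES  # AR+/NE-, AR-/NE+, AR+/NE+, AR-/NE-
    return {
        "TROP2": {ad: c(0.03, 0.70, 200), ne: c(0.60, 0.05, 0),
                  amp: c(0.05, 0.35, 180), dn: c(0.03, 0.70, 200)},
        "PSMA": {ad: c(0.10, 0.10, 120), ne: c(0.85, 0.00, 0),
                 amp: c(0.15, 0.10, 100), dn: c(0.40, 0.02, 12)},
        "DLL3": {ad: c(0.99, 0.00, 0), ne: c(0.17, 0.05, 90),
                 amp: c(0.85, 0.02, 0), dn: c(0.95, 0.00, 0)},
        "CEACAM5": {ad: c(0.85, 0.01, 0), ne: c(0.35, 0.10, 60),
                    amp: c(0.70, 0.02, 0), dn: c(0.60, 0.03, 0)},
        "AR": {ad: c(0.03, 0.30, 160), ne: c(0.85, 0.00, 0),
               amp: c(0.03, 0.30, 160), dn: c(0.85, 0.00, 0)},
        "NKX3.1": {ad: c(0.05, 0.25, 150), ne: c(0.80, 0.00, 0),
                   amp: c(0.05, 0.25, 150), dn: c(0.80, 0.00, 0)},
        "SYP": {ad: c(0.85, 0.00, 0), ne: c(0.05, 0.30, 150),
                amp: c(0.05, 0.30, 150), dn: c(0.85, 0.00, 0)},
        "INSM1": {ad: c(0.88, 0.00, 0), ne: c(0.08, 0.20, 120),
                  amp: c(0.08, 0.20, 120), dn: c(0.88, 0.00, 0)},
    }


def _default_site_weights() -> dict[str, float]:
    return {
        "vertebral_bone": 0.22,
        "other_bone": 0.20,
        "liver": 0.15,
        "lymph_node": 0.15,
        "lung": 0.08,
        "prostate_bed": 0.05,
        "adrenal": 0.04,
        "dura": 0.02,
        "peritoneum": 0.04,
        "pleura": 0.03,
        "other_soft_tissue": 0.02,
    }


def _default_site_shifts() -> dict[str, dict[str, float]]:
    # modest additive organ-site effects on mean H-score
    return {
        "TROP2": {"liver": -17.0, "lung": -40.0},
        "DLL3": {"liver": 11.0, "lung": 14.0},
        "CEACAM5": {"prostate_bed": 19.0},
    }


def _default_genomic_prevalence() -> dict[str, dict[str, float]]:
    ad, ne, amp, dn = SUBTYPES
    return {
        "AR": {ad: 0.45, ne: 0.10, amp: 0.40, dn: 0.20},
        "BRCA2": {ad: 0.08, ne: 0.08, amp: 0.08, dn: 0.08},
        "CHD1": {ad: 0.10, ne: 0.05, amp: 0.08, dn: 0.10},
        "PTEN": {ad: 0.35, ne: 0.30, amp: 0.30, dn: 0.35},
        "RB1": {ad: 0.10, ne: 0.60, amp: 0.35, dn: 0.25},
        "SPOP": {ad: 0.10, ne: 0.03, amp: 0.05, dn: 0.06},
        "TP53": {ad: 0.45, ne: 0.60, amp: 0.55, dn: 0.50},
    }


def _default_genomic_effects() -> dict[tuple[str, str], float]:
    """Log-odds shifts of marker positivity in altered patients."""
    ln = float(np.log(4.0))
    return {
        ("AR", "PSMA"): ln,
        ("AR", "TROP2"): float(np.log(2.0)),
        ("AR", "DLL3"): -float(np.log(3.0)),
        ("AR", "CEACAM5"): -float(np.log(3.0)),
        ("RB1", "PSMA"): -ln,
        ("RB1", "TROP2"): -ln,
        ("RB1", "DLL3"): float(np.log(3.0)),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (seeded, serializable)."""

    n_patients: int = 52
    mean_sites_per_patient: float = 372.0 / 52.0
    cores_per_block_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.30, 3: 0.18, 4: 0.12}
    )
    dominant_subtype_probs: dict[str, float] = field(
        default_factory=lambda: {
            "AR+/NE-": 0.60, "AR-/NE+": 0.15, "AR+/NE+": 0.08, "AR-/NE-": 0.17,
        }
    )
    #: fraction of patients whose metastases mix two subtypes; pure patients
    #: never switch
    mixed_patient_prob: float = 0.20
    #: per-site probability, within a mixed patient, of carrying the
    #: secondary rather than the dominant subtype
    switching_prob: float = 0.35
    site_weights: dict[str, float] = field(default_factory=_default_site_weights)
    marker_cells: dict[str, dict[str, MarkerCell]] = field(
        default_factory=_default_marker_cells
    )
    site_shifts: dict[str, dict[str, float]] = field(default_factory=_default_site_shifts)
    core_sd: float = 12.0
    #: SD of a per-patient, per-marker random shift on the zero-inflation
    #: logit; models shared clonal origin of a patient's metastases, without
    #: which within-patient discordance is implausibly high.
    patient_zero_logit_sd: float = 4.0
    genomic_prevalence: dict[str, dict[str, float]] = field(
        default_factory=_default_genomic_prevalence
    )
    genomic_effects: dict[tuple[str, str], float] = field(
        default_factory=_default_genomic_effects
    )
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.mean_sites_per_patient <= 0:
            raise ConfigurationError("need >= 1 patient and a positive site rate")
        for probs, what in (
            (self.cores_per_block_probs.values(), "cores_per_block_probs"),
            (self.dominant_subtype_probs.values(), "dominant_subtype_probs"),
            (self.site_weights.values(), "site_weights"),
        ):
            probs = list(probs)
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{what} must be a probability distribution")
        if not 0 <= self.switching_prob <= 1 or not 0 <= self.mixed_patient_prob <= 1:
            raise ConfigurationError(
                "switching_prob and mixed_patient_prob must be in [0, 1]"
            )


@dataclass
class CohortTruth:
    """Ground truth paired with a generated cohort.

    ``blocks`` carries the true subtype of every emitted block; ``statuses``
    the realized binarized status of every emitted sample per marker;
    ``positive_prob`` the per-sample marginal probability of positivity given
    its block's latent base value.
    """

    blocks: pd.DataFrame
    statuses: pd.DataFrame
    positive_prob: pd.DataFrame
    site_shifts: dict[str, dict[str, float]]
    genomic_effects: dict[tuple[str, str], float]
    threshold: float
    seed: int


def generate_cohort(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> tuple[CohortTable, CohortTruth]:
    """Generate a schema-valid synthetic cohort plus its ground truth."""
    config = config or GeneratorConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    schema = SchemaConfig()

    markers = [m for m in schema.markers if m in config.marker_cells]
    beta_params = {
        m: {st: cell.interior_beta() for st, cell in by_subtype.items()}
        for m, by_subtype in config.marker_cells.items()
    }
    subtype_names = list(config.dominant_subtype_probs)
    subtype_p = np.array([config.dominant_subtype_probs[s] for s in subtype_names])
    site_names = list(config.site_weights)
    site_p = np.array([config.site_weights[s] for s in site_names])
    core_ns = np.array(list(config.cores_per_block_probs))
    core_p = np.array(list(config.cores_per_block_probs.values()))
    genes = list(config.genomic_prevalence)

    rows: list[dict] = []
    block_rows: list[dict] = []
    status_rows: list[dict] = []
    prob_rows: list[dict] = []
    genomic_rows: list[dict] = []

    for p in range(config.n_patients):
        pid = f"P{p + 1:03d}"
        dominant = subtype_names[rng.choice(len(subtype_names), p=subtype_p)]
        flags = {
            g: int(rng.random() < config.genomic_prevalence[g].get(dominant, 0.0))
            for g in genes
        }
        genomic_rows.append({"patient_id": pid, **flags})
        patient_shift = {
            m: float(rng.normal(0.0, config.patient_zero_logit_sd)) for m in markers
        }
        secondary: str | None = None
        if len(subtype_names) > 1 and rng.random() < config.mixed_patient_prob:
            others = [x for x in subtype_names if x != dominant]
            secondary = others[rng.choice(len(others))]
        n_sites = max(1, int(rng.poisson(config.mean_sites_per_patient)))
        for s in range(n_sites):
            sid = f"S{s + 1:02d}"
            bid = "B1"
            anatomic = site_names[rng.choice(len(site_names), p=site_p)]
            subtype = dominant
            if secondary is not None and rng.random() < config.switching_prob:
                subtype = secondary
            block_rows.append(
                {"patient_id": pid, "site_id": sid, "block_id": bid,
                 "anatomic_site": anatomic, "subtype": subtype,
                 "dominant_subtype": dominant}
            )
            n_cores = int(core_ns[rng.choice(len(core_ns), p=core_p)])

            base: dict[str, float] = {}
            for m in markers:
                cell = config.marker_cells[m][subtype]
                p_zero = cell.p_zero
                shift_lo = sum(
                    eff for (g, mm), eff in config.genomic_effects.items()
                    if mm == m and flags.get(g, 0) == 1
                )
                shift_lo += patient_shift[m]
                if shift_lo:
                    # shifts act on positivity log-odds: lower p_zero when
                    # the alteration (or patient effect) raises the odds of
                    # expression
                    p_zero = float(expit(logit(np.clip(p_zero, 1e-6, 1 - 1e-6)) - shift_lo))
                p_max = min(cell.p_max, 1.0 - p_zero)
                u = rng.random()
                if u < p_zero:
                    b = 0.0
                elif u < p_zero + p_max:
                    b = HSCORE_MAX
                else:
                    a, bb = beta_params[m][subtype]
                    b = HSCORE_MAX * float(rng.beta(a, bb))
                if b > 0:
                    b = float(
                        np.clip(b + config.site_shifts.get(m, {}).get(anatomic, 0.0),
                                0.0, HSCORE_MAX)
                    )
                base[m] = b

            for c in range(n_cores):
                cid = f"C{c + 1}"
                row = {"patient_id": pid, "site_id": sid, "block_id": bid,
                       "core_id": cid, "anatomic_site": anatomic}
                st_row = dict(row)
                pr_row = dict(row)
                for m in markers:
                    b = base[m]
                    if b == 0.0:
                        h = 0.0
                        prob = 0.0
                    else:
                        h = float(np.clip(rng.normal(b, config.core_sd), 0.0, HSCORE_MAX))
                        prob = float(norm.sf((config.threshold - b) / config.core_sd))
                    row[schema.hscore_column(m)] = h
                    st_row[m] = bool(h >= config.threshold)
                    pr_row[m] = prob
                rows.append(row)
                status_rows.append(st_row)
                prob_rows.append(pr_row)

    samples = pd.DataFrame(rows)
    genomics = pd.DataFrame(genomic_rows).set_index("patient_id")
    cohort = CohortTable(
        samples=samples,
        config=schema,
        genomics=genomics,
        provenance={"generator_seed": config.seed, "schema_version": "1"},
    )
    cohort.validate()
    truth = CohortTruth(
        blocks=pd.DataFrame(block_rows),
        statuses=pd.DataFrame(status_rows),
        positive_prob=pd.DataFrame(prob_rows),
        site_shifts=config.site_shifts,
        genomic_effects=config.genomic_effects,
        threshold=config.threshold,
        seed=config.seed,
    )
    return cohort, truth


def truth_heterogeneity(truth: CohortTruth, marker: str, scope: str) -> float:
    """Exact discordance from realized statuses by brute-force enumeration.

    Deliberately independent of the pair-pool implementation: plain nested
    loops over :mod:`itertools` combinations, usable as an oracle.
    """
    df = truth.statuses
    n_disc = 0
    n_tot = 0
    if scope == "intra_tumoral":
        grouped = df.groupby(["patient_id", "site_id", "block_id"])[marker]
        for _, vals in grouped:
            for a, b in itertools.combinations(vals.tolist(), 2):
                n_tot += 1
                n_disc += a != b
    elif scope == "inter_tumoral":
        for _, g in df.groupby("patient_id"):
            items = list(
                zip(g[["site_id", "block_id"]].apply(tuple, axis=1), g[marker])
            )
            for (blk_a, a), (blk_b, b) in itertools.combinations(items, 2):
                if blk_a != blk_b:
                    n_tot += 1
                    n_disc += a != b
    else:
        raise ConfigurationError(f"unknown scope {scope!r}")
    if n_tot == 0:
        raise ConfigurationError(f"no {scope} pairs in truth for {marker}")
    return n_disc / n_tot


# ---------------------------------------------------------------------------
# focused simulators for parameter-recovery studies
# ---------------------------------------------------------------------------


def simulate_site_cohort(
    n_patients: int = 40,
    samples_per_site: int = 2,
    sites: tuple[str, ...] = (
        "vertebral_bone", "other_bone", "liver", "lung", "lymph_node", "prostate_bed",
    ),
    base_mean: float = 110.0,
    site_shifts: dict[str, float] | None = None,
    patient_sd: float = 10.0,
    residual_sd: float = 30.0,
    marker: str = "TROP2",
    seed: int = 0,
) -> CohortTable:
    """Balanced cohort with known additive site shifts and patient effects.

    Every patient contributes every site, so the mixed-model site contrasts
    have a clean estimand equal to the configured shifts.
    """
    site_shifts = {"liver": -20.0} if site_shifts is None else site_shifts
    rng = np.random.default_rng(seed)
    schema = SchemaConfig()
    col = schema.hscore_column(marker)
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        u = rng.normal(0.0, patient_sd)
        for s, site in enumerate(sites):
            for c in range(samples_per_site):
                h = base_mean + site_shifts.get(site, 0.0) + u + rng.normal(0, residual_sd)
                rows.append(
                    {"patient_id": pid, "site_id": f"S{s + 1:02d}", "block_id": "B1",
                     "core_id": f"C{c + 1}", "anatomic_site": site,
                     col: float(np.clip(h, 0.0, HSCORE_MAX))}
                )
    cohort = CohortTable(samples=pd.DataFrame(rows), config=schema)
    cohort.validate()
    return cohort


def simulate_genomic_cohort(
    n_patients: int = 100,
    samples_per_patient: int = 3,
    alteration_prevalence: float = 0.3,
    baseline_logit: float = -0.5,
    log_odds: float = float(np.log(4.0)),
    patient_sd: float = 1.0,
    marker: str = "PSMA",
    gene: str = "AR",
    seed: int = 0,
) -> CohortTable:
    """Cohort with a known alteration -> positivity log-odds effect.

    Per-sample positivity follows a random-intercept logistic model; positive
    samples are emitted with H-score 150, negative with 0, so binarization at
    the default threshold recovers the latent outcome exactly.
    """
    rng = np.random.default_rng(seed)
    schema = SchemaConfig()
    col = schema.hscore_column(marker)
    rows, genomic_rows = [], []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        x = int(rng.random() < alteration_prevalence)
        u = rng.normal(0.0, patient_sd)
        genomic_rows.append({"patient_id": pid, gene: x})
        for s in range(samples_per_patient):
            eta = baseline_logit + log_odds * x + u
            y = rng.random() < expit(eta)
            rows.append(
                {"patient_id": pid, "site_id": f"S{s + 1:02d}", "block_id": "B1",
                 "core_id": "C1", "anatomic_site": "other_bone",
                 col: 150.0 if y else 0.0}
            )
    cohort = CohortTable(
        samples=pd.DataFrame(rows),
        config=schema,
        genomics=pd.DataFrame(genomic_rows).set_index("patient_id"),
    )
    cohort.validate()
    return cohort
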