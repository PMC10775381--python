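"""Anatomic-site and genomic association models.

Two clustered regression surfaces:

* ``site_mixed_model`` — per-site mean H-score contrasts from a linear mixed
  model with fixed effects for anatomic site and a random intercept per
  patient (REML, Wald inference), so repeated sampling of the same patient
  does not masquerade as independent evidence;
* ``genomic_logistic`` — odds ratios relating binarized marker expression to
  per-patient genomic alteration flags via a random-intercept logistic
  regression, fit by maximum likelihood with adaptive-free Gauss-Hermite
  quadrature over the patient random effect.

When the random-intercept variance is estimated at (or collapses to) zero
both models reduce exactly to their unclustered counterparts; in particular
the logistic odds ratio then agrees with the classical 2x2 odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import minimize
from scipy.special import log_expit, roots_hermite
from scipy.stats import norm

from .cohort import CohortTable
from .errors import DegenerateOutcomeError, FittingError, SchemaError
from .scoring import DEFAULT_THRESHOLD

_Z95 = float(norm.ppf(0.975))


# ---------------------------------------------------------------------------
# linear mixed model: site contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteContrast:
    """Mean H-score difference of one site versus the reference site."""

    marker: str
    site: str
    reference_site: str
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_samples: int
    reference_mean: float
    reference_ci_low: float
    reference_ci_high: float
    wide_ci: bool = False  # site represented by a single sample
    singular_fit: bool = False  # patient variance estimated ~0


def site_mixed_model(
    cohort: CohortTable,
    marker: str,
    reference_site: str = "vertebral_bone",
) -> list[SiteContrast]:
    """Per-site mean-expression contrasts versus a reference site.

    Fits ``hscore ~ C(anatomic_site)`` with a patient random intercept by
    REML and returns Wald 95% CIs and two-sided p-values for every
    non-reference site, plus a zero contrast row for the reference carrying
    its estimated mean.  A vanishing patient variance is legitimate and
    flagged; estimates then coincide with ordinary least squares.
    """
    col = cohort.config.hscore_column(marker)
    if col not in cohort.samples.columns:
        raise SchemaError(f"marker {marker!r} not present in cohort")
    df = cohort.samples.dropna(subset=[col])[["patient_id", "anatomic_site", col]]
    df = df.rename(columns={col: "h"}).reset_index(drop=True)
    sites = df["anatomic_site"].unique().tolist()
    if reference_site not in sites:
        raise DegenerateOutcomeError(
            f"reference site {reference_site!r} absent for marker {marker}"
        )
    if len(sites) < 2:
        raise DegenerateOutcomeError("need >= 2 anatomic sites to estimate contrasts")
    if df["patient_id"].nunique() < 2:
        raise DegenerateOutcomeError("need >= 2 patients for a random-intercept model")

    formula = f"h ~ C(anatomic_site, Treatment(reference='{reference_site}'))"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, df, groups=df["patient_id"]).fit(reml=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise FittingError(f"mixed model failed for {marker}: {exc}") from exc
    singular = bool(np.asarray(fit.cov_re).item() < 1e-8)

    site_n = df["anatomic_site"].value_counts()
    ref_mean = float(fit.params["Intercept"])
    ref_se = float(fit.bse["Intercept"])
    ref_lo, ref_hi = ref_mean - _Z95 * ref_se, ref_mean + _Z95 * ref_se

    out = [
        SiteContrast(
            marker=marker,
            site=reference_site,
            reference_site=reference_site,
            mean_difference=0.0,
            ci_low=0.0,
            ci_high=0.0,
            p_value=float("nan"),
            n_samples=int(site_n[reference_site]),
            reference_mean=ref_mean,
            reference_ci_low=ref_lo,
            reference_ci_high=ref_hi,
            singular_fit=singular,
        )
    ]
    prefix = f"C(anatomic_site, Treatment(reference='{reference_site}'))[T."
    for site in sorted(s for s in sites if s != reference_site):
        term = f"{prefix}{site}]"
        est = float(fit.params[term])
        se = float(fit.bse[term])
        out.append(
            SiteContrast(
                marker=marker,
                site=site,
                reference_site=reference_site,
                mean_difference=est,
                ci_low=est - _Z95 * se,
                ci_high=est + _Z95 * se,
                p_value=float(fit.pvalues[term]),
                n_samples=int(site_n[site]),
                reference_mean=ref_mean,
                reference_ci_low=ref_lo,
                reference_ci_high=ref_hi,
                wide_ci=bool(site_n[site] < 2),
                singular_fit=singular,
            )
        )
    return out


def site_contrasts_frame(contrasts: list[SiteContrast]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contrasts])


# ---------------------------------------------------------------------------
# random-intercept logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogitFit:
    """ML fit of logit(P(y=1)) = b0 + b1*x + u_cluster, u ~ N(0, sigma^2)."""

    intercept: float
    coef: float
    coef_se: float
    sigma: float
    loglik: float
    converged: bool


def _cluster_loglik(
    params: np.ndarray,
    y: list[np.ndarray],
    x: list[np.ndarray],
    nodes: np.ndarray,
    logw: np.ndarray,
) -> float:
    b0, b1, sigma = params
    total = 0.0
    scaled = np.sqrt(2.0) * sigma * nodes  # integration over N(0, sigma^2)
    for yi, xi in zip(y, x):
        eta = b0 + b1 * xi[:, None] + scaled[None, :]
        ll = log_expit(eta) * yi[:, None] + log_expit(-eta) * (1.0 - yi[:, None])
        node_ll = ll.sum(axis=0) + logw
        m = node_ll.max()
        total += m + np.log(np.exp(node_ll - m).sum())
    return total


def fit_random_intercept_logit(
    y: np.ndarray,
    x: np.ndarray,
    cluster: np.ndarray,
    n_nodes: int = 25,
) -> LogitFit:
    """Maximum-likelihood random-intercept logistic regression.

    The marginal likelihood integrates the patient-level intercept out with
    Gauss-Hermite quadrature.  With one observation per cluster (or a
    variance estimate on the zero boundary) the fit reduces to ordinary
    logistic regression, for which the Wald SE is taken from the standard
    information matrix.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0} or set(np.unique(x)) - {0.0, 1.0}:
        raise DegenerateOutcomeError("outcome and exposure must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("outcome has a single observed class")
    if len(np.unique(x)) < 2:
        raise DegenerateOutcomeError("exposure has a single observed class")

    codes, _ = pd.factorize(pd.Series(cluster), sort=True)
    ys = [y[codes == c] for c in range(codes.max() + 1)]
    xs = [x[codes == c] for c in range(codes.max() + 1)]

    nodes, weights = roots_hermite(n_nodes)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    # starting values from the plain-logistic 2x2 solution
    glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    x0 = np.array([glm.params[0], glm.params[1], 0.5])

    if max(len(v) for v in ys) == 1:
        # singleton clusters: sigma is unidentifiable (the marginal model is
        # exactly ordinary logistic regression), so report that fit
        return LogitFit(
            intercept=float(glm.params[0]),
            coef=float(glm.params[1]),
            coef_se=float(glm.bse[1]),
            sigma=0.0,
            loglik=float(glm.llf),
            converged=True,
        )

    res = minimize(
        lambda p: -_cluster_loglik(p, ys, xs, nodes, logw),
        x0,
        method="L-BFGS-B",
        bounds=[(-20, 20), (-20, 20), (0.0, 10.0)],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    b0, b1, sigma = res.x

    if sigma < 1e-4:
        # boundary: model is ordinary logistic regression; use its exact MLE
        return LogitFit(
            intercept=float(glm.params[0]),
            coef=float(glm.params[1]),
            coef_se=float(glm.bse[1]),
            sigma=0.0,
            loglik=float(glm.llf),
            converged=True,
        )

    se = _wald_se(res.x, ys, xs, nodes, logw)
    return LogitFit(
        intercept=float(b0),
        coef=float(b1),
        coef_se=se,
        sigma=float(sigma),
        loglik=float(-res.fun),
        converged=bool(res.success),
    )


def _wald_se(params, ys, xs, nodes, logw, h: float = 1e-4) -> float:
    """Central-difference Hessian of the log-likelihood; SE of the slope."""
    k = len(params)
    H = np.zeros((k, k))
    f = lambda p: _cluster_loglik(p, ys, xs, nodes, logw)
    for i in range(k):
        for j in range(i, k):
            pp = params.copy()
            pp[i] += h
            pp[j] += h
            fpp = f(pp)
            pp[j] -= 2 * h
            fpm = f(pp)
            pp[i] -= 2 * h
            fmm = f(pp)
            pp[j] += 2 * h
            fmp = f(pp)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(-H)
        var = cov[1, 1]
        if var <= 0:
            raise np.linalg.LinAlgError("non-positive variance")
        return float(np.sqrt(var))
    except np.linalg.LinAlgError as exc:
        raise FittingError(f"Wald covariance not available: {exc}") from exc


# ---------------------------------------------------------------------------
# genomic association wrapper
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicAssociation:
    """Odds ratio of marker positivity given genomic alteration status."""

    marker: str
    gene: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_altered: int
    n_wildtype: int
    expression_dichotomization: str
    sigma: float
    separated: bool = False


def _check_separation(y: np.ndarray, x: np.ndarray) -> bool:
    cells = [
        ((x == a) & (y == b)).sum() for a in (0, 1) for b in (0, 1)
    ]
    return any(c == 0 for c in cells)


def _association_from_arrays(
    y: np.ndarray,
    x: np.ndarray,
    cluster: np.ndarray,
    marker: str,
    gene: str,
    dichotomization: str,
) -> GenomicAssociation:
    uniq = pd.Series(cluster).groupby(pd.Series(cluster)).size()
    n_alt = int(pd.DataFrame({"c": cluster, "x": x}).groupby("c")["x"].max().sum())
    n_wt = int(len(uniq) - n_alt)

    if _check_separation(y, x):
        disc = float("inf") if ((x == 1) & (y == 0)).sum() == 0 else 0.0
        return GenomicAssociation(
            marker=marker,
            gene=gene,
            odds_ratio=disc,
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            n_altered=n_alt,
            n_wildtype=n_wt,
            expression_dichotomization=dichotomization,
            sigma=float("nan"),
            separated=True,
        )

    fit = fit_random_intercept_logit(y, x, cluster)
    z = fit.coef / fit.coef_se
    p = 2 * norm.sf(abs(z))
    return GenomicAssociation(
        marker=marker,
        gene=gene,
        odds_ratio=float(np.exp(fit.coef)),
        ci_low=float(np.exp(fit.coef - _Z95 * fit.coef_se)),
        ci_high=float(np.exp(fit.coef + _Z95 * fit.coef_se)),
        p_value=float(p),
        n_altered=n_alt,
        n_wildtype=n_wt,
        expression_dichotomization=dichotomization,
        sigma=fit.sigma,
        separated=False,
    )


def genomic_logistic(
    cohort: CohortTable,
    marker: str,
    gene: str,
    threshold: float = DEFAULT_THRESHOLD,
    collapse: str = "any",
) -> GenomicAssociation:
    """Protein-mode association: binarized IHC positivity vs alteration flag.

    ``collapse="any"`` (default) scores each patient positive when any
    measured sample is positive, mirroring patient-level mosaics;
    ``collapse="all"`` requires all sites positive; ``collapse="none"``
    keeps sample-level outcomes with a patient random intercept.
    """
    if cohort.genomics is None or gene not in cohort.genomics.columns:
        raise SchemaError(f"no genomic flags for gene {gene!r}")
    col = cohort.config.hscore_column(marker)
    df = cohort.samples.dropna(subset=[col])[["patient_id", col]]
    flags = cohort.genomics[gene].dropna()
    df = df[df["patient_id"].isin(flags.index)]
    if df.empty:
        raise DegenerateOutcomeError(f"no samples with both {marker} and {gene} data")
    pos = (df[col] >= threshold).astype(float)

    if collapse in ("any", "all"):
        how = "max" if collapse == "any" else "min"
        per = pos.groupby(df["patient_id"]).agg(how)
        y = per.to_numpy()
        x = flags.loc[per.index].to_numpy(dtype=float)
        cluster = per.index.to_numpy()
    elif collapse == "none":
        y = pos.to_numpy()
        x = flags.loc[df["patient_id"]].to_numpy(dtype=float)
        cluster = df["patient_id"].to_numpy()
    else:
        raise SchemaError(f"collapse must be any/all/none, got {collapse!r}")

    return _association_from_arrays(
        y, x, cluster, marker, gene, f"H-score >= {threshold:g} ({collapse})"
    )


def transcript_logistic(
    expression: pd.DataFrame,
    marker: str,
    gene: str,
    fpkm_threshold: float = 1.0,
) -> GenomicAssociation:
    """Transcript-mode association from a per-sample expression table.

    ``expression`` needs columns ``patient_id``, ``<marker>`` (FPKM) and
    ``gene_<gene>`` (0/1 alteration flag); FPKM is dichotomized at
    ``fpkm_threshold`` (expressed iff FPKM >= threshold).
    """
    gcol = f"gene_{gene}"
    for c in ("patient_id", marker, gcol):
        if c not in expression.columns:
            raise SchemaError(f"expression table missing column {c!r}")
    df = expression.dropna(subset=[marker, gcol])
    y = (df[marker] >= fpkm_threshold).to_numpy(dtype=float)
    x = df[gcol].to_numpy(dtype=float)
    cluster = df["patient_id"].to_numpy()
    return _association_from_arrays(
        y, x, cluster, marker, gene, f"FPKM >= {fpkm_threshold:g}"
    )


def associations_frame(rows: list[GenomicAssociation]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
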