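"""Binarized co-expression tables and patient-level expressor classes.

Two complementary summaries of target positivity (H-score >= threshold):

* a 2x2 contingency table of joint positivity for a marker pair, optionally
  restricted to one molecular subtype, counting TMA cores (default) or
  tumor blocks;
* a per-patient three-way classification for one marker over that patient's
  metastatic sites: non-expressor (all sites negative), heterogeneous (both
  positive and negative sites) or uniform-high (all sites positive).

Percentages are rounded half-up, to integers by default with an optional
one-decimal mode, matching how such tables are conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cohort import CohortTable
from .errors import EmptyStratumError, IntegrityError
from .scoring import DEFAULT_THRESHOLD
from .subtyping import attach_subtypes


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _unit_scores(
    cohort: CohortTable,
    markers: list[str],
    unit: str,
    subtypes: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate per-core H-scores to the requested unit (max over cores)."""
    df = cohort.samples.copy()
    cols = {m: cohort.config.hscore_column(m) for m in markers}
    keep = ["patient_id", "site_id", "block_id", "core_id", *cols.values()]
    if subtypes is not None:
        df["subtype"] = subtypes.to_numpy()
        keep.append("subtype")
    df = df[keep].rename(columns={v: k for k, v in cols.items()})
    if unit == "core":
        return df
    group_cols = {
        "block": ["patient_id", "site_id", "block_id"],
        "site": ["patient_id", "site_id"],
    }.get(unit)
    if group_cols is None:
        raise IntegrityError(f"unknown analysis unit {unit!r}")
    agg = {m: "max" for m in markers}
    if subtypes is not None:
        agg["subtype"] = "first"
    return df.groupby(group_cols, as_index=False, sort=False).agg(agg)


@dataclass(frozen=True)
class CoexpressionTable:
    """Joint binarized status counts for one marker pair in one stratum."""

    marker_a: str
    marker_b: str
    stratum: str
    both_positive: int
    a_only: int
    b_only: int
    neither: int
    threshold: float

    @property
    def total(self) -> int:
        return self.both_positive + self.a_only + self.b_only + self.neither

    def percentages(self, decimals: int = 0) -> dict[str, float]:
        return {
            cell: round_half_up(100.0 * getattr(self, cell) / self.total, decimals)
            for cell in ("both_positive", "a_only", "b_only", "neither")
        }

    def swapped(self) -> "CoexpressionTable":
        """The same table with marker roles exchanged."""
        return CoexpressionTable(
            self.marker_b,
            self.marker_a,
            self.stratum,
            self.both_positive,
            self.b_only,
            self.a_only,
            self.neither,
            self.threshold,
        )


def tabulate_coexpression(
    cohort: CohortTable,
    marker_a: str,
    marker_b: str,
    stratum: str = "all",
    unit: str = "core",
    threshold: float = DEFAULT_THRESHOLD,
    subtypes: pd.Series | None = None,
) -> CoexpressionTable:
    """Joint positivity contingency table for two markers.

    Units missing either marker are excluded from the denominator.  When
    ``stratum`` names a subtype, units are filtered on per-core subtype calls
    (``subtypes`` may supply precomputed calls aligned to ``cohort.samples``;
    otherwise block-level calls are derived from the subtype markers).
    """
    if stratum != "all" and subtypes is None:
        subtypes = attach_subtypes(cohort)
    units = _unit_scores(cohort, [marker_a, marker_b], unit, subtypes=subtypes)
    if stratum != "all":
        units = units[units["subtype"] == stratum]
    units = units.dropna(subset=[marker_a, marker_b])
    if units.empty:
        raise EmptyStratumError(
            f"no units with both {marker_a} and {marker_b} measured in stratum "
            f"{stratum!r}"
        )
    a_pos = units[marker_a] >= threshold
    b_pos = units[marker_b] >= threshold
    return CoexpressionTable(
        marker_a=marker_a,
        marker_b=marker_b,
        stratum=stratum,
        both_positive=int((a_pos & b_pos).sum()),
        a_only=int((a_pos & ~b_pos).sum()),
        b_only=int((~a_pos & b_pos).sum()),
        neither=int((~a_pos & ~b_pos).sum()),
        threshold=threshold,
    )


@dataclass(frozen=True)
class PatientExpressionClass:
    """Three-way expressor class for one patient and marker."""

    patient_id: str
    marker: str
    expression_class: str  # non_expressor | heterogeneous | uniform_high
    n_units: int
    threshold: float


def classify_patient(
    cohort: CohortTable,
    patient_id: str,
    marker: str,
    unit: str = "site",
    site_aggregator: str = "max",
    threshold: float = DEFAULT_THRESHOLD,
) -> PatientExpressionClass:
    """Classify one patient's marker expression across metastatic sites.

    Cores are aggregated to the analysis unit (site by default) with
    ``site_aggregator``; the patient is a non-expressor iff every unit is
    below threshold, uniform-high iff every unit is at or above it, and
    heterogeneous otherwise.  A patient with no measured unit is not
    evaluable and raises :class:`EmptyStratumError`.
    """
    df = cohort.samples
    sub = CohortTable(
        samples=df[df["patient_id"] == patient_id].reset_index(drop=True),
        config=cohort.config,
    )
    if sub.samples.empty:
        raise IntegrityError(f"unknown patient {patient_id!r}")
    if site_aggregator != "max":
        if site_aggregator != "mean":
            raise IntegrityError(f"unknown site aggregator {site_aggregator!r}")
    units = _unit_scores(sub, [marker], unit)
    if site_aggregator == "mean" and unit != "core":
        # redo aggregation with mean
        raw = sub.samples.rename(columns={cohort.config.hscore_column(marker): marker})
        group_cols = ["patient_id", "site_id"] if unit == "site" else [
            "patient_id", "site_id", "block_id"
        ]
        units = raw.groupby(group_cols, as_index=False, sort=False).agg({marker: "mean"})
    scores = units[marker].dropna()
    if scores.empty:
        raise EmptyStratumError(
            f"patient {patient_id!r} has no measured {marker} unit; not evaluable"
        )
    pos = scores >= threshold
    if pos.all():
        cls = "uniform_high"
    elif (~pos).all():
        cls = "non_expressor"
    else:
        cls = "heterogeneous"
    return PatientExpressionClass(
        patient_id=patient_id,
        marker=marker,
        expression_class=cls,
        n_units=int(len(scores)),
        threshold=threshold,
    )


def classify_all_patients(
    cohort: CohortTable,
    marker: str,
    unit: str = "site",
    site_aggregator: str = "max",
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, list[str]]:
    """Classify every evaluable patient; returns (classes, excluded patients).

    Patients without a single measured unit for the marker are excluded from
    the denominator and returned separately so the bookkeeping is explicit.
    """
    rows, excluded = [], []
    for pid in cohort.samples["patient_id"].unique():
        try:
            c = classify_patient(
                cohort, pid, marker, unit=unit,
                site_aggregator=site_aggregator, threshold=threshold,
            )
        except EmptyStratumError:
            excluded.append(pid)
            continue
        rows.append(
            {
                "patient_id": c.patient_id,
                "marker": c.marker,
                "expression_class": c.expression_class,
                "n_units": c.n_units,
            }
        )
    return pd.DataFrame(rows), excluded


@dataclass(frozen=True)
class PositivityResult:
    """Positive fraction with explicit numerator/denominator bookkeeping."""

    marker: str
    stratum: str
    unit: str
    n_positive: int
    n_total: int
    threshold: float

    def percentage(self, decimals: int = 0) -> float:
        return round_half_up(100.0 * self.n_positive / self.n_total, decimals)


def subtype_positivity(
    cohort: CohortTable,
    marker: str,
    subtype: str | None = None,
    unit: str = "block",
    threshold: float = DEFAULT_THRESHOLD,
    subtypes: pd.Series | None = None,
) -> PositivityResult:
    """Fraction of units positive for a marker, optionally within a subtype.

    ``unit="patient"`` implements any-site patient-level positivity: a
    patient counts positive when at least one measured unit is positive, and
    the denominator is the number of evaluable patients.
    """
    stratum = subtype or "all"
    if unit == "patient":
        df = cohort.samples
        col = cohort.config.hscore_column(marker)
        per = df.dropna(subset=[col]).groupby("patient_id")[col].max()
        if per.empty:
            raise EmptyStratumError(f"no patient with measured {marker}")
        n_pos = int((per >= threshold).sum())
        return PositivityResult(marker, stratum, unit, n_pos, int(len(per)), threshold)

    if stratum != "all" and subtypes is None:
        subtypes = attach_subtypes(cohort)
    units = _unit_scores(cohort, [marker], unit, subtypes=subtypes)
    if stratum != "all":
        units = units[units["subtype"] == stratum]
    units = units.dropna(subset=[marker])
    if units.empty:
        raise EmptyStratumError(
            f"no evaluable {unit} units for {marker} in stratum {stratum!r}"
        )
    n_pos = int((units[marker] >= threshold).sum())
    return PositivityResult(marker, stratum, unit, n_pos, int(len(units)), threshold)
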