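"""Four-quadrant AR/NE molecular subtype classification.

Tumors are classified by the joint status of two marker axes: androgen
receptor signaling (AR, NKX3.1) and neuroendocrine differentiation
(SYP, INSM1).  An axis is positive when its aggregated H-score reaches the
positivity threshold, giving four subtypes:

    AR+/NE-  prostatic adenocarcinoma
    AR-/NE+  neuroendocrine prostate cancer (NEPC)
    AR+/NE+  amphicrine carcinoma
    AR-/NE-  double-negative CRPC

Classification happens at the tumor-block level by default: each marker is
first aggregated across the block's cores, then the axis rule is applied.
Externally provided pathologist labels (a ``subtype_label`` cohort column)
take precedence over derived calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean, median

import pandas as pd

from .config import AR_AXIS_MARKERS, NE_AXIS_MARKERS, SUBTYPES
from .cohort import SUBTYPE_LABEL_COLUMN, CohortTable
from .errors import ConfigurationError, IndeterminateSubtypeError, IntegrityError
from .scoring import DEFAULT_THRESHOLD, HScore

_AGGREGATORS = {"max": max, "mean": fmean, "median": median}


@dataclass(frozen=True)
class SubtypeCall:
    """Subtype assignment with the axis scores that produced it."""

    subtype: str
    ar_axis_score: float | None
    ne_axis_score: float | None
    source: str  # "derived" or "provided"

    @property
    def ar_positive(self) -> bool:
        return self.subtype.startswith("AR+")

    @property
    def ne_positive(self) -> bool:
        return self.subtype.endswith("NE+")


def _axis_score(
    scores: tuple[float | None, ...], aggregator: str, axis: str
) -> float:
    if aggregator not in _AGGREGATORS:
        raise ConfigurationError(f"unknown axis aggregator {aggregator!r}")
    present = [float(s.value if isinstance(s, HScore) else s) for s in scores if s is not None and not pd.isna(s)]
    if not present:
        raise IndeterminateSubtypeError(
            f"both {axis} axis markers missing; subtype indeterminate"
        )
    return float(_AGGREGATORS[aggregator](present))


def classify_subtype(
    ar_h: float | HScore | None,
    nkx_h: float | HScore | None,
    syp_h: float | HScore | None,
    insm1_h: float | HScore | None,
    axis_threshold: float = DEFAULT_THRESHOLD,
    aggregator: str = "max",
) -> SubtypeCall:
    """Classify one unit from its four subtype-marker H-scores.

    Missing markers are allowed as long as each axis retains at least one
    measured marker; the axis score is the ``max`` (default) or ``mean`` of
    the measured markers, positive iff >= ``axis_threshold``.
    """
    ar_score = _axis_score((ar_h, nkx_h), aggregator, "AR")
    ne_score = _axis_score((syp_h, insm1_h), aggregator, "NE")
    subtype = (
        ("AR+" if ar_score >= axis_threshold else "AR-")
        + "/"
        + ("NE+" if ne_score >= axis_threshold else "NE-")
    )
    return SubtypeCall(subtype, ar_score, ne_score, source="derived")


def subtype_block(
    cohort: CohortTable,
    block: tuple[str, str, str],
    core_aggregator: str = "max",
    axis_threshold: float = DEFAULT_THRESHOLD,
    axis_aggregator: str = "max",
) -> SubtypeCall:
    """Subtype one tumor block, aggregating markers across its cores.

    ``block`` is the (patient_id, site_id, block_id) triple.  A provided
    ``subtype_label`` overrides the derived call; conflicting labels within
    one block are an integrity error.
    """
    pid, sid, bid = block
    df = cohort.samples
    rows = df[
        (df["patient_id"] == pid) & (df["site_id"] == sid) & (df["block_id"] == bid)
    ]
    if rows.empty:
        raise IntegrityError(f"no cores found for block {block}")

    if SUBTYPE_LABEL_COLUMN in rows.columns:
        labels = sorted(set(rows[SUBTYPE_LABEL_COLUMN].dropna()))
        if len(labels) > 1:
            raise IntegrityError(f"conflicting subtype labels for block {block}: {labels}")
        if labels:
            label = labels[0]
            if label not in SUBTYPES:
                raise IntegrityError(
                    f"block {block}: subtype label {label!r} not one of {SUBTYPES}"
                )
            return SubtypeCall(label, None, None, source="provided")

    if core_aggregator not in _AGGREGATORS:
        raise ConfigurationError(f"unknown core aggregator {core_aggregator!r}")
    agg = _AGGREGATORS[core_aggregator]

    def marker_value(marker: str) -> float | None:
        col = cohort.config.hscore_column(marker)
        if col not in rows.columns:
            return None
        vals = rows[col].dropna()
        return float(agg(vals.tolist())) if len(vals) else None

    ar, nkx = (marker_value(m) for m in AR_AXIS_MARKERS)
    syp, insm1 = (marker_value(m) for m in NE_AXIS_MARKERS)
    return classify_subtype(
        ar, nkx, syp, insm1, axis_threshold=axis_threshold, aggregator=axis_aggregator
    )


def assign_block_subtypes(
    cohort: CohortTable,
    core_aggregator: str = "max",
    axis_threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Subtype every block; one row per block with its call and axis scores."""
    keys = (
        cohort.samples[["patient_id", "site_id", "block_id"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    out = []
    for key in keys:
        call = subtype_block(
            cohort, key, core_aggregator=core_aggregator, axis_threshold=axis_threshold
        )
        out.append(
            {
                "patient_id": key[0],
                "site_id": key[1],
                "block_id": key[2],
                "subtype": call.subtype,
                "ar_axis_score": call.ar_axis_score,
                "ne_axis_score": call.ne_axis_score,
                "source": call.source,
            }
        )
    return pd.DataFrame(out)


def attach_subtypes(cohort: CohortTable, **kwargs) -> pd.Series:
    """Per-core subtype column (each core inherits its block's call)."""
    blocks = assign_block_subtypes(cohort, **kwargs)
    merged = cohort.samples.merge(
        blocks[["patient_id", "site_id", "block_id", "subtype"]],
        on=["patient_id", "site_id", "block_id"],
        how="left",
    )
    return pd.Series(merged["subtype"].to_numpy(), index=cohort.samples.index, name="subtype")
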