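"""Cohort schema, validation and TSV interchange.

A cohort is a long-format table with one row per TMA core.  Mandatory columns
are the four identifiers (``patient_id``, ``site_id``, ``block_id``,
``core_id``) and ``anatomic_site``; marker measurements appear as a
precomputed H-score column ``<marker>_h`` and/or staining-fraction columns
``<marker>_p0/_p1/_p2``.  Empty marker cells mean "not assessed" and are
excluded from every downstream denominator.  Per-patient binary genomic
alteration flags live either in wide ``gene_<NAME>`` columns of the same file
or in a sidecar table ``<stem>.genomic.tsv`` keyed by ``patient_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import ID_COLUMNS, SchemaConfig
from .errors import IntegrityError, SchemaError, VocabularyError
from .scoring import HSCORE_MAX, StainFractions, compute_hscore

SUBTYPE_LABEL_COLUMN = "subtype_label"
_FRACTION_HSCORE_TOL = 1e-6


@dataclass(frozen=True)
class SampleRecord:
    """One validated TMA core with its marker measurements."""

    patient_id: str
    site_id: str
    block_id: str
    core_id: str
    anatomic_site: str
    hscores: dict[str, float]
    subtype_label: str | None = None

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.patient_id, self.site_id, self.block_id, self.core_id)


@dataclass
class CohortTable:
    """Validated cohort of TMA cores plus optional genomic flags.

    ``samples`` always carries the identifier columns, ``anatomic_site`` and
    one ``<marker>_h`` float column per configured marker (NaN where not
    assessed).  Raw fraction columns are preserved when supplied so that
    write/read round-trips are lossless.
    """

    samples: pd.DataFrame
    config: SchemaConfig = field(default_factory=SchemaConfig)
    genomics: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    # -- cohort shape ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_patients(self) -> int:
        return self.samples["patient_id"].nunique()

    @property
    def n_sites(self) -> int:
        return self.samples.groupby(["patient_id", "site_id"]).ngroups if len(self.samples) else 0

    @property
    def n_blocks(self) -> int:
        return (
            self.samples.groupby(["patient_id", "site_id", "block_id"]).ngroups
            if len(self.samples)
            else 0
        )

    def hscores(self, marker: str) -> pd.Series:
        """Per-core H-scores for one marker (NaN = not assessed)."""
        col = self.config.hscore_column(marker)
        if col not in self.samples.columns:
            raise SchemaError(f"marker {marker!r} not present in cohort")
        return self.samples[col]

    def records(self) -> Iterator[SampleRecord]:
        for _, row in self.samples.iterrows():
            hs = {
                m: float(row[self.config.hscore_column(m)])
                for m in self.config.markers
                if self.config.hscore_column(m) in self.samples.columns
                and not pd.isna(row[self.config.hscore_column(m)])
            }
            label = row.get(SUBTYPE_LABEL_COLUMN)
            yield SampleRecord(
                patient_id=row["patient_id"],
                site_id=row["site_id"],
                block_id=row["block_id"],
                core_id=row["core_id"],
                anatomic_site=row["anatomic_site"],
                hscores=hs,
                subtype_label=None if label is None or pd.isna(label) else str(label),
            )

    def validate(self) -> None:
        """Re-run all invariant checks; raises on the first violated kind."""
        _validate_frame(self.samples, self.config)
        if self.genomics is not None:
            _validate_genomics(self.genomics, self.samples, self.config)


# ---------------------------------------------------------------------------
# validation internals
# ---------------------------------------------------------------------------


def _canonical_site(value: str, config: SchemaConfig) -> str:
    return config.site_synonyms.get(value, value)


def _validate_frame(df: pd.DataFrame, config: SchemaConfig) -> None:
    missing = [c for c in (*ID_COLUMNS, "anatomic_site") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    marker_cols = [
        c
        for m in config.markers
        for c in (config.hscore_column(m), *config.fraction_columns(m))
        if c in df.columns
    ]
    if not marker_cols:
        raise SchemaError(
            "no marker measurement columns found; expected at least one of "
            f"{[config.hscore_column(m) for m in config.markers]}"
        )

    integrity: list[str] = []
    vocabulary: list[str] = []

    for col in ID_COLUMNS:
        bad = df.index[df[col].isna() | (df[col].astype(str).str.strip() == "")]
        integrity.extend(f"row {i}: empty {col}" for i in bad)

    dup = df.duplicated(subset=list(ID_COLUMNS), keep=False)
    if dup.any():
        keys = df.loc[dup, list(ID_COLUMNS)].apply(tuple, axis=1).unique()
        integrity.append(
            f"duplicate (patient, site, block, core) identifiers: {sorted(map(str, keys))}"
        )

    vocab = set(config.site_vocabulary)
    for i, raw in df["anatomic_site"].items():
        if pd.isna(raw) or _canonical_site(str(raw), config) not in vocab:
            vocabulary.append(f"row {i}: unknown anatomic site {raw!r}")

    hcols = [config.hscore_column(m) for m in config.markers if config.hscore_column(m) in df.columns]
    for col in hcols:
        vals = df[col]
        bad = df.index[(vals < 0) | (vals > HSCORE_MAX)]
        integrity.extend(
            f"row {i}: {col}={vals[i]} outside [0, {HSCORE_MAX:g}]" for i in bad
        )
    if hcols:
        no_marker = df.index[df[hcols].isna().all(axis=1)]
        integrity.extend(f"row {i}: no marker measurement present" for i in no_marker)

    if integrity:
        raise IntegrityError("; ".join(integrity))
    if vocabulary:
        raise VocabularyError("; ".join(vocabulary))


def _validate_genomics(
    genomics: pd.DataFrame, samples: pd.DataFrame, config: SchemaConfig
) -> None:
    unknown_genes = set(genomics.columns) - set(config.genes)
    if unknown_genes:
        raise VocabularyError(f"unknown genes in genomic flags: {sorted(unknown_genes)}")
    unknown_patients = set(genomics.index) - set(samples["patient_id"])
    if unknown_patients:
        raise IntegrityError(
            f"genomic flags reference unknown patients: {sorted(unknown_patients)}"
        )
    vals = genomics.to_numpy()
    ok = np.isin(vals[~pd.isna(vals)], [0, 1])
    if not ok.all():
        raise IntegrityError("genomic flags must be 0/1")


def _fill_hscores(df: pd.DataFrame, config: SchemaConfig) -> pd.DataFrame:
    """Compute ``<m>_h`` from fraction columns; cross-check when both given."""
    df = df.copy()
    problems: list[str] = []
    for m in config.markers:
        p0c, p1c, p2c = config.fraction_columns(m)
        hc = config.hscore_column(m)
        if p0c not in df.columns:
            if hc not in df.columns:
                continue
            df[hc] = pd.to_numeric(df[hc], errors="coerce")
            continue
        for c in (p0c, p1c, p2c):
            if c not in df.columns:
                raise SchemaError(f"marker {m}: fraction column {c} missing")
            df[c] = pd.to_numeric(df[c], errors="coerce")
        if hc not in df.columns:
            df[hc] = np.nan
        df[hc] = pd.to_numeric(df[hc], errors="coerce")
        has_frac = df[[p0c, p1c, p2c]].notna().all(axis=1)
        for i in df.index[has_frac]:
            try:
                h = compute_hscore(
                    StainFractions(df.at[i, p0c], df.at[i, p1c], df.at[i, p2c])
                ).value
            except IntegrityError as exc:
                problems.append(f"row {i}, marker {m}: {exc}")
                continue
            existing = df.at[i, hc]
            if pd.isna(existing):
                df.at[i, hc] = h
            elif abs(existing - h) > _FRACTION_HSCORE_TOL:
                problems.append(
                    f"row {i}, marker {m}: H-score column {existing} disagrees "
                    f"with fractions ({h})"
                )
    if problems:
        raise IntegrityError("; ".join(problems))
    return df


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------


def _genomic_sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".genomic.tsv")


def read_cohort(path: str | Path, config: SchemaConfig | None = None) -> CohortTable:
    """Read and validate a cohort interchange file.

    Raises :class:`SchemaError`, :class:`IntegrityError` or
    :class:`VocabularyError` with row-indexed diagnostics; a cohort is never
    partially loaded.
    """
    config = config or SchemaConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep=config.delimiter, dtype=str, keep_default_na=False, na_values=[""]
    )
    for col in (*ID_COLUMNS, "anatomic_site", SUBTYPE_LABEL_COLUMN):
        if col in df.columns:
            df[col] = df[col].astype("string").astype(object)

    df = _fill_hscores(df, config)
    _validate_frame(df, config)
    df["anatomic_site"] = [
        _canonical_site(str(v), config) for v in df["anatomic_site"]
    ]

    genomics = None
    gene_cols = [config.gene_column(g) for g in config.genes if config.gene_column(g) in df.columns]
    if gene_cols:
        wide = df[["patient_id", *gene_cols]].drop_duplicates()
        if wide["patient_id"].duplicated().any():
            raise IntegrityError("genomic flag columns differ within a patient")
        genomics = wide.set_index("patient_id")
        genomics.columns = [c.removeprefix("gene_") for c in gene_cols]
        genomics = genomics.apply(pd.to_numeric)
    else:
        sidecar = _genomic_sidecar_path(path)
        if sidecar.exists():
            g = pd.read_csv(sidecar, sep=config.delimiter, dtype={"patient_id": str})
            if "patient_id" not in g.columns:
                raise SchemaError("genomic sidecar missing patient_id column")
            genomics = g.set_index("patient_id")
    if genomics is not None:
        _validate_genomics(genomics, df, config)

    cohort = CohortTable(
        samples=df.reset_index(drop=True),
        config=config,
        genomics=genomics,
        provenance={"source": str(path), "schema_version": "1"},
    )
    return cohort


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to disk; ``read_cohort`` on the result is the identity.

    Column order is fixed (identifiers, anatomic site, optional subtype
    label, then per-marker fraction and H-score columns in panel order) so
    output is byte-stable for a given cohort.  Genomic flags go to a sidecar
    ``<stem>.genomic.tsv``.
    """
    path = Path(path)
    cfg = cohort.config
    cols: list[str] = [*ID_COLUMNS, "anatomic_site"]
    if SUBTYPE_LABEL_COLUMN in cohort.samples.columns:
        cols.append(SUBTYPE_LABEL_COLUMN)
    for m in cfg.markers:
        for c in (*cfg.fraction_columns(m), cfg.hscore_column(m)):
            if c in cohort.samples.columns:
                cols.append(c)
    out = cohort.samples[cols]
    out.to_csv(path, sep=cfg.delimiter, index=False, na_rep="")
    if cohort.genomics is not None:
        g = cohort.genomics.reset_index()
        g.to_csv(_genomic_sidecar_path(path), sep=cfg.delimiter, index=False)
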