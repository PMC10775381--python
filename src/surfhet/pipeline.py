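"""Full-pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes scoring/validation, subtyping, co-expression,
patient classification, heterogeneity and (when genomic flags are present)
association on one cohort file, writing tidy TSV outputs plus a JSON manifest
of input hashes, seeds and per-stage artifacts.  Statistical outputs are a
pure function of (cohort file, config, seed): re-running with the same
inputs reproduces them byte for byte; wall-clock timestamps live only in the
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from . import association, coexpression, heterogeneity
from .cohort import CohortTable, read_cohort
from .config import SchemaConfig
from .errors import DegenerateOutcomeError, EmptyStratumError, NoPairsError, SurfhetError
from .subtyping import assign_block_subtypes, attach_subtypes

SURFACE_MARKERS = ("TROP2", "PSMA", "DLL3", "CEACAM5")
CANONICAL_PAIRS = (("TROP2", "PSMA", "AR+/NE-"), ("DLL3", "CEACAM5", "AR-/NE+"))


def _package_version() -> str:
    try:
        return version("surfhet")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    tool_version: str
    config_hash: str
    input_hashes: dict[str, str]
    seed: int
    started: str
    finished: str | None = None
    outputs: dict[str, str] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)
    complete: bool = False

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    cohort_path: str | Path,
    out_dir: str | Path,
    schema_config: SchemaConfig | None = None,
    seed: int = 0,
    n_pairs: int = 1000,
    n_boot: int = 1000,
    reference_site: str = "vertebral_bone",
    markers: tuple[str, ...] = SURFACE_MARKERS,
) -> RunManifest:
    """Run every analysis stage on one cohort file; returns the manifest."""
    cohort_path = Path(cohort_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema_config = schema_config or SchemaConfig()

    cfg_hash = hashlib.sha256(
        json.dumps(schema_config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        tool_version=_package_version(),
        config_hash=cfg_hash,
        input_hashes={cohort_path.name: _sha256(cohort_path)},
        seed=seed,
        started=datetime.now(timezone.utc).isoformat(),
    )
    manifest_path = out_dir / "manifest.json"

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        manifest.outputs[name] = _sha256(path)

    try:
        cohort = read_cohort(cohort_path, schema_config)

        blocks = assign_block_subtypes(cohort)
        emit("subtypes.tsv", blocks)
        subtypes = attach_subtypes(cohort)

        coex_rows = []
        for a, b, stratum in CANONICAL_PAIRS:
            try:
                t = coexpression.tabulate_coexpression(
                    cohort, a, b, stratum=stratum, subtypes=subtypes
                )
            except EmptyStratumError as exc:
                manifest.notices.append(f"coexpression {a}/{b}: {exc}")
                continue
            pct = t.percentages()
            coex_rows.append(
                {"marker_a": a, "marker_b": b, "stratum": stratum,
                 "both_positive": t.both_positive, "a_only": t.a_only,
                 "b_only": t.b_only, "neither": t.neither, "total": t.total,
                 **{f"pct_{k}": v for k, v in pct.items()}}
            )
        emit("coexpression.tsv", pd.DataFrame(coex_rows))

        class_rows = []
        for m in markers:
            classes, excluded = coexpression.classify_all_patients(cohort, m)
            if excluded:
                manifest.notices.append(
                    f"patient classification {m}: {len(excluded)} patients not evaluable"
                )
            class_rows.append(classes)
        emit("patient_classes.tsv", pd.concat(class_rows, ignore_index=True))

        het_rows = []
        for m in markers:
            for scope in heterogeneity.SCOPES:
                try:
                    pool = heterogeneity.enumerate_pairs(cohort, m, scope)
                except NoPairsError as exc:
                    manifest.notices.append(f"heterogeneity {m}/{scope}: {exc}")
                    continue
                est = heterogeneity.heterogeneity_bootstrap(
                    pool, n_pairs=n_pairs, n_boot=n_boot, seed=seed
                )
                het_rows.append(est.as_row())
        emit("heterogeneity.tsv", pd.DataFrame(het_rows))

        contrast_frames = []
        for m in markers:
            try:
                contrasts = association.site_mixed_model(cohort, m, reference_site)
            except (DegenerateOutcomeError, SurfhetError) as exc:
                manifest.notices.append(f"site model {m}: {exc}")
                continue
            contrast_frames.append(association.site_contrasts_frame(contrasts))
        if contrast_frames:
            emit("site_contrasts.tsv", pd.concat(contrast_frames, ignore_index=True))

        if cohort.genomics is None:
            manifest.notices.append("association stage skipped: no genomic flags")
        else:
            assoc_rows = []
            for m in markers:
                for gene in cohort.genomics.columns:
                    try:
                        assoc_rows.append(
                            association.genomic_logistic(cohort, m, gene)
                        )
                    except (DegenerateOutcomeError, SurfhetError) as exc:
                        manifest.notices.append(f"association {m}~{gene}: {exc}")
            if assoc_rows:
                emit("associations.tsv", association.associations_frame(assoc_rows))

        manifest.complete = True
    finally:
        manifest.finished = datetime.now(timezone.utc).isoformat()
        manifest.save(manifest_path)
    return manifest
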