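"""Cohort schema configuration.

The interchange format is a UTF-8 delimited text file (TSV by default, CSV by
flag) with one row per TMA core.  Which columns carry identifiers, which
markers are expected and what the positivity threshold is are all held in a
:class:`SchemaConfig` so that cohorts scored with different marker panels or
site vocabularies can reuse the same readers and estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Cell-surface targets plus the subtype-defining marker panel.
DEFAULT_MARKERS: tuple[str, ...] = (
    "TROP2", "PSMA", "DLL3", "CEACAM5", "AR", "NKX3.1", "SYP", "INSM1",
)

#: Androgen-receptor-axis and neuroendocrine-axis markers used for subtyping.
AR_AXIS_MARKERS: tuple[str, str] = ("AR", "NKX3.1")
NE_AXIS_MARKERS: tuple[str, str] = ("SYP", "INSM1")

#: The four-quadrant molecular subtype labels.
SUBTYPES: tuple[str, ...] = ("AR+/NE-", "AR-/NE+", "AR+/NE+", "AR-/NE-")

#: Closed vocabulary of 11 major anatomic metastatic site categories.
DEFAULT_SITE_VOCABULARY: tuple[str, ...] = (
    "vertebral_bone",
    "other_bone",
    "liver",
    "lung",
    "lymph_node",
    "prostate_bed",
    "adrenal",
    "dura",
    "peritoneum",
    "pleura",
    "other_soft_tissue",
)

#: Genes with per-patient binary alteration flags.
DEFAULT_GENES: tuple[str, ...] = (
    "AR", "BRCA2", "CHD1", "PTEN", "RB1", "SPOP", "TP53",
)

ID_COLUMNS: tuple[str, ...] = ("patient_id", "site_id", "block_id", "core_id")


@dataclass
class SchemaConfig:
    """Column layout, vocabularies and thresholds for one cohort file.

    Parameters
    ----------
    markers
        Marker panel; each marker ``M`` may appear in the file as a
        precomputed H-score column ``M_h`` and/or staining-fraction columns
        ``M_p0, M_p1, M_p2`` (percent of cells at intensity 0/1/2).
    site_vocabulary
        Closed list of accepted anatomic site labels.
    site_synonyms
        Mapping from nonstandard spellings onto vocabulary labels, applied
        before validation (e.g. ``{"LN": "lymph_node"}``).
    positivity_threshold
        H-score cut-off for binarized positivity (positive iff score >= it);
        one global value applied to every marker.
    delimiter
        Field delimiter of the interchange file ("\\t" or ",").
    genes
        Accepted gene names for per-patient alteration flags.
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    site_vocabulary: tuple[str, ...] = DEFAULT_SITE_VOCABULARY
    site_synonyms: dict[str, str] = field(default_factory=dict)
    positivity_threshold: float = 20.0
    delimiter: str = "\t"
    genes: tuple[str, ...] = DEFAULT_GENES

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        self.site_vocabulary = tuple(self.site_vocabulary)
        self.genes = tuple(self.genes)
        if self.positivity_threshold < 0:
            raise ConfigurationError(
                f"positivity threshold must be >= 0, got {self.positivity_threshold}"
            )
        if self.delimiter not in ("\t", ","):
            raise ConfigurationError(
                f"delimiter must be tab or comma, got {self.delimiter!r}"
            )
        if not self.markers:
            raise ConfigurationError("marker list must be non-empty")
        bad = {v for v in self.site_synonyms.values()} - set(self.site_vocabulary)
        if bad:
            raise ConfigurationError(
                f"site synonyms map onto unknown labels: {sorted(bad)}"
            )

    # -- marker column helpers -------------------------------------------

    def hscore_column(self, marker: str) -> str:
        return f"{marker}_h"

    def fraction_columns(self, marker: str) -> tuple[str, str, str]:
        return (f"{marker}_p0", f"{marker}_p1", f"{marker}_p2")

    def gene_column(self, gene: str) -> str:
        return f"gene_{gene}"

    # -- (de)serialization -----------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["markers"] = list(self.markers)
        d["site_vocabulary"] = list(self.site_vocabulary)
        d["genes"] = list(self.genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SchemaConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown schema config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SchemaConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigurationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)
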