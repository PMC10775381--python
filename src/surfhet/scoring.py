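"""H-score computation and binarization.

Semiquantitative IHC scoring on a two-intensity scale: each tumor sample is
scored as the percentage of cells with no staining (level 0), faint staining
(level 1) and prominent staining (level 2).  The H-score is the
intensity-weighted sum

    H = 0 * p0 + 1 * p1 + 2 * p2,      0 <= H <= 200,

and a sample is called positive for a marker when its H-score reaches the
positivity threshold (default 20, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, IntegrityError

HSCORE_MAX = 200.0
DEFAULT_THRESHOLD = 20.0

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class StainFractions:
    """Percentages of cells at staining levels 0, 1 and 2 (sum to 100)."""

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for name, v in (("p0", self.p0), ("p1", self.p1), ("p2", self.p2)):
            if v < 0 or v > 100:
                raise IntegrityError(f"stain fraction {name}={v} outside [0, 100]")
        total = self.p0 + self.p1 + self.p2
        if abs(total - 100.0) > max(_FRACTION_TOL, 100 * _FRACTION_TOL):
            raise IntegrityError(
                f"stain fractions sum to {total}, expected 100"
            )


@dataclass(frozen=True)
class HScore:
    """Validated H-score on the [0, 200] scale."""

    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= HSCORE_MAX):
            raise IntegrityError(f"H-score {self.value} outside [0, {HSCORE_MAX:g}]")


@dataclass(frozen=True)
class BinaryStatus:
    """Positive/negative call together with the threshold that produced it."""

    positive: bool
    threshold: float


def compute_hscore(fractions: StainFractions) -> HScore:
    """Intensity-weighted H-score from staining-level fractions."""
    return HScore(0.0 * fractions.p0 + 1.0 * fractions.p1 + 2.0 * fractions.p2)


def binarize(h: HScore | float, threshold: float = DEFAULT_THRESHOLD) -> BinaryStatus:
    """Call a sample positive iff its H-score is >= ``threshold``.

    The boundary is inclusive: an H-score exactly at the threshold is
    positive.
    """
    if threshold < 0:
        raise ConfigurationError(f"positivity threshold must be >= 0, got {threshold}")
    value = h.value if isinstance(h, HScore) else HScore(float(h)).value
    return BinaryStatus(positive=value >= threshold, threshold=threshold)
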