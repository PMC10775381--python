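"""Typed exception hierarchy.

Every failure mode the pipeline can hit maps to one of these classes so that
callers (and the CLI, which converts them to distinct exit codes) can react to
the *kind* of problem: malformed input, bad configuration, or a statistical
degeneracy in an otherwise well-formed dataset.
"""


class SurfhetError(Exception):
    """Base class for all package errors."""


class SchemaError(SurfhetError):
    """Input table is missing mandatory columns or has an unusable layout."""


class IntegrityError(SurfhetError):
    """Row-level constraint violated (duplicate keys, out-of-range values)."""


class VocabularyError(SurfhetError):
    """A categorical value falls outside the configured vocabulary."""


class ConfigurationError(SurfhetError):
    """Invalid or infeasible configuration value."""


class IndeterminateSubtypeError(SurfhetError):
    """Both markers of a subtype axis are missing for a block."""


class EmptyStratumError(SurfhetError):
    """No evaluable units remain after stratum / missingness filtering."""


class NoPairsError(SurfhetError):
    """A heterogeneity pair pool is empty at the requested scope."""


class DegenerateOutcomeError(SurfhetError):
    """A regression outcome or exposure has a single observed class."""


class FittingError(SurfhetError):
    """A statistical model failed to converge."""
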