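"""Typed exceptions raised across the pipeline.

Every malformed input raises one of these; nothing is silently coerced.
"""


class HypoxsigError(Exception):
    """Base class for all package errors."""


class FormatError(HypoxsigError):
    """A file or table violates its format contract (non-integer cell,
    duplicate IDs, negative expression, malformed GMT line, ...)."""


class ConsistencyError(HypoxsigError):
    """Two artifacts that must agree do not (e.g. a sample present in the
    count matrix but missing from the sample sheet)."""


class EstimationError(HypoxsigError):
    """A statistical estimate cannot be formed from the given data
    (e.g. no gene with positive counts in every sample)."""


class ValidationError(HypoxsigError):
    """A configuration or argument contract is violated."""
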