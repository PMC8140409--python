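"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`PMHIAError` so the CLI can map any
validation failure to a non-zero exit naming the failing stage.
"""


class PMHIAError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PMHIAError):
    """A file does not match the expected on-disk format (units, variables)."""


class GridError(PMHIAError):
    """Grid inconsistency: irregular spacing, mismatched grids, pole crossing."""


class ValidationError(PMHIAError):
    """An in-memory object violates a domain invariant."""


class SchemaError(PMHIAError):
    """A tabular input does not match its declared schema."""


class CoverageError(PMHIAError):
    """A lookup table does not cover a required key (country, endpoint, age)."""


class DomainError(PMHIAError):
    """Spatial domains do not overlap as required."""
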