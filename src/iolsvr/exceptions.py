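"""Exception types shared across the package."""


class IolsvrError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(IolsvrError, ValueError):
    """A biometry value or parameter violates its physical precondition."""


class InvalidConfigError(IolsvrError, ValueError):
    """A configuration object (grid, catalogue, correlation) is unusable."""


class InvalidGeometryError(IolsvrError, ValueError):
    """The optical geometry is degenerate (e.g. lens plane behind retina)."""


class SchemaError(IolsvrError, ValueError):
    """A cohort table does not conform to the canonical schema."""
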