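"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage errors exit 1, :class:`DataError`
exits 2, :class:`NumericalError` exits 3.
"""


class BprwError(Exception):
    """Base class for all package-specific errors."""


class DataError(BprwError):
    """Malformed, irregular, or otherwise unusable input data."""


class IrregularSamplingError(DataError):
    """A track's timestamps deviate from a fixed sampling interval."""


class SchemaError(DataError):
    """A parameter or configuration file does not match the expected schema."""


class NumericalError(BprwError):
    """A fit or estimator failed to converge or is degenerate."""
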