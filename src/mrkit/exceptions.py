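"""Exception hierarchy.

Everything raised deliberately by mrkit derives from :class:`MRKitError`,
so callers can catch one type. I/O failures from the filesystem itself
(missing files) propagate as the builtin ``FileNotFoundError``.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class SchemaError(MRKitError):
    """A required column is missing or a file's layout cannot be understood."""


class ValidationError(MRKitError):
    """Data violates an invariant (bad allele, non-positive SE, asymmetric LD...)."""


class ParameterError(MRKitError):
    """A caller-supplied parameter is outside its valid range."""


class HarmonizationError(MRKitError):
    """Harmonization left no usable variants, so estimation is impossible."""


class EstimationError(MRKitError):
    """An estimator cannot be computed on the given instrument."""
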