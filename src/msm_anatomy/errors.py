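"""Exception hierarchy shared across the pipeline stages."""


class MsmAnatomyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MsmAnatomyError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ParseError(MsmAnatomyError, ValueError):
    """A sequence or alignment file could not be parsed."""


class ValidationError(MsmAnatomyError, ValueError):
    """Input violates a documented precondition."""


class UsageError(MsmAnatomyError, ValueError):
    """An operation was invoked with unsupported arguments."""


class SamplingError(MsmAnatomyError, ValueError):
    """A random sample was requested that the input cannot provide."""
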