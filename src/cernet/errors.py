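"""Exception hierarchy shared by all pipeline stages."""


class CernetError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CernetError, ValueError):
    """An argument violates a documented precondition."""


class NotFoundError(CernetError, KeyError):
    """A requested identifier is absent from the given container."""


class InsufficientDataError(CernetError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateInputError(CernetError, ValueError):
    """Input is formally valid but the statistic is undefined on it
    (e.g. a paired t-test on differences with zero variance)."""


class SchemaError(CernetError, ValueError):
    """An input file does not match the expected tabular schema."""
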