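"""Exception types shared across the pipeline."""


class LewysegError(Exception):
    """Base class for package errors."""


class ParameterError(LewysegError, ValueError):
    """A parameter is outside its documented range."""


class DomainError(LewysegError, ValueError):
    """Input values violate a mathematical precondition (e.g. negative OD)."""


class DegenerateInputError(LewysegError, ValueError):
    """Input carries too little signal for the requested operation."""


class InvalidWhitePointError(LewysegError, ValueError):
    """The brightfield white point I0 must be strictly positive."""
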