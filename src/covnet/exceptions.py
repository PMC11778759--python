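"""Exception hierarchy for covnet."""


class CovnetError(Exception):
    """Base class for all covnet errors."""


class FormatError(CovnetError, ValueError):
    """A delimited-text input violated the expected layout or content."""


class ConvergenceError(CovnetError, RuntimeError):
    """An iterative solver exhausted its iteration budget."""
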