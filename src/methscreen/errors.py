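"""Exception hierarchy for methscreen."""


class MethscreenError(Exception):
    """Base class for all package errors."""


class ParameterError(MethscreenError, ValueError):
    """A configuration or function parameter is out of its valid domain."""


class SizingError(ParameterError):
    """A simulation request cannot fit in the configured genome."""


class ParseError(MethscreenError, ValueError):
    """An input file violates its declared dialect; message names the line."""


class DegenerateInputError(MethscreenError, ValueError):
    """A statistic was requested on an input too small to define it."""


class UndefinedLevelError(MethscreenError, ValueError):
    """A methylation level was requested at a site with zero coverage."""


class UndefinedRatioError(MethscreenError, ValueError):
    """A relative change was requested from a zero baseline."""


class UndefinedCorrelationError(MethscreenError, ValueError):
    """A correlation was requested against a constant vector."""


class UndefinedTestError(MethscreenError, ValueError):
    """A contingency test was requested on a table with a zero margin."""


class ContractError(MethscreenError, ValueError):
    """A caller violated an operation's documented precondition."""
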