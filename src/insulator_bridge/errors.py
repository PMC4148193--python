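"""Exception hierarchy shared by all analysis stages."""


class InsulatorBridgeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(InsulatorBridgeError, ValueError):
    """A model parameter is outside its physically meaningful range."""


class InputError(InsulatorBridgeError, ValueError):
    """Input data violate a precondition (too few points, wrong shape, ...)."""


class ConfigError(InsulatorBridgeError, ValueError):
    """A configuration value is inconsistent (e.g. window not a multiple of bin)."""


class FitFailureError(InsulatorBridgeError, RuntimeError):
    """No start of a multi-start fit converged.

    Carries per-start diagnostics so callers can see what was attempted.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = list(diagnostics or [])


class ParseError(InsulatorBridgeError, ValueError):
    """A record in a text file could not be parsed.

    Parameters
    ----------
    message : description of the problem
    path : file being read
    line : 1-based line number of the offending record
    """

    def __init__(self, message: str, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
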