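"""Exception hierarchy shared across the pipeline."""


class LnclusterError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LnclusterError, ValueError):
    """Invalid configuration or parameter value."""


class FormatError(LnclusterError, ValueError):
    """Malformed input file.

    Carries file/line/field coordinates so that parse failures are
    actionable; ``str()`` renders them.
    """

    def __init__(self, message, *, path=None, line=None, field=None):
        self.path = path
        self.line = line
        self.field = field
        coords = []
        if path is not None:
            coords.append(str(path))
        if line is not None:
            coords.append(f"line {line}")
        if field is not None:
            coords.append(f"field {field!r}")
        prefix = ":".join(coords)
        super().__init__(f"{prefix}: {message}" if prefix else message)


class InputError(LnclusterError, ValueError):
    """Invalid in-memory input to an operation."""


class DegenerateTemplateError(InputError):
    """A cluster template with no contrast (all ones or cluster absent)."""


class UndefinedCorrelationError(InputError):
    """Pearson correlation requested against a constant vector."""
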