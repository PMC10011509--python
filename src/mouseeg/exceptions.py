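"""Exception hierarchy shared across the pipeline."""


class MouseEEGError(Exception):
    """Base class for all package errors."""


class ParameterError(MouseEEGError, ValueError):
    """A parameter value is invalid or an infeasible combination was requested."""


class FormatError(MouseEEGError, IOError):
    """An on-disk file is malformed (corrupt header, truncation, bad table)."""


class ClassificationError(MouseEEGError, RuntimeError):
    """Sleep staging cannot proceed (degenerate features, too few epochs)."""


class DegenerateInputError(MouseEEGError, ValueError):
    """A statistical routine received input with no usable variance."""
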