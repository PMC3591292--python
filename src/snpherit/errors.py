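"""Exception types shared across the package."""


class SnpheritError(Exception):
    """Base class for package errors."""


class ConfigurationError(SnpheritError, ValueError):
    """A configuration value is outside its documented range."""


class QcError(SnpheritError, ValueError):
    """Quality control produced an unusable result (e.g. no SNPs retained)."""


class ConvergenceError(SnpheritError, RuntimeError):
    """REML failed to converge; carries the last iteration state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state
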