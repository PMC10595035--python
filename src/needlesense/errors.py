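"""Exception hierarchy shared across the toolkit."""


class NeedleSenseError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(NeedleSenseError, ValueError):
    """Bad user input: malformed spectrum, label, config value, ..."""


class FormatError(NeedleSenseError, ValueError):
    """Malformed file or incompatible grids/shapes."""


class CalibrationError(NeedleSenseError, ValueError):
    """Calibration table violates its monotonicity contract."""


class ConfigError(NeedleSenseError, ValueError):
    """Invalid configuration (out-of-range motor step, unknown class, ...)."""


class DivergenceError(NeedleSenseError, RuntimeError):
    """Training cost became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged (non-finite cost) at epoch {epoch}")
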